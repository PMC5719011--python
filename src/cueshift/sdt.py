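"""Signal detection metrics for the cued orientation task.

The "right" (clockwise) stimulus is treated as the target throughout, so
the hit rate is P(respond right | right stimulus) and the false-alarm
rate is P(respond right | left stimulus).  Sensitivity and criterion are

    d' = Phi^-1(HR) - Phi^-1(FAR)
    c  = -0.5 * (Phi^-1(HR) + Phi^-1(FAR))

with Phi^-1 the standard normal quantile, so positive c is a bias toward
"left" responses and negative c a bias toward "right".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

__all__ = [
    "RateEstimate",
    "SDTMetrics",
    "CueEffect",
    "InsufficientDataError",
    "compute_rates",
    "dprime_criterion",
    "optimal_criterion",
    "cue_effects",
    "sdt_by_condition",
    "condition_effects",
]


class InsufficientDataError(ValueError):
    """A condition cell holds no signal or no noise trials."""


@dataclass(frozen=True)
class RateEstimate:
    hit_rate: float
    false_alarm_rate: float
    n_signal: int
    n_noise: int
    correction: str = "none"  # "none" or "adjusted"


@dataclass(frozen=True)
class SDTMetrics:
    dprime: float
    criterion_c: float


@dataclass(frozen=True)
class CueEffect:
    """Left-minus-right cue contrasts within one cue time (pre or post)."""

    delta_c: float
    delta_dprime: float
    delta_c_optimal: float | None = None


def compute_rates(
    stim: pd.Series | np.ndarray,
    responses: pd.Series | np.ndarray,
    mask: pd.Series | np.ndarray | None = None,
    condition: str = "",
) -> RateEstimate:
    """Hit and false-alarm rates, with 1/(2N) correction at the boundary.

    ``stim`` and ``responses`` are "left"/"right" labels; ``mask``
    restricts to a condition subset.  Rates of exactly 0 or 1 are moved to
    1/(2N) and 1 - 1/(2N) (N the relevant trial count) and the estimate is
    flagged as adjusted.
    """
    stim = np.asarray(stim, dtype=object)
    responses = np.asarray(responses, dtype=object)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        stim, responses = stim[mask], responses[mask]
    signal = stim == "right"
    noise = stim == "left"
    n_signal, n_noise = int(signal.sum()), int(noise.sum())
    if n_signal == 0 or n_noise == 0:
        raise InsufficientDataError(
            f"condition {condition or '<unnamed>'}: needs at least one right- and "
            f"one left-stimulus trial (got {n_signal} signal, {n_noise} noise)"
        )
    hr = float((responses[signal] == "right").mean())
    far = float((responses[noise] == "right").mean())
    correction = "none"
    if hr == 0.0:
        hr, correction = 1.0 / (2 * n_signal), "adjusted"
    elif hr == 1.0:
        hr, correction = 1.0 - 1.0 / (2 * n_signal), "adjusted"
    if far == 0.0:
        far, correction = 1.0 / (2 * n_noise), "adjusted"
    elif far == 1.0:
        far, correction = 1.0 - 1.0 / (2 * n_noise), "adjusted"
    return RateEstimate(hr, far, n_signal, n_noise, correction)


def dprime_criterion(rates: RateEstimate) -> SDTMetrics:
    """Sensitivity d' and criterion c from corrected hit/false-alarm rates."""
    hr, far = rates.hit_rate, rates.false_alarm_rate
    if not (0.0 < hr < 1.0 and 0.0 < far < 1.0):
        raise ValueError(
            "rates must lie strictly inside (0, 1); apply the boundary "
            "correction in compute_rates first"
        )
    z_hr, z_far = norm.ppf(hr), norm.ppf(far)
    return SDTMetrics(dprime=z_hr - z_far, criterion_c=-0.5 * (z_hr + z_far))


def optimal_criterion(odds_a: float, dprime: float) -> float:
    """Accuracy-maximising criterion ln(a) / d'.

    ``odds_a`` is the prior odds of a left vs right stimulus given the
    cue (2 for a left cue at 66.67% validity, 1/2 for a right cue).
    """
    if odds_a <= 0:
        raise ValueError("odds_a must be > 0")
    if dprime <= 0:
        raise ValueError("optimal criterion undefined for d' <= 0")
    return float(np.log(odds_a) / dprime)


def cue_effects(
    left: SDTMetrics,
    right: SDTMetrics,
    validity: float | None = 2.0 / 3.0,
    dprime_for_shift: float | None = None,
) -> CueEffect:
    """Left-minus-right contrasts of criterion and sensitivity.

    ``delta_c_optimal`` is the shift an accuracy-maximising observer would
    show between left and right cues of the given validity, computed from
    ``dprime_for_shift`` if supplied, else from each cue's own d'.  It is
    omitted (None) when validity is None or any required d' is <= 0.
    """
    delta_c = left.criterion_c - right.criterion_c
    delta_d = left.dprime - right.dprime
    delta_opt: float | None = None
    if validity is not None:
        a = validity / (1.0 - validity)
        d_left = dprime_for_shift if dprime_for_shift is not None else left.dprime
        d_right = dprime_for_shift if dprime_for_shift is not None else right.dprime
        if d_left > 0 and d_right > 0:
            delta_opt = optimal_criterion(a, d_left) - optimal_criterion(1.0 / a, d_right)
    return CueEffect(delta_c=delta_c, delta_dprime=delta_d, delta_c_optimal=delta_opt)


def sdt_by_condition(trials: pd.DataFrame, responses: pd.Series) -> pd.DataFrame:
    """Per subject x block_type x cue SDT table.

    Returns one row per cell with HR, FAR, n_signal, n_noise, correction,
    dprime and c.
    """
    rows = []
    for (subject, bt, cue), idx in trials.groupby(
        ["subject", "block_type", "cue"]
    ).groups.items():
        sub = trials.loc[idx]
        rates = compute_rates(
            sub["stim"], responses.loc[idx], condition=f"{subject}/{bt}/{cue}"
        )
        m = dprime_criterion(rates)
        rows.append(
            {
                "subject": subject,
                "block_type": bt,
                "cue": cue,
                "hr": rates.hit_rate,
                "far": rates.false_alarm_rate,
                "n_signal": rates.n_signal,
                "n_noise": rates.n_noise,
                "correction": rates.correction,
                "dprime": m.dprime,
                "c": m.criterion_c,
            }
        )
    return pd.DataFrame(rows)


def condition_effects(
    metrics: pd.DataFrame, validity: float = 2.0 / 3.0
) -> pd.DataFrame:
    """Per subject x block_type cue-effect table from :func:`sdt_by_condition`.

    Emits delta_c = c_left - c_right, delta_dprime, and delta_c_optimal.
    """
    rows = []
    for (subject, bt), grp in metrics.groupby(["subject", "block_type"]):
        by_cue = grp.set_index("cue")
        if not {"left", "right"} <= set(by_cue.index):
            raise InsufficientDataError(
                f"subject {subject} {bt}: needs both left- and right-cue cells"
            )
        left = SDTMetrics(by_cue.loc["left", "dprime"], by_cue.loc["left", "c"])
        right = SDTMetrics(by_cue.loc["right", "dprime"], by_cue.loc["right", "c"])
        eff = cue_effects(left, right, validity=validity)
        rows.append(
            {
                "subject": subject,
                "block_type": bt,
                "delta_c": eff.delta_c,
                "delta_dprime": eff.delta_dprime,
                "delta_c_optimal": eff.delta_c_optimal,
            }
        )
    return pd.DataFrame(rows)
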