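"""Psychophysical reverse correlation via per-predictor logistic regression.

Two complementary views of how trial-to-trial stimulus fluctuations drive
the observer's choice:

* **temporal**: for each of the 30 frames, an intercept + single-slope
  logistic regression of the response (right = 1) on that frame's
  orientation *in radians*.  The 30 slopes form a temporal information-
  usage profile; running the same regressions on the stimulus category
  instead of the response yields the optimal-usage benchmark.
* **feature**: for each whole-degree orientation theta in [-40, +40], the
  per-trial count of frames falling in the closed band
  [theta - 5, theta + 5] enters a logistic regression of the response on
  that count.  The 81 slopes form a feature information-usage profile.

Fits are plain maximum likelihood (no regularisation) so that perfect
separation shows up as extreme coefficients; such fits are flagged and
repaired from neighbouring orientations (:func:`repair_extreme_betas`),
mirroring how degenerate regressions are handled in practice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import (
    ConvergenceWarning,
    PerfectSeparationWarning,
)

from .synthetic_data import orientation_matrix

__all__ = [
    "TemporalProfile",
    "FeatureProfile",
    "fit_logit_slope",
    "temporal_revcorr",
    "optimal_temporal_usage",
    "feature_counts",
    "feature_count_matrix",
    "feature_revcorr",
    "repair_extreme_betas",
    "smooth_timecourse",
    "profile_slope",
    "FEATURE_THETAS",
    "BETA_FLAG_THRESHOLD",
]

#: Whole-degree feature orientations analysed.
FEATURE_THETAS = np.arange(-40, 41)

#: Half-width (degrees) of the closed orientation band around each theta.
FEATURE_HALF_WIDTH = 5.0

#: |beta| beyond this (per radian or per count) is treated as degenerate.
BETA_FLAG_THRESHOLD = 10.0

#: Fewest trials a condition may hold before fitting is refused.
MIN_TRIALS = 20


@dataclass
class TemporalProfile:
    """Frame-wise regression slopes (log-odds of "right" per radian)."""

    betas: np.ndarray  # shape (n_frames,)
    ses: np.ndarray
    flagged: np.ndarray  # bool, degenerate fits
    condition: str = ""
    n_trials: int = 0


@dataclass
class FeatureProfile:
    """Orientation-band regression slopes (log-odds of "right" per patch count)."""

    betas: np.ndarray  # shape (81,), indexed by FEATURE_THETAS
    ses: np.ndarray
    flagged: np.ndarray
    thetas: np.ndarray = field(default_factory=lambda: FEATURE_THETAS.copy())
    condition: str = ""
    n_trials: int = 0
    repair_log: list = field(default_factory=list)

    @property
    def n_regressions(self) -> int:
        return len(self.betas)


def fit_logit_slope(x: np.ndarray, y: np.ndarray) -> tuple[float, float, bool]:
    """Fit an intercept + single-slope logistic regression by ML.

    Returns (slope, standard error, flagged).  ``flagged`` is True when
    the fit is degenerate: perfect separation, non-convergence, a
    constant predictor or response, or |slope| above
    :data:`BETA_FLAG_THRESHOLD`.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.min() == y.max():
        return np.nan, np.nan, True
    X = np.column_stack([np.ones_like(x), x])
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            res = sm.Logit(y, X).fit(disp=0, maxiter=100)
            beta, se = float(res.params[1]), float(res.bse[1])
        except Exception:
            return np.nan, np.nan, True
    for w in caught:
        if issubclass(w.category, (ConvergenceWarning, PerfectSeparationWarning)):
            flagged = True
    if not np.isfinite(beta) or not np.isfinite(se):
        flagged = True
    if np.isfinite(beta) and abs(beta) > BETA_FLAG_THRESHOLD:
        flagged = True
    return beta, se, flagged


def _as_binary(labels: pd.Series | np.ndarray) -> np.ndarray:
    """Code "right" responses/stimuli as 1 and "left" as 0."""
    arr = np.asarray(labels, dtype=object)
    bad = ~np.isin(arr, ("left", "right"))
    if bad.any():
        raise ValueError(f"labels must be 'left'/'right'; got {set(arr[bad])}")
    return (arr == "right").astype(float)


def temporal_revcorr(
    trials: pd.DataFrame,
    responses: pd.Series | np.ndarray,
    condition: str = "",
    min_trials: int = MIN_TRIALS,
    multivariate: bool = False,
) -> TemporalProfile:
    """Temporal information-usage profile of the given trials.

    One univariate logistic regression per frame of the response
    (right = 1) on that frame's orientation converted to radians.  With
    ``multivariate=True`` a single 30-predictor model is fit instead and
    its slopes returned; the univariate reading is the default.
    """
    y = _as_binary(responses)
    ori = np.deg2rad(orientation_matrix(trials))
    if len(y) != len(ori):
        raise ValueError("responses must align with trials")
    if len(y) < min_trials:
        raise ValueError(
            f"condition {condition or '<unnamed>'}: {len(y)} trials < "
            f"minimum {min_trials}"
        )
    n_frames = ori.shape[1]
    if multivariate:
        X = np.column_stack([np.ones(len(y)), ori])
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        bad = any(
            issubclass(w.category, (ConvergenceWarning, PerfectSeparationWarning))
            for w in caught
        )
        betas = np.asarray(res.params[1:], dtype=float)
        ses = np.asarray(res.bse[1:], dtype=float)
        flagged = np.full(n_frames, bad) | ~np.isfinite(betas) | (
            np.abs(betas) > BETA_FLAG_THRESHOLD
        )
        return TemporalProfile(
            betas, ses, flagged, condition=condition, n_trials=len(y)
        )
    betas = np.empty(n_frames)
    ses = np.empty(n_frames)
    flagged = np.zeros(n_frames, dtype=bool)
    for f in range(n_frames):
        betas[f], ses[f], flagged[f] = fit_logit_slope(ori[:, f], y)
    return TemporalProfile(betas, ses, flagged, condition=condition, n_trials=len(y))


def optimal_temporal_usage(
    trials: pd.DataFrame, condition: str = "", min_trials: int = MIN_TRIALS
) -> TemporalProfile:
    """Optimal-usage benchmark: regress the stimulus category, not the response."""
    return temporal_revcorr(
        trials, trials["stim"], condition=condition or "optimal", min_trials=min_trials
    )


def feature_counts(
    orientations: np.ndarray, theta: float, half_width: float = FEATURE_HALF_WIDTH
) -> int:
    """Number of frames with orientation in the closed band [theta-hw, theta+hw]."""
    if not -40 <= theta <= 40:
        raise ValueError("theta must lie in [-40, 40]")
    ori = np.asarray(orientations, dtype=float)
    return int(((ori >= theta - half_width) & (ori <= theta + half_width)).sum())


def feature_count_matrix(
    ori: np.ndarray,
    thetas: np.ndarray = FEATURE_THETAS,
    half_width: float = FEATURE_HALF_WIDTH,
) -> np.ndarray:
    """Per-trial band counts for every theta; shape (n_trials, len(thetas))."""
    ori = np.asarray(ori, dtype=float)
    counts = np.empty((ori.shape[0], len(thetas)), dtype=float)
    for j, th in enumerate(thetas):
        counts[:, j] = ((ori >= th - half_width) & (ori <= th + half_width)).sum(axis=1)
    return counts


def feature_revcorr(
    trials: pd.DataFrame,
    responses: pd.Series | np.ndarray,
    condition: str = "",
    min_trials: int = MIN_TRIALS,
    repair: bool = True,
) -> FeatureProfile:
    """Feature information-usage profile over the 81 orientation bands.

    Orientations stay in degrees; the predictor for each theta is the
    per-trial count of frames within [theta - 5, theta + 5].  Degenerate
    fits are flagged and, when ``repair`` is on, replaced via
    :func:`repair_extreme_betas`.
    """
    y = _as_binary(responses)
    ori = orientation_matrix(trials)
    if len(y) != len(ori):
        raise ValueError("responses must align with trials")
    if len(y) < min_trials:
        raise ValueError(
            f"condition {condition or '<unnamed>'}: {len(y)} trials < "
            f"minimum {min_trials}"
        )
    counts = feature_count_matrix(ori)
    k = len(FEATURE_THETAS)
    betas = np.empty(k)
    ses = np.empty(k)
    flagged = np.zeros(k, dtype=bool)
    for j in range(k):
        betas[j], ses[j], flagged[j] = fit_logit_slope(counts[:, j], y)
    profile = FeatureProfile(
        betas, ses, flagged, condition=condition, n_trials=len(y)
    )
    return repair_extreme_betas(profile) if repair else profile


class UnrepairableProfileError(RuntimeError):
    """Every regression in the profile is degenerate."""


def repair_extreme_betas(profile: FeatureProfile) -> FeatureProfile:
    """Replace degenerate betas from neighbouring orientations.

    Each flagged beta becomes the inverse-distance-weighted mean of the
    nearest non-flagged beta on each side (one-sided at the boundary);
    replacements always draw on original, non-flagged values.  Every
    substitution is appended to ``repair_log`` as
    (theta, old_beta, new_beta).  The flag array is preserved so callers
    can still see which fits were degenerate.
    """
    flagged = profile.flagged
    if not flagged.any():
        return profile
    if flagged.all():
        raise UnrepairableProfileError(
            f"condition {profile.condition or '<unnamed>'}: all "
            f"{len(flagged)} regressions degenerate"
        )
    good = np.flatnonzero(~flagged)
    betas = profile.betas.copy()
    log = list(profile.repair_log)
    for j in np.flatnonzero(flagged):
        left = good[good < j]
        right = good[good > j]
        if left.size and right.size:
            jl, jr = left[-1], right[0]
            dl, dr = j - jl, jr - j
            wl, wr = 1.0 / dl, 1.0 / dr
            new = (wl * profile.betas[jl] + wr * profile.betas[jr]) / (wl + wr)
        elif left.size:
            new = profile.betas[left[-1]]
        else:
            new = profile.betas[right[0]]
        log.append((int(profile.thetas[j]), float(betas[j]), float(new)))
        betas[j] = new
    return FeatureProfile(
        betas=betas,
        ses=profile.ses.copy(),
        flagged=flagged.copy(),
        thetas=profile.thetas.copy(),
        condition=profile.condition,
        n_trials=profile.n_trials,
        repair_log=log,
    )


def smooth_timecourse(betas: np.ndarray, window: int = 2) -> np.ndarray:
    """Trailing moving average for display only; never feeds statistics."""
    if window < 1:
        raise ValueError("window must be >= 1")
    betas = np.asarray(betas, dtype=float)
    out = np.empty_like(betas)
    for i in range(len(betas)):
        out[i] = betas[max(0, i - window + 1) : i + 1].mean()
    return out


def profile_slope(profile: FeatureProfile | np.ndarray) -> float:
    """OLS slope of beta against theta (per degree).

    Accepts a :class:`FeatureProfile` or a bare length-81 beta array (for
    difference profiles such as valid minus invalid).
    """
    if isinstance(profile, FeatureProfile):
        betas, thetas = profile.betas, profile.thetas
    else:
        betas = np.asarray(profile, dtype=float)
        thetas = FEATURE_THETAS
    if not np.all(np.isfinite(betas)):
        raise ValueError("profile contains non-finite betas; repair first")
    return float(np.polyfit(thetas, betas, 1)[0])
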