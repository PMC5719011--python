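"""Simulated observers embodying candidate expectation mechanisms.

Three ways an expectation cue could change behaviour, each implemented as
a deterministic decision rule over the 30-frame orientation stream:

* **criterion shift** — the sensory evidence (the plain frame average) is
  untouched; the cue moves the decision criterion the average is compared
  against.
* **early weighting** — the cue boosts the gain of cue-congruent
  orientations in the first few frames (a change in the early sensory
  signal).
* **ambiguous bias** — orientations near vertical are displaced toward
  the cued direction before averaging (a change in ambiguous sensory
  signal), leaving unambiguous orientations essentially untouched.

All observers share the package sign convention: positive orientation =
clockwise = "right".  Ties at the criterion resolve to "left" so that
noise-free observers are fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .synthetic_data import orientation_matrix

__all__ = [
    "CriterionModelConfig",
    "EarlyWeightConfig",
    "AmbiguousBiasConfig",
    "respond_criterion_model",
    "respond_early_weighting",
    "transform_ambiguous",
    "respond_ambiguous_bias",
]


def _default_criteria() -> dict[tuple[str, str], float]:
    return {
        ("pre", "left"): 4.0,
        ("pre", "right"): -4.0,
        ("pre", "neutral"): 0.0,
        ("post", "left"): 6.0,
        ("post", "right"): -6.0,
        ("post", "neutral"): 0.0,
    }


@dataclass
class CriterionModelConfig:
    """Condition-specific decision criteria (degrees) for the frame average.

    A left cue raises the criterion (making "left" responses more likely),
    a right cue lowers it; neutral cues leave it at zero.  Defaults are
    +/-4 deg for pre cues and +/-6 deg for post cues.  ``internal_noise_sd``
    adds zero-mean Gaussian noise (degrees) to the frame average before
    the comparison; the default 0 gives a deterministic observer.
    """

    criterion_by_condition: dict[tuple[str, str], float] = field(
        default_factory=_default_criteria
    )
    internal_noise_sd: float = 0.0

    def __post_init__(self) -> None:
        for (bt, cue), crit in self.criterion_by_condition.items():
            if cue == "left" and crit < 0:
                raise ValueError(f"left-cue criterion must be >= 0, got {crit}")
            if cue == "right" and crit > 0:
                raise ValueError(f"right-cue criterion must be <= 0, got {crit}")
        if self.internal_noise_sd < 0:
            raise ValueError("internal_noise_sd must be >= 0")


@dataclass
class EarlyWeightConfig:
    """Early-frame over-weighting of cue-congruent evidence.

    Frame i (1-based) receives weight ``8 - i`` for i <= ``n_early`` and 1
    afterwards.  With ``congruent_only`` (the default) the boost applies
    only to frames whose orientation sign matches the cued direction
    (right cue <-> positive angle); a 0 deg frame carries no
    cue-consistent sign and keeps weight 1.  Neutral-cue trials use unit
    weights throughout.  ``normalize`` selects the aggregate: "weights"
    divides the weighted sum by the summed weights, "n" by the frame
    count.
    """

    n_early: int = 6
    congruent_only: bool = True
    normalize: str = "weights"

    def __post_init__(self) -> None:
        if not 0 < self.n_early < 8:
            raise ValueError("n_early must be in 1..7 so weights stay positive")
        if self.normalize not in ("weights", "n"):
            raise ValueError("normalize must be 'weights' or 'n'")

    def weight(self, frame: int) -> float:
        """Weight of 1-based frame index ``frame`` when congruent."""
        return float(8 - frame) if frame <= self.n_early else 1.0


@dataclass
class AmbiguousBiasConfig:
    """Cue-directed displacement of near-vertical orientations.

    An orientation theta becomes ``theta + s * phi(theta | mu, sigma^2)``
    for right cues (minus for left cues), where phi is the normal density.
    With the defaults (scale 240, mu 0, sigma 6) the displacement peaks at
    240 / (6 sqrt(2 pi)) ~= 15.96 deg at vertical and is negligible beyond
    ~25 deg.
    """

    scale: float = 240.0
    mu: float = 0.0
    sigma: float = 6.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")

    @property
    def max_displacement(self) -> float:
        """Largest possible displacement, attained at theta = mu."""
        return self.scale * norm.pdf(0.0, 0.0, self.sigma)


def _conditions(trials: pd.DataFrame) -> pd.DataFrame:
    need = {"block_type", "cue"}
    if not need <= set(trials.columns):
        raise ValueError(f"trial table lacks columns {need - set(trials.columns)}")
    return trials


def respond_criterion_model(
    trials: pd.DataFrame,
    config: CriterionModelConfig | None = None,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Respond by comparing the frame average to a condition criterion.

    Response is "right" iff mean(orientations) + noise strictly exceeds
    the criterion for the trial's (block_type, cue) condition; exact
    equality gives "left".  Raises KeyError-derived config errors when a
    trial's condition is missing from the criterion map.
    """
    config = config or CriterionModelConfig()
    _conditions(trials)
    means = orientation_matrix(trials).mean(axis=1)
    crit = np.empty(len(trials))
    for i, (bt, cue) in enumerate(zip(trials["block_type"], trials["cue"])):
        key = (bt, cue)
        if key not in config.criterion_by_condition:
            raise KeyError(f"no criterion configured for condition {key}")
        crit[i] = config.criterion_by_condition[key]
    if config.internal_noise_sd > 0:
        if rng is None:
            raise ValueError("internal noise requires an rng")
        means = means + rng.normal(0.0, config.internal_noise_sd, size=len(trials))
    return pd.Series(
        np.where(means > crit, "right", "left"), index=trials.index, dtype="string"
    )


def respond_early_weighting(
    trials: pd.DataFrame, config: EarlyWeightConfig | None = None
) -> pd.Series:
    """Respond from a weighted frame average with early congruent boost.

    On predictive-cue trials frame i <= n_early gets weight 8 - i when its
    orientation sign matches the cue, otherwise 1; the decision compares
    the weighted mean (sum(w * theta) / sum(w) by default) against 0.
    Neutral trials use the plain average.  Ties give "left".
    """
    config = config or EarlyWeightConfig()
    _conditions(trials)
    ori = orientation_matrix(trials)
    n_frames = ori.shape[1]
    base = np.ones(n_frames)
    early = np.arange(1, n_frames + 1) <= config.n_early
    boosted = np.where(early, 8.0 - np.arange(1, n_frames + 1), 1.0)
    cue_sign = trials["cue"].map({"left": -1.0, "right": 1.0, "neutral": 0.0}).to_numpy()
    w = np.ones_like(ori)
    predictive = cue_sign != 0
    if config.congruent_only:
        congruent = np.sign(ori) == cue_sign[:, None]
        w[predictive] = np.where(congruent[predictive], boosted, base)
    else:
        w[predictive] = boosted
    num = (w * ori).sum(axis=1)
    den = w.sum(axis=1) if config.normalize == "weights" else float(n_frames)
    evidence = num / den
    return pd.Series(
        np.where(evidence > 0, "right", "left"), index=trials.index, dtype="string"
    )


def transform_ambiguous(
    theta, cue: str, config: AmbiguousBiasConfig | None = None
):
    """Displace orientation(s) toward the cued direction near vertical.

    Returns ``theta + scale * phi(theta | mu, sigma^2)`` for right cues
    and ``theta - scale * phi(...)`` for left cues.  ``theta`` may be a
    scalar or array (degrees).
    """
    config = config or AmbiguousBiasConfig()
    if cue not in ("left", "right"):
        raise ValueError("transform applies to predictive cues only")
    sign = 1.0 if cue == "right" else -1.0
    theta = np.asarray(theta, dtype=float)
    out = theta + sign * config.scale * norm.pdf(theta, config.mu, config.sigma)
    return float(out) if out.ndim == 0 else out


def respond_ambiguous_bias(
    trials: pd.DataFrame, config: AmbiguousBiasConfig | None = None
) -> pd.Series:
    """Respond from the average of cue-displaced orientations.

    Predictive trials transform every frame with
    :func:`transform_ambiguous` and compare the transformed mean to 0;
    neutral trials compare the raw mean to 0.  Ties give "left".
    """
    config = config or AmbiguousBiasConfig()
    _conditions(trials)
    ori = orientation_matrix(trials)
    cue_sign = trials["cue"].map({"left": -1.0, "right": 1.0, "neutral": 0.0}).to_numpy()
    disp = config.scale * norm.pdf(ori, config.mu, config.sigma)
    transformed = ori + cue_sign[:, None] * disp
    evidence = transformed.mean(axis=1)
    return pd.Series(
        np.where(evidence > 0, "right", "left"), index=trials.index, dtype="string"
    )
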