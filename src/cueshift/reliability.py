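"""Split-half reliability of cue effects and attenuation-corrected ceilings.

A per-subject effect (typically the criterion shift delta_c) is
recomputed on the odd- and even-indexed trials of each subject; the
Pearson correlation of the two half-sample estimates across subjects is
the split-half reliability r_half.  The Spearman-Brown prophecy formula

    r_full = 2 r_half / (1 + r_half)

projects it to the reliability of the full-length measure, and the
correction for attenuation

    r_maximum = sqrt(r_measure1 * r_measure2)

bounds the correlation observable between two measures given their
reliabilities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, asdict
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

__all__ = [
    "ReliabilityReport",
    "split_half_effect",
    "spearman_brown",
    "attenuation_ceiling",
    "reliability_report",
]


@dataclass
class ReliabilityReport:
    r_half_pre: float
    r_half_post: float
    r_full_pre: float
    r_full_post: float
    r_maximum: float
    r_observed: float
    n_subjects: int

    def to_dict(self) -> dict:
        return asdict(self)


def split_half_effect(
    trials: pd.DataFrame,
    responses: pd.Series,
    effect: Callable[[pd.DataFrame, pd.Series], float],
) -> tuple[pd.Series, pd.Series, float]:
    """Recompute a per-subject effect on odd vs even trials and correlate.

    Trials are split by the parity of the within-subject presentation
    index (the ``trial`` column).  ``effect`` maps a subject's trial
    subset and aligned responses to a scalar; subjects on which it raises
    for either half are dropped with a warning.  Returns the odd-half
    values, even-half values (indexed by subject) and their Pearson
    correlation across subjects.
    """
    odd_vals: dict = {}
    even_vals: dict = {}
    for subject, sub in trials.groupby("subject"):
        resp = responses.loc[sub.index]
        odd_mask = (sub["trial"] % 2).astype(bool)
        try:
            odd = effect(sub[odd_mask], resp[odd_mask])
            even = effect(sub[~odd_mask], resp[~odd_mask])
        except Exception as exc:  # empty cell etc. -> exclude subject
            warnings.warn(
                f"subject {subject} excluded from split-half analysis: {exc}",
                stacklevel=2,
            )
            continue
        odd_vals[subject] = odd
        even_vals[subject] = even
    if len(odd_vals) < 3:
        raise ValueError(
            f"split-half reliability needs >= 3 usable subjects, got {len(odd_vals)}"
        )
    odd_s = pd.Series(odd_vals, name="odd")
    even_s = pd.Series(even_vals, name="even")
    r_half = float(pearsonr(odd_s, even_s).statistic)
    return odd_s, even_s, r_half


def spearman_brown(r_half: float) -> float:
    """Project a split-half reliability to full-length: 2r / (1 + r)."""
    if r_half <= -1.0:
        raise ValueError("spearman_brown undefined for r_half <= -1")
    return 2.0 * r_half / (1.0 + r_half)


def attenuation_ceiling(r1: float, r2: float) -> float:
    """Maximum observable correlation between two measures: sqrt(r1 * r2)."""
    if r1 < 0 or r2 < 0:
        raise ValueError("reliabilities must be non-negative")
    return math.sqrt(r1 * r2)


def reliability_report(
    trials: pd.DataFrame,
    responses: pd.Series,
    effect: Callable[[pd.DataFrame, pd.Series], float],
) -> ReliabilityReport:
    """Full reliability analysis of a cue effect across pre and post blocks.

    Computes the split-half reliability of ``effect`` separately on the
    pre- and post-cue blocks, applies the Spearman-Brown correction to
    each, derives the attenuation ceiling on the pre/post correlation,
    and compares it with the correlation actually observed between the
    full-sample pre and post effects.
    """
    halves = {}
    for bt in ("pre", "post"):
        mask = trials["block_type"] == bt
        _, _, r_half = split_half_effect(trials[mask], responses[mask], effect)
        halves[bt] = r_half
    r_full_pre = spearman_brown(halves["pre"])
    r_full_post = spearman_brown(halves["post"])
    r_max = attenuation_ceiling(max(r_full_pre, 0.0), max(r_full_post, 0.0))
    full = {}
    for bt in ("pre", "post"):
        mask = trials["block_type"] == bt
        vals = {}
        for subject, sub in trials[mask].groupby("subject"):
            vals[subject] = effect(sub, responses.loc[sub.index])
        full[bt] = pd.Series(vals)
    pre, post = full["pre"].align(full["post"], join="inner")
    r_obs = float(pearsonr(pre, post).statistic)
    return ReliabilityReport(
        r_half_pre=halves["pre"],
        r_half_post=halves["post"],
        r_full_pre=r_full_pre,
        r_full_post=r_full_post,
        r_maximum=r_max,
        r_observed=r_obs,
        n_subjects=int(len(pre)),
    )
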