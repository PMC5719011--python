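"""Display helpers for reverse-correlation profiles.

Smoothing here is cosmetic (trailing two-frame window on timecourses)
and is never applied before statistics.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .revcorr import FEATURE_THETAS, smooth_timecourse

__all__ = ["plot_signatures", "plot_feature_profiles"]


def plot_signatures(bundles: dict, path: str | Path) -> None:
    """One row per mechanism: smoothed temporal profile + feature profiles."""
    mechs = list(bundles)
    fig, axes = plt.subplots(len(mechs), 2, figsize=(9, 3 * len(mechs)), squeeze=False)
    for row, mech in enumerate(mechs):
        b = bundles[mech]
        ax = axes[row][0]
        frames = np.arange(1, len(b.temporal["predictive"].betas) + 1)
        for label, prof in b.temporal.items():
            ax.plot(frames, smooth_timecourse(prof.betas), label=label)
        ax.set_xlabel("frame")
        ax.set_ylabel("beta (per rad)")
        ax.set_title(f"{mech}: temporal usage")
        ax.legend(fontsize=7)
        ax = axes[row][1]
        for cue, prof in b.feature.items():
            ax.plot(FEATURE_THETAS, prof.betas, label=cue)
        ax.set_xlabel("orientation (deg)")
        ax.set_ylabel("beta (per count)")
        ax.set_title(f"{mech}: feature usage")
        ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_feature_profiles(mean_difference: dict, path: str | Path) -> None:
    """Valid-minus-invalid difference profiles for pre and post cues."""
    fig, ax = plt.subplots(figsize=(5, 3.5))
    for bt, betas in mean_difference.items():
        ax.plot(FEATURE_THETAS, betas, label=f"{bt} cues")
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("orientation (deg)")
    ax.set_ylabel("valid - invalid beta")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
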