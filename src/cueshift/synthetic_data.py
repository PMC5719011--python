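"""Synthetic cued-orientation experiments.

Generates trial sets with the statistical structure of a cued
orientation-averaging task: each trial shows a rapid stream of Gabor
patches whose orientations are drawn from a truncated normal
distribution centred left or right of vertical, preceded or followed by
a probabilistic cue.  Also provides the adaptive 2-down-1-up staircase
used to titrate the per-subject offset of the stimulus distribution.

Sign convention (global to the package): 0 degrees is vertical, positive
angles are clockwise and correspond to "right" stimuli and responses.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "StimulusParams",
    "CueScheduleParams",
    "StaircaseConfig",
    "StaircaseError",
    "sample_trial_orientations",
    "build_cue_schedule",
    "run_staircase",
    "generate_experiment",
    "write_trials",
    "read_trials",
    "orientation_columns",
    "orientation_matrix",
]

#: Mean and SD of the per-subject offset distribution produced by the
#: staircase in the original task (degrees from vertical).
GROUP_OFFSET_MEAN = 7.49
GROUP_OFFSET_SD = 3.85


@dataclass
class StimulusParams:
    """Parameters of the per-trial orientation stream.

    Each trial presents ``n_frames`` Gabor patches whose orientations are
    iid draws from a normal distribution with mean ``+offset_mean``
    (right/clockwise stimuli) or ``-offset_mean`` (left/counterclockwise
    stimuli) and standard deviation ``orientation_sd``, truncated by
    rejection to ``bounds``.
    """

    n_frames: int = 30
    frame_duration_ms: float = 16.7  # display metadata only
    orientation_sd: float = 22.5
    offset_mean: float = GROUP_OFFSET_MEAN
    bounds: tuple[float, float] = (-45.0, 45.0)

    def __post_init__(self) -> None:
        if self.n_frames <= 0:
            raise ValueError("n_frames must be a positive integer")
        if self.orientation_sd < 0:
            raise ValueError("orientation_sd must be >= 0")
        lo, hi = self.bounds
        if not lo < hi:
            raise ValueError("bounds must be an increasing interval")
        if abs(self.offset_mean) >= hi:
            raise ValueError("offset_mean magnitude must be below the upper bound")


@dataclass
class CueScheduleParams:
    """Cue/block structure of a session.

    Predictive cues point left or right and are valid (match the stimulus
    category) with probability ``validity``; a fraction
    ``neutral_fraction`` of trials instead carry an uninformative neutral
    cue.  Blocks alternate between pre-cue and post-cue type within each
    run, starting from ``first_block_type``.
    """

    validity: float = 2.0 / 3.0
    neutral_fraction: float = 0.25
    runs: int = 4
    blocks_per_run: int = 4
    trials_per_block: int = 30
    first_block_type: str = "pre"
    #: "bernoulli" draws neutral/valid status independently per trial;
    #: "exact" enforces the exact per-block counts instead.
    allocation: str = "bernoulli"

    def __post_init__(self) -> None:
        if not 0.5 < self.validity <= 1.0:
            raise ValueError("validity must lie in (0.5, 1]")
        if not 0.0 <= self.neutral_fraction < 1.0:
            raise ValueError("neutral_fraction must lie in [0, 1)")
        for name in ("runs", "blocks_per_run", "trials_per_block"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.first_block_type not in ("pre", "post"):
            raise ValueError("first_block_type must be 'pre' or 'post'")
        if self.allocation not in ("bernoulli", "exact"):
            raise ValueError("allocation must be 'bernoulli' or 'exact'")

    @property
    def n_trials(self) -> int:
        return self.runs * self.blocks_per_run * self.trials_per_block


@dataclass
class StaircaseConfig:
    """2-down-1-up staircase on the stimulus offset.

    The offset decreases after two consecutive correct responses and
    increases after every error, converging on ~70.7% accuracy.  The step
    size follows ``step_sizes`` indexed by the number of reversals so far
    (the last entry is reused once the schedule is exhausted).  The run
    stops after ``stop_reversals`` reversals and the threshold is the mean
    offset at the last ``threshold_reversals`` of them.
    """

    initial_offset: float = 20.0
    step_sizes: tuple[float, ...] = (8.0, 4.0, 2.0, 1.0)
    stop_reversals: int = 10
    threshold_reversals: int = 6
    max_trials: int = 2000
    offset_bounds: tuple[float, float] = (0.0, 40.0)

    def __post_init__(self) -> None:
        steps = tuple(float(s) for s in self.step_sizes)
        if not steps or any(s <= 0 for s in steps):
            raise ValueError("step sizes must be strictly positive")
        if list(steps) != sorted(steps, reverse=True):
            raise ValueError("step sizes must be non-increasing")
        if self.stop_reversals < self.threshold_reversals:
            raise ValueError("stop_reversals must be >= threshold_reversals")


class StaircaseError(RuntimeError):
    """Raised when the staircase fails to converge within ``max_trials``."""


ORI_COLUMNS_CACHE: dict[int, list[str]] = {}


def orientation_columns(n_frames: int = 30) -> list[str]:
    """Column names of the per-frame orientations in a trial table."""
    if n_frames not in ORI_COLUMNS_CACHE:
        ORI_COLUMNS_CACHE[n_frames] = [f"ori_{i:02d}" for i in range(1, n_frames + 1)]
    return ORI_COLUMNS_CACHE[n_frames]


def orientation_matrix(trials: pd.DataFrame) -> np.ndarray:
    """Return the (n_trials, n_frames) orientation array of a trial table."""
    cols = [c for c in trials.columns if c.startswith("ori_")]
    return trials[cols].to_numpy(dtype=float)


def sample_trial_orientations(
    category: str,
    params: StimulusParams,
    rng: np.random.Generator,
    size: int | None = None,
) -> np.ndarray:
    """Draw frame orientations for one trial (or ``size`` trials).

    Orientations come from N(mean, sd^2) with mean ``+offset_mean`` for
    "right" and ``-offset_mean`` for "left" stimuli, truncated to
    ``params.bounds`` by rejection: out-of-bounds draws are redrawn, so
    the boundary carries no probability mass.

    Returns a 1-D array of length ``n_frames``, or an array of shape
    (size, n_frames) when ``size`` is given.
    """
    if category not in ("left", "right"):
        raise ValueError(f"category must be 'left' or 'right', got {category!r}")
    mean = params.offset_mean if category == "right" else -params.offset_mean
    n = params.n_frames * (1 if size is None else size)
    lo, hi = params.bounds
    if params.orientation_sd == 0:
        out = np.full(n, mean)
    else:
        out = np.empty(n)
        filled = 0
        while filled < n:
            draws = rng.normal(mean, params.orientation_sd, size=n - filled)
            keep = draws[(draws >= lo) & (draws <= hi)]
            out[filled : filled + keep.size] = keep
            filled += keep.size
    if size is None:
        return out
    return out.reshape(size, params.n_frames)


def build_cue_schedule(
    params: CueScheduleParams, rng: np.random.Generator
) -> pd.DataFrame:
    """Lay out the per-trial cue/stimulus structure of one session.

    Cues are drawn first and the stimulus category conditionally on the
    cue (equal to the cue with probability ``validity``), which yields the
    stated cue-validity semantics and 50/50 stimulus marginals in
    expectation.  Neutral trials draw the category uniformly.

    Returns a DataFrame with columns trial, run, block, block_type, cue,
    stim, valid (boolean, NA for neutral cues).
    """
    rows = []
    trial = 0
    order = ("pre", "post") if params.first_block_type == "pre" else ("post", "pre")
    for run in range(1, params.runs + 1):
        for block in range(1, params.blocks_per_run + 1):
            block_type = order[(block - 1) % 2]
            nt = params.trials_per_block
            if params.allocation == "exact":
                n_neutral = round(params.neutral_fraction * nt)
                neutral_mask = np.zeros(nt, dtype=bool)
                neutral_mask[rng.permutation(nt)[:n_neutral]] = True
                n_pred = nt - n_neutral
                n_valid = round(params.validity * n_pred)
                valid_pool = np.zeros(n_pred, dtype=bool)
                valid_pool[rng.permutation(n_pred)[:n_valid]] = True
            else:
                neutral_mask = rng.random(nt) < params.neutral_fraction
                valid_pool = None
            pred_i = 0
            for t in range(nt):
                if neutral_mask[t]:
                    cue = "neutral"
                    stim = "right" if rng.random() < 0.5 else "left"
                    valid = pd.NA
                else:
                    cue = "right" if rng.random() < 0.5 else "left"
                    if valid_pool is None:
                        is_valid = rng.random() < params.validity
                    else:
                        is_valid = bool(valid_pool[pred_i])
                        pred_i += 1
                    stim = cue if is_valid else ("left" if cue == "right" else "right")
                    valid = bool(is_valid)
                rows.append(
                    {
                        "trial": trial,
                        "run": run,
                        "block": block,
                        "block_type": block_type,
                        "cue": cue,
                        "stim": stim,
                        "valid": valid,
                    }
                )
                trial += 1
    df = pd.DataFrame(rows)
    df["valid"] = df["valid"].astype("boolean")
    return df


def run_staircase(
    observer: Callable[[np.ndarray], str],
    config: StaircaseConfig,
    stim: StimulusParams,
    rng: np.random.Generator,
    history: list | None = None,
) -> float:
    """Estimate a threshold offset with a 2-down-1-up staircase.

    ``observer`` maps an orientation stream (degrees) to a response
    ("left"/"right").  Each staircase trial draws a random category,
    samples a stream at the current offset, and scores the observer's
    response.  Two consecutive correct responses shrink the offset by the
    current step, each error grows it; the tested offset at every
    direction reversal is recorded and the step size advances along
    ``config.step_sizes``.

    Returns the mean offset over the last ``threshold_reversals``
    reversals.  Raises :class:`StaircaseError` if ``max_trials`` is
    exceeded before ``stop_reversals`` reversals occur.  When ``history``
    is a list, the offset tested on each trial is appended to it.
    """
    offset = float(config.initial_offset)
    lo, hi = config.offset_bounds
    if hi >= stim.bounds[1]:
        raise ValueError("offset ceiling must stay below the stimulus bound")
    reversals: list[float] = []
    n_correct_streak = 0
    last_direction = 0  # +1 offset moving up, -1 moving down
    for _ in range(config.max_trials):
        if history is not None:
            history.append(offset)
        category = "right" if rng.random() < 0.5 else "left"
        trial_params = StimulusParams(
            n_frames=stim.n_frames,
            frame_duration_ms=stim.frame_duration_ms,
            orientation_sd=stim.orientation_sd,
            offset_mean=offset,
            bounds=stim.bounds,
        )
        orientations = sample_trial_orientations(category, trial_params, rng)
        correct = observer(orientations) == category
        step = config.step_sizes[min(len(reversals), len(config.step_sizes) - 1)]
        direction = 0
        if correct:
            n_correct_streak += 1
            if n_correct_streak == 2:
                n_correct_streak = 0
                direction = -1
        else:
            n_correct_streak = 0
            direction = +1
        if direction != 0:
            if last_direction != 0 and direction != last_direction:
                reversals.append(offset)
                if len(reversals) >= config.stop_reversals:
                    return float(np.mean(reversals[-config.threshold_reversals :]))
                step = config.step_sizes[min(len(reversals), len(config.step_sizes) - 1)]
            last_direction = direction
            offset = float(np.clip(offset + direction * step, lo, hi))
    raise StaircaseError(
        f"staircase did not reach {config.stop_reversals} reversals "
        f"within {config.max_trials} trials"
    )


def _subject_offset(rng: np.random.Generator, hi: float) -> float:
    """Draw a per-subject offset from the group distribution, truncated to (0, hi)."""
    while True:
        x = rng.normal(GROUP_OFFSET_MEAN, GROUP_OFFSET_SD)
        if 0.0 < x < hi:
            return x


def generate_experiment(
    stim: StimulusParams | None = None,
    cues: CueScheduleParams | None = None,
    n_subjects: int = 1,
    seed: int | np.random.SeedSequence = 0,
    subject_offsets: Sequence[float] | None = None,
) -> pd.DataFrame:
    """Generate a complete multi-subject trial table.

    Each subject receives an independent RNG stream spawned from ``seed``
    and, unless ``subject_offsets`` is given, an offset drawn from the
    group distribution N(7.49, 3.85^2) truncated to (0, upper bound).
    Half the subjects start with a pre-cue block, half with a post-cue
    block.  Orientations are rounded to 4 decimal places, the precision
    of the CSV dialect, so that a write/read round trip is an identity.

    Returns a DataFrame with one row per trial:
    subject, trial, run, block, block_type, cue, stim, valid, response
    (empty), and ori_01..ori_{n_frames}.
    """
    stim = stim or StimulusParams()
    cues = cues or CueScheduleParams()
    root = (
        seed
        if isinstance(seed, np.random.SeedSequence)
        else np.random.SeedSequence(seed)
    )
    streams = root.spawn(n_subjects)
    frames = []
    offsets_used: dict[int, float] = {}
    ori_cols = orientation_columns(stim.n_frames)
    for s, ss in enumerate(streams, start=1):
        rng = np.random.default_rng(ss)
        if subject_offsets is not None:
            offset = float(subject_offsets[s - 1])
        else:
            offset = _subject_offset(rng, stim.bounds[1])
        offsets_used[s] = offset
        sub_stim = StimulusParams(
            n_frames=stim.n_frames,
            frame_duration_ms=stim.frame_duration_ms,
            orientation_sd=stim.orientation_sd,
            offset_mean=offset,
            bounds=stim.bounds,
        )
        sub_cues = CueScheduleParams(
            validity=cues.validity,
            neutral_fraction=cues.neutral_fraction,
            runs=cues.runs,
            blocks_per_run=cues.blocks_per_run,
            trials_per_block=cues.trials_per_block,
            first_block_type="pre" if s % 2 == 1 else "post",
            allocation=cues.allocation,
        )
        schedule = build_cue_schedule(sub_cues, rng)
        ori = np.empty((len(schedule), stim.n_frames))
        for i, cat in enumerate(schedule["stim"]):
            ori[i] = sample_trial_orientations(cat, sub_stim, rng)
        ori = np.round(ori, 4)
        df = schedule.copy()
        df.insert(0, "subject", s)
        df["response"] = pd.array([pd.NA] * len(df), dtype="string")
        df[ori_cols] = ori
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    out.attrs["subject_offsets"] = offsets_used  # not serialised to CSV
    return out


# ---------------------------------------------------------------------------
# Trial CSV dialect
# ---------------------------------------------------------------------------

def write_trials(trials: pd.DataFrame, path) -> None:
    """Write a trial table in the package's CSV dialect.

    Header ``subject,trial,run,block,block_type,cue,stim,valid,response,
    ori_01,...``; valid is 1/0/NA, response may be empty, orientations
    carry 4 decimal places; UTF-8, LF line endings.
    """
    df = trials.copy()
    valid = df["valid"].astype("boolean")
    df["valid"] = valid.map({True: "1", False: "0"}, na_action="ignore").fillna("NA")
    if "response" in df:
        df["response"] = df["response"].fillna("")
    ori_cols = [c for c in df.columns if c.startswith("ori_")]
    for c in ori_cols:
        df[c] = df[c].map(lambda v: f"{v:.4f}")
    df.to_csv(path, index=False, lineterminator="\n", encoding="utf-8")


def read_trials(path) -> pd.DataFrame:
    """Read a trial table written by :func:`write_trials`."""
    df = pd.read_csv(path, dtype={"valid": "string", "response": "string"})
    df["valid"] = df["valid"].map({"1": True, "0": False}).astype("boolean")
    resp = df["response"]
    df["response"] = resp.where(resp.notna() & (resp != ""), pd.NA).astype("string")
    return df


def trials_digest(trials: pd.DataFrame) -> str:
    """Stable content hash of a trial table (used to stamp reports)."""
    h = hashlib.sha256()
    h.update(trials.to_csv(index=False, lineterminator="\n").encode())
    return h.hexdigest()[:16]
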