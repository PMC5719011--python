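"""End-to-end study orchestration.

Ties the generator, observers and analysis chain together:

* :func:`run_signature_simulations` — large single-"subject" simulations
  of the three candidate expectation mechanisms, analysed by temporal and
  feature reverse correlation to expose each mechanism's signature
  (L-shaped temporal profile for early weighting, central deflection for
  ambiguous bias, flat vertical offset for a criterion shift).
* :func:`run_criterion_model_experiment` — the deterministic
  criterion-shift model (pre +/-4 deg, post +/-6 deg, neutral 0 deg) run on a
  multi-subject trial set, with the full 10-condition feature analysis,
  degenerate-fit repair and subject exclusion.
* :func:`run_full_analysis` — synthetic experiment -> simulated responses
  -> SDT -> cue effects -> reverse correlation -> reliability, bundled
  into one reproducible report.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import observers, revcorr, sdt
from .reliability import ReliabilityReport, reliability_report
from .synthetic_data import (
    CueScheduleParams,
    StaircaseConfig,
    StimulusParams,
    generate_experiment,
    orientation_columns,
    sample_trial_orientations,
    write_trials,
)

__all__ = [
    "ObserverSettings",
    "StudyConfig",
    "SignatureBundle",
    "CriterionModelResult",
    "delta_c_effect",
    "simulate_cued_trials",
    "run_signature_simulations",
    "run_criterion_model_experiment",
    "run_full_analysis",
]

log = logging.getLogger("cueshift")

IDENTITY_CONDITIONS = [
    (bt, cue) for bt in ("pre", "post") for cue in ("left", "right", "neutral")
]
VALIDITY_CONDITIONS = [(bt, v) for bt in ("pre", "post") for v in (True, False)]


@dataclass
class ObserverSettings:
    """Observer used for the full study replica.

    ``model`` picks the mechanism; for the criterion model,
    ``pre_criterion``/``post_criterion`` are the unsigned criterion
    magnitudes (degrees).  Each subject's magnitudes are jittered around
    those bases by a *shared* latent component with SD
    ``criterion_jitter_sd`` (one draw per subject, applied to both pre
    and post — subjects who shift more do so for both cue times, so the
    pre and post effects correlate across subjects) plus an independent
    per-cue-time component with SD ``criterion_unique_sd``.
    ``internal_noise_sd`` adds trial-level Gaussian noise (degrees) to
    the frame average, giving a non-degenerate psychometric function.
    """

    model: str = "criterion"
    pre_criterion: float = 4.0
    post_criterion: float = 6.0
    internal_noise_sd: float = 10.0
    criterion_jitter_sd: float = 2.0
    criterion_unique_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.model not in ("criterion", "early", "ambiguous"):
            raise ValueError("model must be criterion|early|ambiguous")


@dataclass
class StudyConfig:
    """Everything needed to regenerate a full study replica."""

    stimulus: StimulusParams = field(default_factory=StimulusParams)
    cues: CueScheduleParams = field(default_factory=CueScheduleParams)
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    observer: ObserverSettings = field(default_factory=ObserverSettings)
    n_subjects: int = 30
    seed: int = 0
    #: a subject is dropped from the model experiment when more than this
    #: many of its 486 identity-condition feature fits are degenerate
    max_degenerate_fits: int = 5
    sim_trials_per_cue: int = 100_000

    def to_dict(self) -> dict:
        d = asdict(self)
        d["stimulus"]["bounds"] = list(self.stimulus.bounds)
        d["staircase"]["step_sizes"] = list(self.staircase.step_sizes)
        d["staircase"]["offset_bounds"] = list(self.staircase.offset_bounds)
        return d

    def digest(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "StudyConfig":
        d = dict(d)
        stim = d.pop("stimulus", {})
        cues = d.pop("cues", {})
        stair = d.pop("staircase", {})
        obs = d.pop("observer", {})
        if "bounds" in stim:
            stim["bounds"] = tuple(stim["bounds"])
        if "step_sizes" in stair:
            stair["step_sizes"] = tuple(stair["step_sizes"])
        if "offset_bounds" in stair:
            stair["offset_bounds"] = tuple(stair["offset_bounds"])
        return cls(
            stimulus=StimulusParams(**stim),
            cues=CueScheduleParams(**cues),
            staircase=StaircaseConfig(**stair),
            observer=ObserverSettings(**obs),
            **d,
        )

    @classmethod
    def from_yaml(cls, path) -> "StudyConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


def delta_c_effect(trials: pd.DataFrame, responses: pd.Series) -> float:
    """Per-subset criterion shift: c under left cues minus c under right cues."""
    cs = {}
    for cue in ("left", "right"):
        m = (trials["cue"] == cue).to_numpy()
        rates = sdt.compute_rates(
            trials.loc[m, "stim"], responses[m], condition=f"cue={cue}"
        )
        cs[cue] = sdt.dprime_criterion(rates).criterion_c
    return cs["left"] - cs["right"]


def simulate_cued_trials(
    n_per_cue: int,
    stim: StimulusParams | None = None,
    validity: float = 2.0 / 3.0,
    seed: int | np.random.SeedSequence = 0,
    block_type: str = "pre",
) -> pd.DataFrame:
    """Flat trial set with ``n_per_cue`` trials per cue identity.

    Used by the signature simulations, which need many trials per cue
    rather than the blocked session structure.  Predictive cues match the
    stimulus category with probability ``validity``; neutral trials draw
    the category uniformly.
    """
    stim = stim or StimulusParams()
    rng = np.random.default_rng(seed)
    cues: list[str] = []
    stims: list[str] = []
    for cue in ("left", "right", "neutral"):
        for _ in range(n_per_cue):
            if cue == "neutral":
                s = "right" if rng.random() < 0.5 else "left"
            else:
                s = cue if rng.random() < validity else (
                    "left" if cue == "right" else "right"
                )
            cues.append(cue)
            stims.append(s)
    cue_arr = np.array(cues)
    stim_arr = np.array(stims)
    n = len(stim_arr)
    ori = np.empty((n, stim.n_frames))
    for cat in ("left", "right"):
        m = stim_arr == cat
        ori[m] = sample_trial_orientations(cat, stim, rng, size=int(m.sum()))
    df = pd.DataFrame(
        {
            "subject": 1,
            "trial": np.arange(n),
            "run": 1,
            "block": 1,
            "block_type": block_type,
            "cue": cue_arr,
            "stim": stim_arr,
            "valid": pd.array(
                [pd.NA if c == "neutral" else (c == s) for c, s in zip(cues, stims)],
                dtype="boolean",
            ),
        }
    )
    df[orientation_columns(stim.n_frames)] = ori
    return df


@dataclass
class SignatureBundle:
    """Reverse-correlation signatures of one simulated mechanism."""

    mechanism: str
    temporal: dict  # {"predictive": TemporalProfile, "neutral": TemporalProfile}
    feature: dict  # {"left"|"right"|"neutral": FeatureProfile}
    n_trials_per_cue: int


def _respond(mechanism: str, trials: pd.DataFrame) -> pd.Series:
    if mechanism == "criterion":
        cfg = observers.CriterionModelConfig(
            criterion_by_condition={
                ("pre", "left"): 4.0,
                ("pre", "right"): -4.0,
                ("pre", "neutral"): 0.0,
            }
        )
        return observers.respond_criterion_model(trials, cfg)
    if mechanism == "early":
        return observers.respond_early_weighting(trials)
    if mechanism == "ambiguous":
        return observers.respond_ambiguous_bias(trials)
    raise ValueError(f"unknown mechanism {mechanism!r}")


def run_signature_simulations(
    n_per_cue: int = 100_000,
    stim: StimulusParams | None = None,
    seed: int = 0,
    mechanisms: tuple[str, ...] = ("early", "ambiguous", "criterion"),
) -> dict[str, SignatureBundle]:
    """Simulate each mechanism and extract its reverse-correlation signature.

    One large cued trial set is generated and shared across mechanisms
    (the mechanisms differ only in their decision rule, so responding to
    common stimuli is statistically equivalent and cheaper).  For each
    mechanism the temporal profile is fit separately for predictive
    (left+right pooled) and neutral cues, and the feature profile for
    each cue identity.
    """
    trials = simulate_cued_trials(n_per_cue, stim=stim, seed=seed)
    predictive = (trials["cue"] != "neutral").to_numpy()
    out: dict[str, SignatureBundle] = {}
    for mech in mechanisms:
        log.info("signature simulation: %s (%d trials/cue)", mech, n_per_cue)
        resp = _respond(mech, trials)
        temporal = {
            "predictive": revcorr.temporal_revcorr(
                trials[predictive], resp[predictive], condition=f"{mech}/predictive"
            ),
            "neutral": revcorr.temporal_revcorr(
                trials[~predictive], resp[~predictive], condition=f"{mech}/neutral"
            ),
        }
        feature = {}
        for cue in ("left", "right", "neutral"):
            m = (trials["cue"] == cue).to_numpy()
            feature[cue] = revcorr.feature_revcorr(
                trials[m], resp[m], condition=f"{mech}/{cue}"
            )
        out[mech] = SignatureBundle(
            mechanism=mech, temporal=temporal, feature=feature,
            n_trials_per_cue=n_per_cue,
        )
    return out


@dataclass
class CriterionModelResult:
    """Output of the criterion-shift model experiment."""

    profiles: dict  # (subject, condition label) -> FeatureProfile
    retained_subjects: list
    excluded_subjects: list
    degenerate_counts: dict  # subject -> degenerate identity-condition fits
    slopes: pd.DataFrame  # per subject x block_type valid-invalid slope
    mean_difference: dict  # block_type -> mean valid-invalid beta profile (81,)
    n_regressions: int

    @property
    def n_input_subjects(self) -> int:
        return len(self.retained_subjects) + len(self.excluded_subjects)


def _condition_label(bt: str, key) -> str:
    if isinstance(key, bool):
        return f"{bt}/{'valid' if key else 'invalid'}"
    return f"{bt}/{key}"


def run_criterion_model_experiment(
    trials: pd.DataFrame,
    config: observers.CriterionModelConfig | None = None,
    responses: pd.Series | None = None,
    max_degenerate_fits: int = 5,
) -> CriterionModelResult:
    """Run the criterion-shift model and the full feature analysis.

    The deterministic criterion model responds to every trial (unless
    ``responses`` are supplied); per subject, feature reverse correlation
    is fit for the 6 cue-identity conditions (pre/post x
    left/right/neutral) and the 4 validity conditions (pre/post x
    valid/invalid) — 810 regressions per subject.  Subjects with more
    than ``max_degenerate_fits`` degenerate identity-condition fits are
    excluded; remaining degenerate betas are repaired from neighbouring
    orientations.  Emits per-subject valid-minus-invalid difference
    profiles and their slopes.
    """
    config = config or observers.CriterionModelConfig()
    if responses is None:
        responses = observers.respond_criterion_model(trials, config)
    profiles: dict = {}
    degenerate: dict = {}
    excluded: list = []
    retained: list = []
    slope_rows = []
    n_regressions = 0
    for subject, sub in trials.groupby("subject"):
        resp = responses.loc[sub.index]
        sub_profiles = {}
        n_bad = 0
        for bt, cue in IDENTITY_CONDITIONS:
            m = ((sub["block_type"] == bt) & (sub["cue"] == cue)).to_numpy()
            prof = revcorr.feature_revcorr(
                sub[m], resp[m], condition=f"s{subject}/{bt}/{cue}"
            )
            n_regressions += prof.n_regressions
            n_bad += int(prof.flagged.sum())
            sub_profiles[_condition_label(bt, cue)] = prof
        for bt, v in VALIDITY_CONDITIONS:
            m = (
                (sub["block_type"] == bt)
                & (sub["valid"].fillna(False) == v)
                & (sub["cue"] != "neutral")
            ).to_numpy()
            prof = revcorr.feature_revcorr(
                sub[m], resp[m], condition=_condition_label(bt, v) + f"/s{subject}"
            )
            n_regressions += prof.n_regressions
            sub_profiles[_condition_label(bt, v)] = prof
        degenerate[subject] = n_bad
        if n_bad > max_degenerate_fits:
            excluded.append(subject)
            log.info(
                "subject %s excluded: %d degenerate identity-condition fits "
                "(threshold %d)", subject, n_bad, max_degenerate_fits,
            )
            continue
        retained.append(subject)
        for key, prof in sub_profiles.items():
            profiles[(subject, key)] = prof
        for bt in ("pre", "post"):
            diff = (
                sub_profiles[f"{bt}/valid"].betas
                - sub_profiles[f"{bt}/invalid"].betas
            )
            slope_rows.append(
                {
                    "subject": subject,
                    "block_type": bt,
                    "slope": revcorr.profile_slope(diff),
                }
            )
    slopes = pd.DataFrame(slope_rows)
    mean_diff = {}
    for bt in ("pre", "post"):
        diffs = [
            profiles[(s, f"{bt}/valid")].betas - profiles[(s, f"{bt}/invalid")].betas
            for s in retained
        ]
        mean_diff[bt] = np.mean(diffs, axis=0) if diffs else np.full(81, np.nan)
    return CriterionModelResult(
        profiles=profiles,
        retained_subjects=retained,
        excluded_subjects=excluded,
        degenerate_counts=degenerate,
        slopes=slopes,
        mean_difference=mean_diff,
        n_regressions=n_regressions,
    )


def _study_responses(
    trials: pd.DataFrame, settings: ObserverSettings, seed: np.random.SeedSequence
) -> pd.Series:
    """Simulate study responses with per-subject criteria and internal noise."""
    if settings.model == "early":
        return observers.respond_early_weighting(trials)
    if settings.model == "ambiguous":
        return observers.respond_ambiguous_bias(trials)
    parts = []
    subjects = sorted(trials["subject"].unique())
    streams = seed.spawn(len(subjects))
    for subject, ss in zip(subjects, streams):
        rng = np.random.default_rng(ss)
        shared = rng.normal(0, settings.criterion_jitter_sd)
        pre = max(
            0.0,
            settings.pre_criterion
            + shared
            + rng.normal(0, settings.criterion_unique_sd),
        )
        post = max(
            0.0,
            settings.post_criterion
            + shared
            + rng.normal(0, settings.criterion_unique_sd),
        )
        cfg = observers.CriterionModelConfig(
            criterion_by_condition={
                ("pre", "left"): pre,
                ("pre", "right"): -pre,
                ("pre", "neutral"): 0.0,
                ("post", "left"): post,
                ("post", "right"): -post,
                ("post", "neutral"): 0.0,
            },
            internal_noise_sd=settings.internal_noise_sd,
        )
        sub = trials[trials["subject"] == subject]
        parts.append(observers.respond_criterion_model(sub, cfg, rng))
    return pd.concat(parts)


def run_full_analysis(
    config: StudyConfig | None = None, outdir: str | Path | None = None
) -> dict:
    """Generate, simulate, and analyse a complete study replica.

    Stages: synthetic experiment -> simulated responses -> SDT per
    condition -> cue effects -> temporal reverse correlation (predictive
    vs neutral, pre and post) -> feature reverse correlation (the full
    10-condition analysis with repair and exclusion) -> reliability
    report.  Returns a JSON-serialisable report; when ``outdir`` is given
    the trial CSV, metrics CSVs and report JSON are written there.
    """
    config = config or StudyConfig()
    root = np.random.SeedSequence(config.seed)
    gen_seed, resp_seed = root.spawn(2)
    stage = "generate"
    try:
        trials = generate_experiment(
            config.stimulus, config.cues, config.n_subjects, seed=gen_seed
        )
        log.info("generated %d trials for %d subjects", len(trials), config.n_subjects)
        stage = "respond"
        responses = _study_responses(trials, config.observer, resp_seed)
        stage = "sdt"
        metrics = sdt.sdt_by_condition(trials, responses)
        effects = sdt.condition_effects(metrics, validity=config.cues.validity)
        stage = "temporal reverse correlation"
        temporal_rows = []
        n_temporal = 0
        for subject, sub in trials.groupby("subject"):
            resp = responses.loc[sub.index]
            for bt in ("pre", "post"):
                for label, mask in (
                    ("predictive", (sub["block_type"] == bt) & (sub["cue"] != "neutral")),
                    ("neutral", (sub["block_type"] == bt) & (sub["cue"] == "neutral")),
                ):
                    m = mask.to_numpy()
                    prof = revcorr.temporal_revcorr(
                        sub[m], resp[m], condition=f"s{subject}/{bt}/{label}"
                    )
                    n_temporal += len(prof.betas)
                    temporal_rows.append(
                        {
                            "subject": subject,
                            "block_type": bt,
                            "cue_class": label,
                            "mean_beta": float(np.nanmean(prof.betas[~prof.flagged]))
                            if (~prof.flagged).any()
                            else np.nan,
                            "betas": prof.betas.tolist(),
                        }
                    )
        temporal_df = pd.DataFrame(temporal_rows)
        stage = "feature reverse correlation"
        model_result = run_criterion_model_experiment(
            trials,
            responses=responses,
            max_degenerate_fits=config.max_degenerate_fits,
        )
        stage = "reliability"
        rel = reliability_report(trials, responses, delta_c_effect)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    mean_effects = (
        effects.groupby("block_type")[["delta_c", "delta_dprime", "delta_c_optimal"]]
        .mean()
        .to_dict(orient="index")
    )
    pooled_temporal = {
        label: float(
            temporal_df.loc[temporal_df["cue_class"] == label, "mean_beta"].mean()
        )
        for label in ("predictive", "neutral")
    }
    slopes = model_result.slopes.groupby("block_type")["slope"].mean().to_dict()
    report = {
        "seed": config.seed,
        "config_digest": config.digest(),
        "config": config.to_dict(),
        "n_subjects": config.n_subjects,
        "n_trials": int(len(trials)),
        "mean_effects": mean_effects,
        "mean_temporal_beta": pooled_temporal,
        "valid_minus_invalid_slope": slopes,
        "reliability": rel.to_dict(),
        "n_feature_regressions": model_result.n_regressions,
        "n_temporal_regressions": n_temporal,
        "excluded_subjects": model_result.excluded_subjects,
        "retained_subjects": model_result.retained_subjects,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_trials(trials.assign(response=responses), outdir / "trials.csv")
        metrics.to_csv(outdir / "sdt_metrics.csv", index=False)
        effects.to_csv(outdir / "cue_effects.csv", index=False)
        model_result.slopes.to_csv(outdir / "validity_slopes.csv", index=False)
        temporal_df.drop(columns="betas").to_csv(
            outdir / "temporal_usage.csv", index=False
        )
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=2, default=float)
        log.info("report written to %s", outdir)
    return report
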