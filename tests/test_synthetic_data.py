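"""Stimulus generator, cue schedule, staircase, and trial CSV round trip."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import truncnorm

from cueshift.synthetic_data import (
    CueScheduleParams,
    StaircaseConfig,
    StaircaseError,
    StimulusParams,
    build_cue_schedule,
    generate_experiment,
    orientation_matrix,
    read_trials,
    run_staircase,
    sample_trial_orientations,
    write_trials,
)


class TestStimulus:
    def test_zero_variance_collapses_to_offset(self, rng):
        p = StimulusParams(orientation_sd=0.0, offset_mean=7.49)
        assert np.array_equal(
            sample_trial_orientations("right", p, rng), np.full(30, 7.49)
        )
        assert np.array_equal(
            sample_trial_orientations("left", p, rng), np.full(30, -7.49)
        )

    def test_rejection_sampling_never_leaks_bounds(self, rng):
        p = StimulusParams()
        draws = sample_trial_orientations("right", p, rng, size=40_000)  # 1.2e6 values
        assert draws.min() >= -45.0 and draws.max() <= 45.0

    def test_matches_truncated_normal_mean(self, rng):
        # oracle: closed-form truncated-normal mean on [-45, 45]
        p = StimulusParams(offset_mean=7.49)
        a = (-45.0 - 7.49) / 22.5
        b = (45.0 - 7.49) / 22.5
        expected = truncnorm.mean(a, b, loc=7.49, scale=22.5)
        draws = sample_trial_orientations("right", p, rng, size=4000)  # 1.2e5 values
        assert abs(draws.mean() - expected) < 0.1

    def test_left_category_mirrors_right(self, rng):
        p = StimulusParams()
        left = sample_trial_orientations("left", p, rng, size=3000)
        assert left.mean() < 0

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_frames": 0},
            {"orientation_sd": -1.0},
            {"offset_mean": 50.0},
            {"bounds": (10.0, -10.0)},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            StimulusParams(**kwargs)

    def test_unknown_category_rejected(self, rng):
        with pytest.raises(ValueError):
            sample_trial_orientations("up", StimulusParams(), rng)


class TestCueSchedule:
    def test_session_structure(self, rng):
        sched = build_cue_schedule(CueScheduleParams(), rng)
        assert len(sched) == 480
        blocks = sched.groupby(["run", "block"])["block_type"].agg(["first", "nunique", "size"])
        assert (blocks["nunique"] == 1).all()
        assert (blocks["size"] == 30).all()
        types = sched.drop_duplicates(["run", "block"])["block_type"]
        assert (types == "pre").sum() == 8 and (types == "post").sum() == 8

    def test_blocks_alternate_within_runs(self, rng):
        sched = build_cue_schedule(CueScheduleParams(first_block_type="post"), rng)
        for _, run in sched.drop_duplicates(["run", "block"]).groupby("run"):
            seq = run.sort_values("block")["block_type"].tolist()
            assert seq == ["post", "pre", "post", "pre"]

    def test_valid_flag_is_cue_stim_agreement(self, rng):
        sched = build_cue_schedule(CueScheduleParams(), rng)
        pred = sched[sched["cue"] != "neutral"]
        assert (pred["valid"] == (pred["cue"] == pred["stim"])).all()
        assert sched.loc[sched["cue"] == "neutral", "valid"].isna().all()

    def test_neutral_count_within_binomial_bound(self, rng):
        sched = build_cue_schedule(CueScheduleParams(), rng)
        n, p = 480, 0.25
        sigma = np.sqrt(n * p * (1 - p))
        assert abs((sched["cue"] == "neutral").sum() - n * p) <= 3 * sigma

    def test_full_validity_means_every_predictive_trial_valid(self, rng):
        sched = build_cue_schedule(CueScheduleParams(validity=1.0), rng)
        pred = sched[sched["cue"] != "neutral"]
        assert pred["valid"].all()

    def test_empirical_validity_within_binomial_bound(self, rng):
        # ~10^4 trials
        params = CueScheduleParams(runs=84)
        sched = build_cue_schedule(params, rng)
        pred = sched[sched["cue"] != "neutral"]
        k, n = int(pred["valid"].sum()), len(pred)
        p = params.validity
        assert abs(k - n * p) <= 3 * np.sqrt(n * p * (1 - p))

    def test_exact_allocation_enforces_per_block_counts(self, rng):
        params = CueScheduleParams(allocation="exact")
        sched = build_cue_schedule(params, rng)
        per_block = sched.groupby(["run", "block"]).apply(
            lambda b: (b["cue"] == "neutral").sum(), include_groups=False
        )
        assert (per_block == round(0.25 * 30)).all()
        pred = sched[sched["cue"] != "neutral"]
        per_block_valid = pred.groupby(["run", "block"])["valid"].mean()
        # 15 of 22-23 predictive trials valid -> ratio near 2/3 in every block
        assert ((per_block_valid - 2 / 3).abs() < 0.05).all()

    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            CueScheduleParams(validity=0.5)
        with pytest.raises(ValueError):
            CueScheduleParams(neutral_fraction=1.0)
        with pytest.raises(ValueError):
            CueScheduleParams(first_block_type="mid")


class TestStaircase:
    def test_always_correct_descends_to_floor(self, rng):
        cfg = StaircaseConfig()
        stim = StimulusParams(orientation_sd=0.0)

        def oracle(ori):
            return "right" if ori.mean() > 0 else "left"

        threshold = run_staircase(oracle, cfg, stim, rng)
        # an infallible observer drives the offset to the floor; the only
        # upward moves are the reversal bounces of size <= max step
        assert threshold < 2 * max(cfg.step_sizes)

    def test_always_incorrect_climbs_to_ceiling(self, rng):
        # a systematically wrong observer drives the offset monotonically
        # up; with no direction change there is never a reversal
        cfg = StaircaseConfig(max_trials=200)
        history = []
        with pytest.raises(StaircaseError):
            run_staircase(
                lambda ori: "right" if ori.mean() <= 0 else "left",
                cfg,
                StimulusParams(orientation_sd=0.0),
                rng,
                history=history,
            )
        assert all(b >= a for a, b in zip(history, history[1:]))
        assert history[-1] == cfg.offset_bounds[1]

    def test_nonconvergence_raises(self, rng):
        cfg = StaircaseConfig(max_trials=5)
        with pytest.raises(StaircaseError):
            run_staircase(lambda ori: "right", cfg, StimulusParams(), rng)

    def test_threshold_matches_accuracy_sweep_oracle(self, rng):
        """2-down-1-up converges near the ~70.7%-correct offset."""
        noise_sd = 5.0
        stim = StimulusParams(orientation_sd=22.5)

        def make_observer(r):
            return lambda ori: "right" if ori.mean() + r.normal(0, noise_sd) > 0 else "left"

        # oracle: brute-force accuracy sweep over offsets
        sweep_rng = np.random.default_rng(777)
        offsets = np.arange(0.5, 16.1, 0.5)
        acc = []
        for off in offsets:
            p = StimulusParams(orientation_sd=22.5, offset_mean=off)
            ok = 0
            n = 3000
            for cat in ("left", "right"):
                draws = sample_trial_orientations(cat, p, sweep_rng, size=n // 2)
                means = draws.mean(axis=1) + sweep_rng.normal(0, noise_sd, n // 2)
                resp_right = means > 0
                ok += int((resp_right == (cat == "right")).sum())
            acc.append(ok / n)
        target = float(np.interp(0.707, acc, offsets))

        thresholds = [
            run_staircase(
                make_observer(np.random.default_rng(1000 + i)),
                StaircaseConfig(max_trials=5000),
                stim,
                np.random.default_rng(2000 + i),
            )
            for i in range(12)
        ]
        assert abs(np.mean(thresholds) - target) < 2.0


class TestExperiment:
    def test_single_subject_has_480_rows(self):
        trials = generate_experiment(n_subjects=1, seed=5)
        assert len(trials) == 480

    def test_identical_seeds_are_bit_identical(self):
        a = generate_experiment(n_subjects=2, seed=9)
        b = generate_experiment(n_subjects=2, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_different_seeds_differ(self):
        a = generate_experiment(n_subjects=1, seed=9)
        b = generate_experiment(n_subjects=1, seed=10)
        assert not np.array_equal(orientation_matrix(a), orientation_matrix(b))

    def test_subject_offsets_track_group_distribution(self):
        n = 30
        trials = generate_experiment(n_subjects=n, seed=17)
        offsets = np.array(
            [trials.attrs["subject_offsets"][s] for s in range(1, n + 1)]
        )
        se = 3.85 / np.sqrt(n)
        assert abs(offsets.mean() - 7.49) < 3 * se

    def test_csv_round_trip_is_identity(self, tmp_path):
        trials = generate_experiment(n_subjects=1, seed=3)
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        back = read_trials(path)
        pd.testing.assert_frame_equal(
            back, trials.reset_index(drop=True), check_dtype=False
        )

    def test_csv_dialect_header_and_format(self, tmp_path):
        trials = generate_experiment(n_subjects=1, seed=3)
        path = tmp_path / "trials.csv"
        write_trials(trials, path)
        text = path.read_text()
        header = text.splitlines()[0]
        assert header.startswith(
            "subject,trial,run,block,block_type,cue,stim,valid,response,ori_01"
        )
        assert header.endswith("ori_30")
        first = text.splitlines()[1].split(",")
        assert first[7] in {"1", "0", "NA"}
        assert "." in first[9] and len(first[9].split(".")[1]) == 4
        assert "\r" not in text
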