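"""Borg interpolation, aggregation, normalization and dataset assembly."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from stsfatigue.dataset_builder import (
    ALL_FEATURE_IDS,
    BuildConfig,
    DegenerateBaselineError,
    InsufficientCyclesError,
    aggregate_hr,
    assign_cycles,
    build_dataset,
    class_summary,
    interpolate_borg,
    label_fatigue,
    normalize,
    select_nearest_cycles,
)
from stsfatigue.io_core import BorgReport, HeartRateSeries


STANDARD_REPORTS = tuple(
    BorgReport(time=t, value=v)
    for t, v in ((30, 2), (60, 4), (90, 7), (120, 10))
)


class TestInterpolateBorg:
    def test_complete_session_has_13_grid_values(self):
        grid = interpolate_borg(STANDARD_REPORTS, duration=120)
        assert len(grid) == 13
        np.testing.assert_array_equal(grid.times, np.arange(0, 121, 10))

    def test_starts_at_assumed_zero(self):
        grid = interpolate_borg(STANDARD_REPORTS, duration=120)
        assert grid.values[0] == 0.0

    def test_linear_segment_through_origin(self):
        grid = interpolate_borg(STANDARD_REPORTS, duration=120)
        # line through (0,0) and (30,2) evaluated at t=10
        assert grid.values[1] == pytest.approx(2 / 3, abs=1e-12)

    def test_report_beyond_duration_rejected(self):
        with pytest.raises(ValueError, match="beyond"):
            interpolate_borg(STANDARD_REPORTS, duration=90)


class TestLabelFatigue:
    @pytest.mark.parametrize(
        "value, label",
        [(0, "LF"), (3, "LF"), (3.4, "LF"), (3.5, "MF"), (5, "MF"),
         (6.4, "MF"), (6.5, "HF"), (7, "HF"), (10, "HF")],
    )
    def test_banding_with_round_half_up(self, value, label):
        assert label_fatigue(value) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            label_fatigue(10.5)

    @given(st.floats(min_value=0, max_value=10))
    def test_label_matches_integer_banding_of_rounded_value(self, value):
        import math

        rounded = math.floor(value + 0.5)
        expected = "LF" if rounded <= 3 else "MF" if rounded <= 6 else "HF"
        assert label_fatigue(value) == expected


class TestNearestSelection:
    def test_nearest_five_with_earlier_tiebreak(self):
        mid_times = np.arange(1.0, 11.0)  # 1..10 s at indices 0..9
        # the five nearest to t=5 are the cycles at 3..7 s
        assert select_nearest_cycles(mid_times, target=5.0, k=5) == [
            2, 3, 4, 5, 6,
        ]
        # a genuine tie (k=2 around 5 -> 5 plus one of {4, 6}) goes earlier
        assert select_nearest_cycles(mid_times, target=5.0, k=2) == [3, 4]

    def test_target_before_first_cycle_takes_first_k(self):
        mid_times = np.arange(1.0, 11.0)
        assert select_nearest_cycles(mid_times, target=0.0, k=5) == [
            0, 1, 2, 3, 4,
        ]

    def test_used_cycles_excluded_and_shortage_raises(self):
        mid_times = np.arange(1.0, 9.0)
        used = {0, 1, 2, 3}
        with pytest.raises(InsufficientCyclesError):
            select_nearest_cycles(mid_times, 4.0, k=5, already_used=used)

    def test_reuse_allows_previously_used_cycles(self):
        mid_times = np.arange(1.0, 7.0)
        chosen = select_nearest_cycles(
            mid_times, 6.0, k=5, already_used=set(range(6)), allow_reuse=True
        )
        assert chosen == [1, 2, 3, 4, 5]


class TestAggregateHR:
    @staticmethod
    def _series(times, bpm):
        return HeartRateSeries(times=times, bpm=bpm, resting_bpm=60.0)

    def test_constant_series_returns_constant(self):
        hr = self._series(np.arange(120.0), np.full(120, 100.0))
        assert aggregate_hr(hr, target=37.3) == 100.0

    def test_identity_series_returns_target(self):
        t = np.arange(1.0, 121.0)
        hr = self._series(t, t)  # bpm equals time
        assert aggregate_hr(hr, target=60.0, k=5) == pytest.approx(60.0)

    def test_too_few_samples_raise(self):
        hr = self._series(np.arange(3.0) + 1, np.array([80.0, 81, 82]))
        with pytest.raises(InsufficientCyclesError):
            aggregate_hr(hr, target=1.0, k=5)


class TestNormalize:
    def test_self_normalization_is_exactly_one(self):
        assert normalize(1.2, 1.2) == 1.0

    def test_exact_ratio(self):
        assert normalize(2.4, 1.2) == 2.0

    def test_zero_baseline_rejected_naming_feature(self):
        with pytest.raises(DegenerateBaselineError, match="F9"):
            normalize(1.0, 0.0, name="F9")


class TestBuildDataset:
    def test_single_complete_session_yields_11_registers(self, noisy_session):
        session, _ = noisy_session
        dataset = build_dataset([session])
        assert len(dataset) == 11
        assert all(len(r.features) == 33 for r in dataset.registers)
        np.testing.assert_array_equal(
            [r.borg_time for r in dataset.registers], np.arange(10, 111, 10)
        )

    def test_early_terminated_session_yields_grid_minus_two(self, participant):
        from stsfatigue.synthgen import SynthConfig, generate_session

        config = SynthConfig(
            seed=3, duration=60.0,
            borg_schedule=((30.0, 5.0), (60.0, 10.0)),
        ).noiseless()
        session, _ = generate_session(config, participant, seed=3)
        dataset = build_dataset([session])
        assert len(dataset) == 5  # grid 0..60 by 10, minus baseline and final

    def test_no_cycle_reused_across_non_final_timepoints(self, noisy_session):
        from stsfatigue.features import extract_cycle_features
        from stsfatigue.segmentation import segment_session

        session, _ = noisy_session
        seg = segment_session(session)
        mids = np.array(
            [f.mid_time for f in extract_cycle_features(session, seg)]
        )
        grid = interpolate_borg(session.borg, session.duration)
        assignments = assign_cycles(mids, grid.times, k=5)
        non_final = [i for group in assignments[:-1] for i in group]
        assert len(non_final) == len(set(non_final))
        assert len(assignments) == len(grid) - 1

    def test_baseline_self_normalization_is_exactly_one(self, noisy_session):
        from stsfatigue.features import FEATURE_IDS, extract_cycle_features
        from stsfatigue.segmentation import segment_session

        session, _ = noisy_session
        seg = segment_session(session)
        feats = extract_cycle_features(session, seg)
        mids = np.array([f.mid_time for f in feats])
        grid = interpolate_borg(session.borg, session.duration)
        baseline_idx = assign_cycles(mids, grid.times, k=5)[0]
        matrix = np.array(
            [[f.values[fid] for fid in FEATURE_IDS] for f in feats]
        )
        baseline = matrix[baseline_idx].mean(axis=0)
        assert all(normalize(b, b) == 1.0 for b in baseline)

    def test_session_with_borg_10_covers_all_three_labels(self, noisy_session):
        session, _ = noisy_session
        labels = {r.label for r in build_dataset([session]).registers}
        assert labels == {"LF", "MF", "HF"}

    def test_resting_hr_baseline_option(self, noisy_session):
        session, _ = noisy_session
        t0 = build_dataset([session], BuildConfig(hr_baseline="t0"))
        resting = build_dataset([session], BuildConfig(hr_baseline="resting"))
        ratio = session.heart_rate.resting_bpm
        f33_t0 = np.array([r.features["F33"] for r in t0.registers])
        f33_rest = np.array([r.features["F33"] for r in resting.registers])
        assert (f33_rest >= f33_t0).all()  # resting HR is the lower baseline


class TestClassSummary:
    def test_constant_feature_has_mean_one_sd_zero(self):
        from stsfatigue.dataset_builder import FatigueDataset, Register

        dataset = FatigueDataset()
        for i, label in enumerate(["LF", "MF", "HF"] * 3):
            dataset.registers.append(
                Register(
                    participant_id="P000",
                    borg_time=10.0 * (i + 1),
                    borg_value=float(i),
                    features={fid: 1.0 for fid in ALL_FEATURE_IDS},
                    label=label,
                )
            )
        summary = class_summary(dataset)
        assert summary.shape == (33, 6)
        for label in ("LF", "MF", "HF"):
            assert summary.loc["F1", (label, "mean")] == 1.0
            assert summary.loc["F1", (label, "sd")] == 0.0

    def test_single_register_dataset_marks_missing_classes(self, noisy_session):
        session, _ = noisy_session
        dataset = build_dataset([session])
        dataset.registers = [dataset.registers[0]]  # an LF register
        summary = class_summary(dataset)
        label = dataset.registers[0].label
        assert summary.loc["F1", (label, "sd")] == 0.0
        other = [lab for lab in ("LF", "MF", "HF") if lab != label]
        assert summary[other].isna().all().all()

    def test_register_count_is_grid_length_minus_two(self, default_cohort):
        sessions = [s for s, _ in default_cohort][:5]
        dataset = build_dataset(sessions)
        grid = interpolate_borg(sessions[0].borg, sessions[0].duration)
        assert len(dataset) == 5 * (len(grid) - 2)
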