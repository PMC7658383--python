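import numpy as np
import pytest

from copgait import (
    ChannelStats,
    EmptyDatasetError,
    GaitStep,
    ParameterError,
    PlantarStream,
    SensorStream,
    WindowSpec,
    build_samples,
    compute_stats,
    mean_step_period,
    standardize,
    training_frame_budget,
)
from copgait.windowing import WindowedDataset, expected_sample_count


def constant_setup(n=400, value=0.0, sites=("H", "L", "T", "W")):
    sensors = {
        s: SensorStream(s, 148.0, np.full((n, 6), value, dtype=float)) for s in sites
    }
    cop = np.linspace(0, 17.48, n)
    plantar = PlantarStream(148.0, np.full(n, 500.0), cop, cop * 0.05)
    return sensors, plantar


class TestWindowSpec:
    def test_full_universe_feature_dim_is_24(self):
        assert WindowSpec(10, ("H", "L", "T", "W")).feature_dim == 24

    def test_sites_normalized_to_canonical_order(self):
        assert WindowSpec(10, ("T", "H")).sites == ("H", "T")

    @pytest.mark.parametrize("kwargs", [dict(lookback_frames=0, sites=("H",)),
                                        dict(lookback_frames=5, sites=()),
                                        dict(lookback_frames=5, sites=("X",))])
    def test_invalid_spec_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            WindowSpec(**kwargs)


class TestMeanStepPeriod:
    def test_two_step_mean(self):
        steps = [GaitStep(0, 100, 160), GaitStep(160, 260, 326)]
        assert mean_step_period(steps) == 163

    def test_singleton(self):
        assert mean_step_period([GaitStep(0, 100, 148)]) == 148

    def test_zero_jitter_generator_cycle(self, zero_jitter_session):
        steps = zero_jitter_session.truth_steps
        assert mean_step_period(steps) == 163

    def test_no_successor_rejected(self):
        with pytest.raises(ParameterError):
            mean_step_period([GaitStep(0, 100, None)])


class TestBuildSamples:
    def test_one_full_history_step_gives_stance_count_samples(self):
        sensors, plantar = constant_setup()
        step = GaitStep(200, 320, None)  # 120 stance frames, history ≥ P
        ds = build_samples(sensors, plantar, [step], WindowSpec(150, ("T",)))
        assert len(ds) == 120

    def test_full_subset_has_24_columns(self):
        sensors, plantar = constant_setup()
        step = GaitStep(200, 260, None)
        ds = build_samples(sensors, plantar, [step], WindowSpec(150, ("H", "L", "T", "W")))
        assert ds.x.shape[2] == 24

    def test_constant_channels_give_constant_windows(self):
        sensors, plantar = constant_setup(value=3.5)
        step = GaitStep(200, 230, None)
        ds = build_samples(sensors, plantar, [step], WindowSpec(50, ("H", "T")))
        assert np.array_equal(ds.x, np.full_like(ds.x, 3.5))

    def test_insufficient_history_skipped(self):
        sensors, plantar = constant_setup()
        step = GaitStep(100, 220, None)  # with P=150, frames 100..149 lack history
        ds = build_samples(sensors, plantar, [step], WindowSpec(150, ("T",)))
        assert len(ds) == 220 - 150
        assert ds.frame_idx.min() == 150

    def test_all_frames_lack_history_raises(self):
        sensors, plantar = constant_setup()
        step = GaitStep(10, 60, None)
        with pytest.raises(EmptyDatasetError):
            build_samples(sensors, plantar, [step], WindowSpec(300, ("T",)))

    @pytest.mark.parametrize("P", [30, 150, 250])
    def test_count_matches_brute_force_enumerator(self, P, small_session):
        steps = small_session.truth_steps[:4]
        ds = build_samples(
            small_session.sensors, small_session.plantar, steps, WindowSpec(P, ("T",))
        )
        # brute-force enumeration of eligible (step, frame) pairs
        expected = sum(
            1
            for step in steps
            for t in range(step.hs_frame, step.to_frame)
            if t - P >= 0
        )
        assert len(ds) == expected
        assert expected == expected_sample_count(steps, P, len(small_session.plantar))


def test_dataset_dump_round_trip(tmp_path, rng):
    spec = WindowSpec(8, ("H", "T"))
    ds = WindowedDataset(
        rng.normal(size=(10, 8, 12)).astype(np.float32),
        rng.normal(size=10).astype(np.float32),
        np.zeros(10, np.int64),
        np.arange(10),
        spec,
    )
    ds.save(tmp_path / "windows")
    back = WindowedDataset.load(tmp_path / "windows")
    assert np.array_equal(back.x, ds.x)
    assert np.array_equal(back.y, ds.y)
    assert back.spec == spec


class TestStandardize:
    def make_ds(self, x):
        spec = WindowSpec(x.shape[1], ("T",))
        return WindowedDataset(
            x.astype(np.float32),
            np.zeros(len(x), np.float32),
            np.zeros(len(x), np.int64),
            np.arange(len(x)),
            spec,
        )

    def test_direct_formula(self):
        stats = ChannelStats(mean=np.full(6, 2.0), sd=np.full(6, 4.0))
        ds = self.make_ds(np.full((3, 5, 6), 6.0))
        out = standardize(ds, stats)
        assert np.allclose(out.x, 1.0)

    def test_training_moments_near_standard(self, rng):
        ds = self.make_ds(rng.normal(3.0, 2.0, size=(50, 8, 6)))
        out = standardize(ds, compute_stats(ds))
        flat = out.x.reshape(-1, 6).astype(np.float64)
        assert np.allclose(flat.mean(0), 0.0, atol=1e-6)
        assert np.allclose(flat.std(0), 1.0, atol=1e-6)

    def test_reapplication_with_same_stats_changes_values(self, rng):
        ds = self.make_ds(rng.normal(3.0, 2.0, size=(20, 8, 6)))
        stats = compute_stats(ds)
        once = standardize(ds, stats)
        twice = standardize(once, stats)
        assert not np.allclose(once.x, twice.x)

    def test_zero_sd_channel_centered_with_warning(self, rng):
        x = rng.normal(size=(20, 8, 6))
        x[:, :, 2] = 7.0
        ds = self.make_ds(x)
        with pytest.warns(UserWarning, match="constant channel"):
            out = standardize(ds, compute_stats(ds))
        assert np.allclose(out.x[:, :, 2], 0.0, atol=1e-6)


class TestSizing:
    def test_study_training_matrix_rows(self):
        assert training_frame_budget() == 38_332

    def test_split_has_no_step_leakage(self, small_session):
        from copgait import split_steps

        steps = small_session.truth_steps
        plan = split_steps(steps, 0.7, seed=1)
        spec = WindowSpec(150, ("T",))
        tr = build_samples(
            small_session.sensors,
            small_session.plantar,
            [steps[i] for i in plan.train_steps],
            spec,
        )
        te = build_samples(
            small_session.sensors,
            small_session.plantar,
            [steps[i] for i in plan.test_steps],
            spec,
        )
        assert set(tr.frame_idx) & set(te.frame_idx) == set()
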