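import numpy as np
import pytest

from copgait import (
    GaitParams,
    GaitStep,
    ParameterError,
    PlantarStream,
    UndefinedCOPError,
    clean_swing_noise,
    compute_cop_centroid,
    detect_gait_events,
    generate_session,
    split_steps,
    synchronize,
    trim_steps,
)


def plantar_from_grf(grf, rate=148.0):
    grf = np.asarray(grf, dtype=float)
    cop = np.where(grf > 0, 1.0, np.nan)
    return PlantarStream(rate, grf, cop, cop)


class TestSynchronize:
    @pytest.mark.parametrize("lag", [0, 17, -23])
    def test_recovers_constructed_lag(self, lag):
        sess = generate_session(GaitParams(n_steps=3, seed=4, lag_frames=lag))
        _, _, recovered = synchronize(sess.sensors, sess.plantar)
        assert recovered == lag

    def test_alignment_restores_stomp_coincidence(self):
        sess = generate_session(GaitParams(n_steps=3, seed=4, lag_frames=21))
        aligned, plantar, _ = synchronize(sess.sensors, sess.plantar)
        pre = sess.truth_steps[0].hs_frame
        heel = aligned["H"].accel_magnitude()[:pre]
        assert np.argmax(heel) == np.argmax(plantar.grf_n[:pre])


class TestCleanSwingNoise:
    def test_rule_on_constructed_series(self):
        p = plantar_from_grf([0, 4, 12, 30, 8, 0])
        out = clean_swing_noise(p, 10.0)
        assert np.array_equal(out.grf_n, [0, 0, 12, 30, 0, 0])
        assert np.isnan(out.cop_ap_cm[[1, 4]]).all()

    def test_all_zero_fixed_point(self):
        p = plantar_from_grf(np.zeros(10))
        out = clean_swing_noise(p, 10.0)
        assert np.array_equal(out.grf_n, p.grf_n)

    def test_idempotent(self):
        p = plantar_from_grf([0, 4, 12, 30, 8, 0])
        once = clean_swing_noise(p, 10.0)
        twice = clean_swing_noise(once, 10.0)
        assert np.array_equal(once.grf_n, twice.grf_n)


class TestDetectGaitEvents:
    def test_triangular_pulse_matches_brute_force_scan(self):
        # GRF rises 0→600 N over frames 100–160 and falls back over 160–220
        grf = np.zeros(300)
        grf[100:161] = np.linspace(0, 600, 61)
        grf[160:221] = np.linspace(600, 0, 61)
        p = plantar_from_grf(grf)
        cleaned = clean_swing_noise(p, 10.0)
        steps = detect_gait_events(cleaned)
        # independent brute-force scan of the constructed ramp
        supra = np.flatnonzero(cleaned.grf_n > 0)
        hs_expect = next(i for i in supra if grf[i] >= 10)
        peak = int(np.argmax(grf))
        to_expect = next(i for i in range(peak, 300) if cleaned.grf_n[i] < 25)
        assert len(steps) == 1
        assert steps[0].hs_frame == hs_expect
        assert steps[0].to_frame == to_expect

    def test_no_contact_gives_empty_list(self):
        assert detect_gait_events(plantar_from_grf(np.zeros(50))) == []

    def test_detection_matches_generator_truth(self, zero_jitter_session):
        sess = zero_jitter_session
        cleaned = clean_swing_noise(sess.plantar, 10.0)
        steps = detect_gait_events(cleaned)
        assert [(s.hs_frame, s.to_frame) for s in steps] == [
            (s.hs_frame, s.to_frame) for s in sess.truth_steps
        ]
        # successor links agree too
        assert [s.next_hs_frame for s in steps] == [
            s.next_hs_frame for s in sess.truth_steps
        ]

    def test_short_artifacts_discarded(self):
        grf = np.zeros(200)
        grf[50:55] = 400.0  # 5-frame spike ≪ 0.3 s minimum stance
        steps = detect_gait_events(plantar_from_grf(grf))
        assert steps == []


def make_steps(n, start=0, stance=100, cycle=160):
    steps = []
    for i in range(n):
        hs = start + i * cycle
        steps.append(GaitStep(hs, hs + stance, hs + cycle if i < n - 1 else None))
    return steps


class TestTrimSteps:
    def test_single_trip_arithmetic(self):
        assert len(trim_steps(make_steps(40))) == 34

    def test_degenerate_trip_warns_and_empties(self):
        with pytest.warns(UserWarning, match="discarded"):
            assert trim_steps(make_steps(6)) == []

    def test_two_trips_additive(self):
        trip1 = make_steps(40)
        trip2 = make_steps(40, start=10_000)
        kept = trim_steps(trip1 + trip2, trip_boundaries=[9_000])
        assert len(kept) == 68

    def test_keeps_interior_steps(self):
        steps = make_steps(10)
        kept = trim_steps(steps)
        assert kept == steps[3:7]


class TestSplitSteps:
    def test_study_split_counts(self):
        plan = split_steps(make_steps(74), 0.7, seed=0)
        assert len(plan.train_steps) == 52
        assert len(plan.test_steps) == 22

    def test_deterministic_under_seed(self):
        steps = make_steps(20)
        assert split_steps(steps, 0.7, seed=5) == split_steps(steps, 0.7, seed=5)

    @pytest.mark.parametrize("seed", range(5))
    def test_partition_property(self, seed):
        n = 31
        plan = split_steps(make_steps(n), 0.7, seed=seed)
        train, test = set(plan.train_steps), set(plan.test_steps)
        assert train | test == set(range(n))
        assert train & test == set()

    def test_invalid_fraction_rejected(self):
        with pytest.raises(ParameterError):
            split_steps(make_steps(10), 1.5, seed=0)


class TestCopCentroid:
    def test_point_load(self):
        assert compute_cop_centroid([5.0], [3.0], [1.0]) == (3.0, 1.0)

    def test_symmetry(self):
        ap, _ = compute_cop_centroid([2.0, 2.0], [0.0, 10.0], [0.0, 0.0])
        assert ap == pytest.approx(5.0)

    def test_weighted_mean(self):
        ap, _ = compute_cop_centroid([1.0, 2.0, 3.0], [0.0, 1.0, 2.0], [0, 0, 0])
        assert ap == pytest.approx((0 + 2 + 6) / 6)

    def test_zero_load_undefined(self):
        with pytest.raises(UndefinedCOPError):
            compute_cop_centroid([0.0, 0.0], [0.0, 1.0], [0.0, 1.0])
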