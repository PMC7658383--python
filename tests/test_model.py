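import numpy as np
import pytest

from copgait import (
    GaitParams,
    ModelConfig,
    ParameterError,
    TrainedModel,
    WindowSpec,
    build_samples,
    clean_swing_noise,
    compute_stats,
    detect_gait_events,
    generate_session,
    predict,
    predict_trajectory,
    standardize,
    train,
)
from copgait.windowing import WindowedDataset


def make_dataset(rng, n=200, P=12, F=6, target="linear"):
    spec = WindowSpec(lookback_frames=P, sites=("T",), direction="AP")
    X = rng.standard_normal((n, P, F)).astype(np.float32)
    if target == "linear":
        w = rng.standard_normal((P, F)).astype(np.float32) / np.sqrt(P * F)
        y = (X * w).sum(axis=(1, 2))
    elif target == "smooth":
        w = rng.standard_normal((P, F)).astype(np.float32) / np.sqrt(P * F)
        y = (X * w).sum(axis=(1, 2)) + 0.3 * np.tanh(X[:, -1, 0])
    else:  # zero
        y = np.zeros(n, dtype=np.float32)
    return WindowedDataset(
        X, y.astype(np.float32), np.zeros(n, np.int64), np.arange(n), spec
    )


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [dict(epochs=0), dict(batch_size=0), dict(dropout_rate=1.0),
         dict(hidden_sizes=()), dict(learning_rate=0.0)],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            ModelConfig(**kwargs)

    def test_defaults_follow_protocol(self):
        cfg = ModelConfig()
        assert cfg.hidden_sizes == (64, 128, 64)
        assert cfg.epochs == 20
        assert cfg.batch_size == 148


class TestTraining:
    def test_learns_linear_functional(self, rng):
        # noise-free linear target; threshold frozen from a pilot run
        ds = make_dataset(rng, n=500, target="linear")
        cfg = ModelConfig(
            hidden_sizes=(16, 16), dropout_rate=0.0, epochs=60, batch_size=32,
            learning_rate=5e-3, seed=0,
        )
        m = train(ds, cfg)
        y_range = ds.y.max() - ds.y.min()
        assert m.training_history[-1] < 0.05 * y_range

    def test_capacity_overfits_small_set(self, rng):
        # full-width network drives training RMSE below 10% of range
        ds = make_dataset(rng, n=200, target="smooth")
        cfg = ModelConfig(
            dropout_rate=0.0, epochs=20, batch_size=16, learning_rate=5e-3, seed=0
        )
        m = train(ds, cfg)
        assert len(m.training_history) == cfg.epochs
        assert m.training_history[-1] < 0.10 * (ds.y.max() - ds.y.min())

    def test_seeded_determinism(self, rng):
        ds = make_dataset(rng, n=60)
        cfg = ModelConfig(hidden_sizes=(8, 8), epochs=3, batch_size=16, seed=7)
        h1 = train(ds, cfg).training_history
        h2 = train(ds, cfg).training_history
        assert h1 == h2

    def test_zero_target_predicts_near_zero(self, rng):
        ds = make_dataset(rng, n=120, target="zero")
        cfg = ModelConfig(hidden_sizes=(8, 8), dropout_rate=0.0, epochs=10,
                          batch_size=16, seed=0)
        m = train(ds, cfg)
        preds = predict(m, ds)
        assert np.max(np.abs(preds)) < 0.1

    def test_feature_dim_mismatch_rejected(self, rng):
        ds = make_dataset(rng, n=20)
        bad = WindowedDataset(
            ds.x[:, :, :4], ds.y, ds.step_idx, ds.frame_idx, ds.spec
        )
        with pytest.raises(ParameterError):
            train(bad, ModelConfig(hidden_sizes=(4,), epochs=1, batch_size=8))

    def test_save_load_round_trip(self, rng, tmp_path):
        ds = make_dataset(rng, n=40)
        cfg = ModelConfig(hidden_sizes=(6, 6), epochs=2, batch_size=16, seed=3)
        m = train(ds, cfg, channel_stats=compute_stats(ds))
        m.save(tmp_path / "model.npz")
        back = TrainedModel.load(tmp_path / "model.npz")
        assert np.array_equal(predict(m, ds), predict(back, ds))
        assert back.training_history == m.training_history


@pytest.fixture(scope="module")
def tiny_fitted():
    """A quickly-trained model on a short deterministic session."""
    params = GaitParams(
        n_steps=6, seed=5, lag_frames=0, stance_frames_sd=0.0, step_scale_sd=0.0
    )
    sess = generate_session(params)
    cleaned = clean_swing_noise(sess.plantar, 10.0)
    steps = detect_gait_events(cleaned)
    spec = WindowSpec(lookback_frames=163, sites=("T",), direction="AP")
    ds = build_samples(sess.sensors, cleaned, steps[:4], spec)
    stats = compute_stats(ds)
    cfg = ModelConfig(epochs=1, seed=0)
    model = train(standardize(ds, stats), cfg, channel_stats=stats)
    return sess, cleaned, steps, model


class TestPredictTrajectory:
    def test_output_covers_every_stance_frame(self, tiny_fitted):
        sess, cleaned, steps, model = tiny_fitted
        step = steps[4]
        frames, preds = predict_trajectory(model, sess.sensors, cleaned, step)
        assert len(preds) == step.stance_frames == 120
        assert frames[0] == step.hs_frame and frames[-1] == step.to_frame - 1

    def test_causality_future_frames_do_not_matter(self, tiny_fitted):
        sess, cleaned, steps, model = tiny_fitted
        step = steps[4]
        frames, before = predict_trajectory(model, sess.sensors, cleaned, step)
        t_cut = step.hs_frame + 60
        perturbed = {}
        for site, s in sess.sensors.items():
            data = s.data.copy()
            data[t_cut:] += 100.0  # gross future perturbation
            perturbed[site] = type(s)(site=site, sample_rate_hz=s.sample_rate_hz, data=data)
        _, after = predict_trajectory(model, perturbed, cleaned, step)
        k = t_cut - step.hs_frame
        assert np.array_equal(before[:k + 1], after[:k + 1])
        assert not np.array_equal(before[k + 1:], after[k + 1:])

    def test_incompatible_spec_rejected(self, tiny_fitted):
        sess, cleaned, steps, model = tiny_fitted
        with pytest.raises(ParameterError):
            predict_trajectory(
                model, sess.sensors, cleaned, steps[4],
                WindowSpec(lookback_frames=50, sites=("T",)),
            )
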