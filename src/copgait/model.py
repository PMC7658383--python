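"""Recurrent COP regressor: stacked LSTM, RMSprop, RMSE loss.

The network maps a lookback window of standardized IMU frames to one
COP value (many-to-one).  Architecture: three LSTM layers of 64/128/64
units, a dropout layer between the last recurrent layer and a single
linear output unit.  Training minimizes the batch root-mean-square
error with RMSprop for 20 epochs at batch size 148 (one second of
frames at the 148 Hz rate).

The implementation is self-contained numpy: time-major layout, a
contiguous sigmoid gate block per step (SIMD-friendly), full
backpropagation through time, and float32 arithmetic.  Targets are
z-scored internally during training and mapped back to cm at
prediction time; the RMSE loss gradient is scale-free, so optimizing
in standardized target units is what makes the configured learning
rate meaningful.

One trained model predicts one direction (AP or ML); the two
directions are independent single-output models.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .exceptions import (
    DivergenceError,
    EmptyDatasetError,
    ParameterError,
)
from .io import PlantarStream, SensorStream
from .preprocess import GaitStep
from .windowing import ChannelStats, WindowedDataset, WindowSpec, build_samples, standardize

# gate layout within the 4H axis: [ i | f | o | g ]
# (three sigmoid gates contiguous, tanh candidate last)


@dataclass(frozen=True)
class ModelConfig:
    """Hyperparameters of the COP regressor.

    Defaults follow the study protocol (64/128/64 units, 20 epochs,
    batch 148, RMSprop with RMSE loss); dropout rate and learning rate
    are conventional defaults and overridable.
    """

    hidden_sizes: tuple[int, ...] = (64, 128, 64)
    dropout_rate: float = 0.2
    epochs: int = 20
    batch_size: int = 148
    learning_rate: float = 1e-3
    rho: float = 0.9
    epsilon: float = 1e-7
    shuffle: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hidden_sizes or any(h < 1 for h in self.hidden_sizes):
            raise ParameterError("hidden_sizes must be positive")
        if not 0 <= self.dropout_rate < 1:
            raise ParameterError("dropout_rate must be in [0, 1)")
        if self.epochs < 1:
            raise ParameterError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ParameterError("batch_size must be >= 1")
        if self.learning_rate <= 0:
            raise ParameterError("learning_rate must be > 0")
        object.__setattr__(self, "hidden_sizes", tuple(int(h) for h in self.hidden_sizes))


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((n, n)))
    return (q * np.sign(np.diag(r))).astype(np.float32)


def _init_params(
    rng: np.random.Generator, feature_dim: int, hidden_sizes: tuple[int, ...]
) -> list[dict[str, np.ndarray]]:
    params = []
    fin = feature_dim
    for h in hidden_sizes:
        lim = np.sqrt(6.0 / (fin + 4 * h))
        W = rng.uniform(-lim, lim, size=(fin, 4 * h)).astype(np.float32)
        U = np.concatenate([_orthogonal(rng, h) for _ in range(4)], axis=1)
        b = np.zeros(4 * h, dtype=np.float32)
        b[h : 2 * h] = 1.0  # forget-gate bias
        params.append({"W": W, "U": U, "b": b})
        fin = h
    h_last = hidden_sizes[-1]
    lim = np.sqrt(6.0 / (h_last + 1))
    params.append(
        {
            "w": rng.uniform(-lim, lim, size=(h_last, 1)).astype(np.float32),
            "b": np.zeros(1, dtype=np.float32),
        }
    )
    return params


def _lstm_forward(Z: np.ndarray, U: np.ndarray):
    """Run one LSTM layer over a time-major gate pre-activation block.

    ``Z``: (T, B, 4H) input projections incl. bias — consumed in place.
    Returns (Hs, G, C): hidden states, gate activations, cell states.
    """
    T, B, H4 = Z.shape
    H = H4 // 4
    Hs = np.empty((T, B, H), np.float32)
    C = np.empty((T, B, H), np.float32)
    ht = np.zeros((B, H), np.float32)
    ct = np.zeros((B, H), np.float32)
    for t in range(T):
        z = Z[t]
        z += ht @ U
        sg = z[:, : 3 * H]
        np.negative(sg, out=sg)
        np.clip(sg, -30.0, 30.0, out=sg)  # float32 exp overflow guard
        np.exp(sg, out=sg)
        sg += 1.0
        np.reciprocal(sg, out=sg)
        np.tanh(z[:, 3 * H :], out=z[:, 3 * H :])
        i = z[:, :H]
        f = z[:, H : 2 * H]
        o = z[:, 2 * H : 3 * H]
        g = z[:, 3 * H :]
        ct = f * ct
        ct += i * g
        ht = o * np.tanh(ct)
        C[t] = ct
        Hs[t] = ht
    return Hs, Z, C  # Z now holds gate activations


def _lstm_backward(
    d_last: np.ndarray | None,
    dH_full: np.ndarray | None,
    G: np.ndarray,
    C: np.ndarray,
    U: np.ndarray,
):
    """BPTT through one layer.

    ``d_last`` is the gradient arriving only at the final hidden state
    (top layer); ``dH_full`` is a (T, B, H) gradient on every output
    (layers below the top).  Returns dZ (T, B, 4H), the gradient on the
    gate pre-activations.
    """
    T, B, H = C.shape
    Ut = np.ascontiguousarray(U.T)
    dZ = np.empty((T, B, 4 * H), np.float32)
    if d_last is not None:
        dh = d_last.astype(np.float32).copy()
    else:
        dh = dH_full[T - 1].copy()
    dc = np.zeros((B, H), np.float32)
    for t in range(T - 1, -1, -1):
        if dH_full is not None and t < T - 1:
            dh += dH_full[t]
        z = G[t]
        i = z[:, :H]
        f = z[:, H : 2 * H]
        o = z[:, 2 * H : 3 * H]
        g = z[:, 3 * H :]
        tc = np.tanh(C[t])
        dc += dh * o * (1.0 - tc * tc)
        dz = dZ[t]
        dz[:, :H] = dc * g * i * (1.0 - i)
        cprev = C[t - 1] if t > 0 else 0.0
        dz[:, H : 2 * H] = dc * cprev * f * (1.0 - f)
        dz[:, 2 * H : 3 * H] = (dh * tc) * o * (1.0 - o)
        dz[:, 3 * H :] = dc * i * (1.0 - g * g)
        dc *= f
        dh = dz @ Ut
    return dZ


@dataclass
class TrainedModel:
    """A fitted COP regressor plus everything needed to apply it."""

    config: ModelConfig
    direction: str
    params: list[dict[str, np.ndarray]]
    training_history: list[float]
    input_spec: WindowSpec
    channel_stats: ChannelStats | None = None
    y_mean: float = 0.0
    y_sd: float = 1.0

    def save(self, path: str | Path) -> None:
        arrays: dict[str, np.ndarray] = {}
        for li, layer in enumerate(self.params):
            for k, v in layer.items():
                arrays[f"p{li}_{k}"] = v
        if self.channel_stats is not None:
            arrays["stats_mean"] = self.channel_stats.mean
            arrays["stats_sd"] = self.channel_stats.sd
        meta = dict(
            hidden_sizes=list(self.config.hidden_sizes),
            dropout_rate=self.config.dropout_rate,
            epochs=self.config.epochs,
            batch_size=self.config.batch_size,
            learning_rate=self.config.learning_rate,
            rho=self.config.rho,
            epsilon=self.config.epsilon,
            shuffle=self.config.shuffle,
            seed=self.config.seed,
            direction=self.direction,
            lookback=self.input_spec.lookback_frames,
            sites=list(self.input_spec.sites),
            history=self.training_history,
            y_mean=self.y_mean,
            y_sd=self.y_sd,
        )
        np.savez(path, _meta=np.frombuffer(repr(meta).encode(), dtype=np.uint8), **arrays)

    @classmethod
    def load(cls, path: str | Path) -> "TrainedModel":
        import ast

        with np.load(path) as data:
            meta = ast.literal_eval(bytes(data["_meta"]).decode())
            n_layers = len(meta["hidden_sizes"]) + 1
            params = []
            for li in range(n_layers):
                layer = {
                    k.split("_", 1)[1]: data[k]
                    for k in data.files
                    if k.startswith(f"p{li}_")
                }
                params.append(layer)
            stats = None
            if "stats_mean" in data.files:
                stats = ChannelStats(mean=data["stats_mean"], sd=data["stats_sd"])
        config = ModelConfig(
            hidden_sizes=tuple(meta["hidden_sizes"]),
            dropout_rate=meta["dropout_rate"],
            epochs=meta["epochs"],
            batch_size=meta["batch_size"],
            learning_rate=meta["learning_rate"],
            rho=meta["rho"],
            epsilon=meta["epsilon"],
            shuffle=meta["shuffle"],
            seed=meta["seed"],
        )
        spec = WindowSpec(
            lookback_frames=meta["lookback"],
            sites=tuple(meta["sites"]),
            direction=meta["direction"],
        )
        return cls(
            config=config,
            direction=meta["direction"],
            params=params,
            training_history=list(meta["history"]),
            input_spec=spec,
            channel_stats=stats,
            y_mean=meta["y_mean"],
            y_sd=meta["y_sd"],
        )


def _forward_full(
    params: list[dict[str, np.ndarray]],
    X: np.ndarray,
    hidden_sizes: tuple[int, ...],
    keep_cache: bool,
):
    """Forward pass over a (B, P, F) batch; returns the last hidden state
    and, optionally, the per-layer caches for BPTT."""
    B, T, _ = X.shape
    inp = np.ascontiguousarray(np.transpose(X, (1, 0, 2)))  # time-major
    caches = []
    for layer, h in zip(params[:-1], hidden_sizes):
        TB = T * B
        Z = (inp.reshape(TB, -1) @ layer["W"] + layer["b"]).reshape(T, B, 4 * h)
        Hs, G, C = _lstm_forward(Z, layer["U"])
        if keep_cache:
            caches.append((inp, Hs, G, C))
        inp = Hs
    h_last = inp[T - 1]
    return h_last, caches


def _predict_batch(model: "TrainedModel", X: np.ndarray) -> np.ndarray:
    head = model.params[-1]
    out = np.empty(len(X), dtype=np.float64)
    for lo in range(0, len(X), 512):
        hi = min(lo + 512, len(X))
        h_last, _ = _forward_full(
            model.params, X[lo:hi], model.config.hidden_sizes, keep_cache=False
        )
        out[lo:hi] = (h_last @ head["w"] + head["b"]).ravel()
    return out * model.y_sd + model.y_mean


def train(
    samples: WindowedDataset,
    config: ModelConfig,
    channel_stats: ChannelStats | None = None,
) -> TrainedModel:
    """Fit the regressor on (standardized) windowed samples.

    ``channel_stats`` is carried into the returned model so that raw
    sensor streams can be standardized consistently at prediction time.
    Weight initialization, shuffling and dropout are all driven by
    ``config.seed``, making training bit-reproducible on one machine.

    Raises :class:`DivergenceError` (reporting the epoch) if the loss
    goes non-finite.
    """
    if len(samples) == 0:
        raise EmptyDatasetError("no training samples")
    X = np.ascontiguousarray(samples.x, dtype=np.float32)
    if X.ndim != 3:
        raise ParameterError(f"samples.x must be (n, P, F); got {X.shape}")
    n, T, F = X.shape
    if F != samples.spec.feature_dim:
        raise ParameterError(
            f"feature dim {F} inconsistent with spec {samples.spec.feature_dim}"
        )
    y = np.asarray(samples.y, dtype=np.float64)
    y_mean = float(y.mean())
    y_sd = float(y.std())
    if y_sd == 0:
        y_sd = 1.0
    yz = ((y - y_mean) / y_sd).astype(np.float32)

    rng = np.random.default_rng(config.seed)
    params = _init_params(rng, F, config.hidden_sizes)
    head = params[-1]
    # RMSprop accumulators, one per tensor
    sq = [{k: np.zeros_like(v) for k, v in layer.items()} for layer in params]

    lr = np.float32(config.learning_rate)
    rho = np.float32(config.rho)
    eps = np.float32(config.epsilon)
    keep = 1.0 - config.dropout_rate
    history: list[float] = []

    for epoch in range(config.epochs):
        order = rng.permutation(n) if config.shuffle else np.arange(n)
        sq_errs = 0.0
        count = 0
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            B = len(idx)
            xb = X[idx]
            yb = yz[idx]
            h_last, caches = _forward_full(params, xb, config.hidden_sizes, True)
            if config.dropout_rate > 0:
                mask = (rng.random((B, h_last.shape[1])) < keep).astype(np.float32) / keep
                hd = h_last * mask
            else:
                mask = None
                hd = h_last
            yhat = (hd @ head["w"] + head["b"]).ravel()
            err = yhat - yb
            batch_mse = float(np.mean(err.astype(np.float64) ** 2))
            loss = np.sqrt(batch_mse)
            if not np.isfinite(loss):
                raise DivergenceError(epoch)
            sq_errs += batch_mse * B
            count += B

            # -- backward -----------------------------------------------
            grads: list[dict[str, np.ndarray]] = [dict() for _ in params]
            if loss > 0:
                dyhat = (err / (B * loss)).astype(np.float32)[:, None]
                grads[-1]["w"] = hd.T @ dyhat
                grads[-1]["b"] = dyhat.sum(0)
                dhd = dyhat @ head["w"].T
                if mask is not None:
                    dhd = dhd * mask
                dH_full = None
                d_last = dhd
                for li in range(len(config.hidden_sizes) - 1, -1, -1):
                    inp, Hs, G, C = caches[li]
                    layer = params[li]
                    dZ = _lstm_backward(d_last, dH_full, G, C, layer["U"])
                    TB = T * B
                    dZf = dZ.reshape(TB, -1)
                    grads[li]["W"] = inp.reshape(TB, -1).T @ dZf
                    Hprev = np.empty_like(Hs)
                    Hprev[0] = 0.0
                    Hprev[1:] = Hs[:-1]
                    grads[li]["U"] = Hprev.reshape(TB, -1).T @ dZf
                    grads[li]["b"] = dZf.sum(0)
                    if li > 0:
                        dH_full = (dZf @ layer["W"].T).reshape(T, B, -1)
                        d_last = None
                # -- RMSprop update -------------------------------------
                for layer, g, s in zip(params, grads, sq):
                    for k in layer:
                        gk = g[k].reshape(layer[k].shape)
                        s[k] *= rho
                        s[k] += (1.0 - rho) * gk * gk
                        layer[k] -= lr * gk / (np.sqrt(s[k]) + eps)
        history.append(float(np.sqrt(sq_errs / count)) * y_sd)

    return TrainedModel(
        config=config,
        direction=samples.spec.direction,
        params=params,
        training_history=history,
        input_spec=samples.spec,
        channel_stats=channel_stats,
        y_mean=y_mean,
        y_sd=y_sd,
    )


def predict(model: TrainedModel, samples: WindowedDataset) -> np.ndarray:
    """Predict COP (cm) for already-standardized windowed samples."""
    if samples.spec.feature_dim != model.input_spec.feature_dim:
        raise ParameterError("sample feature dim does not match the model")
    return _predict_batch(model, np.ascontiguousarray(samples.x, dtype=np.float32))


def predict_trajectory(
    model: TrainedModel,
    sensors: dict[str, SensorStream],
    plantar: PlantarStream,
    step: GaitStep,
    spec: WindowSpec | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Predict the stance-phase COP trajectory of one step, frame by frame.

    Builds the lookback window for every stance frame (prediction at
    frame ``t`` sees only IMU frames ``< t``), standardizes with the
    training channel statistics, and returns ``(frames, cop_cm)``.
    """
    spec = spec or model.input_spec
    if (
        spec.lookback_frames != model.input_spec.lookback_frames
        or spec.sites != model.input_spec.sites
    ):
        raise ParameterError("window spec incompatible with the trained model")
    try:
        ds = build_samples(sensors, plantar, [step], spec)
    except EmptyDatasetError:
        raise EmptyDatasetError(
            "no stance frame of this step has a full lookback window"
        ) from None
    if model.channel_stats is not None:
        ds = standardize(ds, model.channel_stats)
    preds = _predict_batch(model, np.ascontiguousarray(ds.x, dtype=np.float32))
    return ds.frame_idx, preds
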