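"""Many-to-one windowing: lookback IMU windows → one COP target.

Each training sample pairs a lookback window of ``P`` IMU frames with
the COP value at the frame immediately after the window; the window and
target advance frame by frame through every stance phase.  ``P`` is the
participant's mean heel-strike-to-heel-strike step length in frames, so
every window covers at least the preceding swing and reaches back into
the previous stance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .exceptions import EmptyDatasetError, ParameterError
from .io import SITES, PlantarStream, SensorStream
from .preprocess import GaitStep

#: fixed site stacking order for the feature axis
SITE_ORDER = SITES


@dataclass(frozen=True)
class WindowSpec:
    """Shape contract of the windowed dataset.

    ``feature_dim`` is 6 channels per selected site; sites are stacked
    in the fixed H, L, T, W order regardless of how the subset is
    spelled.
    """

    lookback_frames: int
    sites: tuple[str, ...]
    direction: str = "AP"

    def __post_init__(self) -> None:
        if self.lookback_frames < 1:
            raise ParameterError("lookback_frames must be >= 1")
        if not self.sites:
            raise ParameterError("sites must be non-empty")
        bad = [s for s in self.sites if s not in SITE_ORDER]
        if bad:
            raise ParameterError(f"unknown sites {bad}; expected subset of {SITE_ORDER}")
        if self.direction not in ("AP", "ML"):
            raise ParameterError("direction must be 'AP' or 'ML'")
        ordered = tuple(s for s in SITE_ORDER if s in self.sites)
        object.__setattr__(self, "sites", ordered)

    @property
    def feature_dim(self) -> int:
        return 6 * len(self.sites)


@dataclass
class WindowedDataset:
    """Stacked windowed samples with provenance.

    ``x``: (n, P, feature_dim) float32; ``y``: (n,) COP in cm;
    ``step_idx``/``frame_idx`` record where each sample came from.
    """

    x: np.ndarray
    y: np.ndarray
    step_idx: np.ndarray
    frame_idx: np.ndarray
    spec: WindowSpec

    def __len__(self) -> int:
        return len(self.y)

    def subset(self, mask: np.ndarray) -> "WindowedDataset":
        return WindowedDataset(
            self.x[mask], self.y[mask], self.step_idx[mask], self.frame_idx[mask], self.spec
        )

    def save(self, path) -> None:
        """Dump tensors to ``<path>.npz`` with a JSON sidecar
        (``<path>.json``) recording the window spec and provenance."""
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(
            path.with_suffix(".npz"),
            x=self.x,
            y=self.y,
            step_idx=self.step_idx,
            frame_idx=self.frame_idx,
        )
        sidecar = {
            "lookback_frames": self.spec.lookback_frames,
            "sites": list(self.spec.sites),
            "direction": self.spec.direction,
            "n_samples": len(self),
            "feature_dim": self.spec.feature_dim,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path) -> "WindowedDataset":
        import json
        from pathlib import Path

        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        spec = WindowSpec(
            lookback_frames=meta["lookback_frames"],
            sites=tuple(meta["sites"]),
            direction=meta["direction"],
        )
        with np.load(path.with_suffix(".npz")) as data:
            return cls(
                data["x"], data["y"], data["step_idx"], data["frame_idx"], spec
            )


@dataclass(frozen=True)
class ChannelStats:
    """Per-channel standardization moments, derived from training data only."""

    mean: np.ndarray
    sd: np.ndarray


def mean_step_period(train_steps: list[GaitStep]) -> int:
    """Lookback P = rounded mean heel-strike-to-next-heel-strike length
    over the training steps."""
    cycles = [s.cycle_frames for s in train_steps if s.cycle_frames is not None]
    if not cycles:
        raise ParameterError("no training step has a successor heel strike")
    return int(round(float(np.mean(cycles))))


def stack_features(sensors: dict[str, SensorStream], sites: tuple[str, ...]) -> np.ndarray:
    """Concatenate the selected sites' channels into an (n, 6·k) matrix,
    in fixed site order."""
    missing = [s for s in sites if s not in sensors]
    if missing:
        raise ParameterError(f"sensors missing for sites {missing}")
    return np.concatenate([sensors[s].data for s in SITE_ORDER if s in sites], axis=1)


def build_samples(
    sensors: dict[str, SensorStream],
    plantar: PlantarStream,
    steps: list[GaitStep],
    spec: WindowSpec,
) -> WindowedDataset:
    """Emit one sample per stance frame of every step.

    For stance frame ``t``, the input is IMU frames ``[t-P, t)`` and
    the target is COP(t); frames with insufficient history (window
    would start before the recording) are skipped rather than padded.
    """
    feats = stack_features(sensors, spec.sites).astype(np.float32)
    cop = plantar.cop(spec.direction)
    P = spec.lookback_frames
    xs, ys, sidx, fidx = [], [], [], []
    for k, step in enumerate(steps):
        for t in range(step.hs_frame, step.to_frame):
            if t - P < 0 or t >= len(feats):
                continue
            target = cop[t]
            if not np.isfinite(target):
                continue
            xs.append(feats[t - P : t])
            ys.append(target)
            sidx.append(k)
            fidx.append(t)
    if not xs:
        raise EmptyDatasetError("no stance frame has a full lookback window")
    return WindowedDataset(
        x=np.stack(xs),
        y=np.asarray(ys, dtype=np.float32),
        step_idx=np.asarray(sidx, dtype=np.int64),
        frame_idx=np.asarray(fidx, dtype=np.int64),
        spec=spec,
    )


def compute_stats(train: WindowedDataset) -> ChannelStats:
    """Per-channel mean/SD over all frames of the training windows."""
    flat = train.x.reshape(-1, train.x.shape[-1]).astype(np.float64)
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0)
    return ChannelStats(mean=mean, sd=sd)


def standardize(samples: WindowedDataset, stats: ChannelStats) -> WindowedDataset:
    """Transform each channel to (value − mean)/SD using *training* stats.

    A zero-variance channel is left centered only (with a warning)
    rather than dividing by zero.
    """
    sd = stats.sd.copy()
    zero = sd == 0
    if zero.any():
        warnings.warn(
            f"{int(zero.sum())} constant channel(s): centered but not scaled",
            stacklevel=2,
        )
        sd[zero] = 1.0
    x = (samples.x - stats.mean.astype(np.float32)) / sd.astype(np.float32)
    return WindowedDataset(
        x.astype(np.float32), samples.y, samples.step_idx, samples.frame_idx, samples.spec
    )


def expected_sample_count(
    steps: list[GaitStep], lookback_frames: int, n_total_frames: int
) -> int:
    """Closed-form sample count matching :func:`build_samples`' skipping
    rule (used as a sizing cross-check)."""
    total = 0
    for step in steps:
        lo = max(step.hs_frame, lookback_frames)
        hi = min(step.to_frame, n_total_frames)
        total += max(0, hi - lo)
    return total


def training_frame_budget(
    n_subjects: int = 5,
    n_steps: int = 74,
    frames_per_step: int = 148,
    train_fraction: float = 0.7,
) -> int:
    """Training input-matrix row count from the study's sizing factors:
    subjects × steps × per-step frame budget × training fraction."""
    return int(round(n_subjects * n_steps * frames_per_step * train_fraction))
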