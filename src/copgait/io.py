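"""Stream data model, CSV readers/writers and resampling.

Two kinds of time series flow through the pipeline:

* :class:`SensorStream` — one body site's 6-channel IMU recording
  (tri-axial accelerometer in g, tri-axial gyroscope in deg/s);
* :class:`PlantarStream` — the insole's vertical ground-reaction force
  (N) plus the center-of-pressure coordinates (cm) along the
  anterior–posterior (AP) and medial–lateral (ML) axes.  COP is defined
  only while the foot is loaded; swing frames carry NaN as an explicit
  "undefined" sentinel so that downstream code must mask stance
  explicitly rather than silently treating swing COP as zero.

Streams live on a uniform clock (``sample_rate_hz``) with a clock
offset ``t0_s``; frame indices are 0-based and slices are half-open.
CSV files are comma-separated with a mandatory header and ``.`` decimal
separator, so that write→read round-trips are exact at the printed
precision.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import FormatError, ParameterError

#: Canonical site codes in fixed stacking order: heel, lateral, toe, waist.
SITES: tuple[str, ...] = ("H", "L", "T", "W")

#: IMU channel names in file and feature order.
IMU_CHANNELS: tuple[str, ...] = ("ax", "ay", "az", "gx", "gy", "gz")

SENSOR_COLUMNS = ("t_s",) + IMU_CHANNELS
PLANTAR_COLUMNS = ("t_s", "grf_n", "cop_ap_cm", "cop_ml_cm")


@dataclass
class SensorStream:
    """One site's 6-channel IMU time series on a uniform clock.

    ``data`` is an ``(n, 6)`` float array in :data:`IMU_CHANNELS` order.
    """

    site: str
    sample_rate_hz: float
    data: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ParameterError(f"unknown site {self.site!r}; expected one of {SITES}")
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be > 0")
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != 6:
            raise ParameterError(f"sensor data must be (n, 6); got {self.data.shape}")
        if not np.isfinite(self.data).all():
            raise ParameterError("sensor data must be finite")

    def __len__(self) -> int:
        return self.data.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.sample_rate_hz

    def accel_magnitude(self) -> np.ndarray:
        """Euclidean norm of the three accelerometer channels, in g."""
        return np.linalg.norm(self.data[:, :3], axis=1)

    def shifted(self, frames: int) -> "SensorStream":
        """Shift the stream by ``frames`` on its own clock.

        Positive ``frames`` delays the signal (prepends edge padding);
        negative advances it.  Length is preserved; the vacated end is
        padded with the edge sample.
        """
        if frames == 0:
            return replace(self, data=self.data.copy())
        out = np.empty_like(self.data)
        if frames > 0:
            out[frames:] = self.data[: len(self) - frames]
            out[:frames] = self.data[0]
        else:
            out[:frames] = self.data[-frames:]
            out[frames:] = self.data[-1]
        return replace(self, data=out)


@dataclass
class PlantarStream:
    """Insole stream: vertical GRF plus the COP trajectory it supports."""

    sample_rate_hz: float
    grf_n: np.ndarray
    cop_ap_cm: np.ndarray
    cop_ml_cm: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        if self.sample_rate_hz <= 0:
            raise ParameterError("sample_rate_hz must be > 0")
        self.grf_n = np.asarray(self.grf_n, dtype=float)
        self.cop_ap_cm = np.asarray(self.cop_ap_cm, dtype=float)
        self.cop_ml_cm = np.asarray(self.cop_ml_cm, dtype=float)
        n = len(self.grf_n)
        if len(self.cop_ap_cm) != n or len(self.cop_ml_cm) != n:
            raise ParameterError("plantar series must share one length")
        if not np.isfinite(self.grf_n).all():
            raise ParameterError("grf_n must be finite")
        if (self.grf_n < 0).any():
            raise ParameterError("grf_n must be non-negative")

    def __len__(self) -> int:
        return len(self.grf_n)

    @property
    def times_s(self) -> np.ndarray:
        return self.t0_s + np.arange(len(self)) / self.sample_rate_hz

    def cop(self, direction: str) -> np.ndarray:
        if direction == "AP":
            return self.cop_ap_cm
        if direction == "ML":
            return self.cop_ml_cm
        raise ParameterError(f"direction must be 'AP' or 'ML', got {direction!r}")

    def copy(self) -> "PlantarStream":
        return PlantarStream(
            self.sample_rate_hz,
            self.grf_n.copy(),
            self.cop_ap_cm.copy(),
            self.cop_ml_cm.copy(),
            self.t0_s,
        )


def write_stream(stream: SensorStream | PlantarStream, path: str | Path) -> None:
    """Write a stream to CSV using its canonical column contract."""
    path = Path(path)
    t = stream.times_s
    if isinstance(stream, SensorStream):
        df = pd.DataFrame(stream.data, columns=list(IMU_CHANNELS))
        df.insert(0, "t_s", t)
    else:
        df = pd.DataFrame(
            {
                "t_s": t,
                "grf_n": stream.grf_n,
                "cop_ap_cm": stream.cop_ap_cm,
                "cop_ml_cm": stream.cop_ml_cm,
            }
        )
    df.to_csv(path, index=False, float_format="%.9g")


def read_stream(
    path: str | Path, kind: str, site: str = "H"
) -> SensorStream | PlantarStream:
    """Read and validate a stream CSV.

    Parameters
    ----------
    kind:
        ``"sensor"`` or ``"plantar"``.
    site:
        Site code attached to a sensor stream (the file itself does not
        record it).

    Raises
    ------
    FormatError
        On a wrong column count, NaN where finite values are required,
        non-monotone time, or negative GRF; the message names the
        offending row/column.
    """
    path = Path(path)
    if kind not in ("sensor", "plantar"):
        raise ParameterError(f"kind must be 'sensor' or 'plantar', got {kind!r}")
    expected = SENSOR_COLUMNS if kind == "sensor" else PLANTAR_COLUMNS
    df = pd.read_csv(path)
    if tuple(df.columns) != expected:
        raise FormatError(
            f"{path.name}: expected {len(expected)} columns {expected}, "
            f"got {len(df.columns)} columns {tuple(df.columns)}"
        )
    if len(df) < 2:
        raise FormatError(f"{path.name}: need at least 2 rows")
    t = df["t_s"].to_numpy(dtype=float)
    if not np.isfinite(t).all():
        row = int(np.flatnonzero(~np.isfinite(t))[0])
        raise FormatError(f"{path.name}: non-finite t_s at row {row}")
    dt = np.diff(t)
    if (dt <= 0).any():
        row = int(np.flatnonzero(dt <= 0)[0]) + 1
        raise FormatError(f"{path.name}: non-monotone t_s at row {row}")
    rate = 1.0 / float(np.median(dt))
    if kind == "sensor":
        data = df[list(IMU_CHANNELS)].to_numpy(dtype=float)
        if not np.isfinite(data).all():
            r, c = np.argwhere(~np.isfinite(data))[0]
            raise FormatError(
                f"{path.name}: missing/NaN value at row {int(r)}, "
                f"column {IMU_CHANNELS[int(c)]}"
            )
        return SensorStream(site=site, sample_rate_hz=rate, data=data, t0_s=float(t[0]))
    grf = df["grf_n"].to_numpy(dtype=float)
    if not np.isfinite(grf).all():
        row = int(np.flatnonzero(~np.isfinite(grf))[0])
        raise FormatError(f"{path.name}: missing/NaN grf_n at row {row}")
    if (grf < 0).any():
        row = int(np.flatnonzero(grf < 0)[0])
        raise FormatError(f"{path.name}: negative grf_n at row {row}")
    return PlantarStream(
        sample_rate_hz=rate,
        grf_n=grf,
        cop_ap_cm=df["cop_ap_cm"].to_numpy(dtype=float),
        cop_ml_cm=df["cop_ml_cm"].to_numpy(dtype=float),
        t0_s=float(t[0]),
    )


def resample(
    stream: SensorStream | PlantarStream, target_rate_hz: float
) -> SensorStream | PlantarStream:
    """Linearly resample a stream onto a uniform grid at ``target_rate_hz``.

    The new grid spans the original time range; channel count is
    preserved.  Linear interpolation is adequate for gait content
    (< 20 Hz) and keeps endpoints of monotone ramps exact.  NaN spans in
    COP channels remain NaN wherever either neighbouring source sample
    is NaN.
    """
    if target_rate_hz <= 0:
        raise ParameterError("target_rate_hz must be > 0")
    if len(stream) < 2:
        raise ParameterError("resample needs at least 2 samples")
    t_old = stream.times_s
    n_new = int(np.floor((t_old[-1] - t_old[0]) * target_rate_hz)) + 1
    t_new = t_old[0] + np.arange(n_new) / target_rate_hz

    def interp(y: np.ndarray) -> np.ndarray:
        if np.isnan(y).any():
            # preserve the undefined sentinel: mark outputs whose source
            # neighbourhood contains NaN
            out = np.interp(t_new, t_old, np.nan_to_num(y))
            bad = np.interp(t_new, t_old, np.isnan(y).astype(float)) > 0
            out[bad] = np.nan
            return out
        return np.interp(t_new, t_old, y)

    if isinstance(stream, SensorStream):
        data = np.column_stack([interp(stream.data[:, j]) for j in range(6)])
        return SensorStream(stream.site, target_rate_hz, data, t0_s=float(t_old[0]))
    return PlantarStream(
        target_rate_hz,
        np.clip(interp(stream.grf_n), 0.0, None),
        interp(stream.cop_ap_cm),
        interp(stream.cop_ml_cm),
        t0_s=float(t_old[0]),
    )
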