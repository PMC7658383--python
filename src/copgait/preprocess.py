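"""Synchronization, cleaning, gait-event detection, step handling.

The plantar stream is the ground-truth clock.  Stance is delimited by
vertical-GRF threshold crossings: heel strike (HS) at the rising 10 N
crossing, toe off (TO) at the first post-peak fall below 25 N — the
crossing directions follow heel-strike loading and push-off unloading
physiology.  Spurious pressure during swing is zeroed before event
detection, and edge steps of each corridor trip are trimmed because
gait is not yet steady there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .exceptions import ParameterError, SynchronizationError, UndefinedCOPError
from .io import PlantarStream, SensorStream


@dataclass(frozen=True)
class GaitStep:
    """One step's event indices on the plantar clock.

    ``stance`` is the half-open frame slice [hs_frame, to_frame).
    """

    hs_frame: int
    to_frame: int
    next_hs_frame: int | None = None

    def __post_init__(self) -> None:
        if not self.hs_frame < self.to_frame:
            raise ParameterError("hs_frame must be < to_frame")
        if self.next_hs_frame is not None and self.to_frame > self.next_hs_frame:
            raise ParameterError("to_frame must be <= next_hs_frame")

    @property
    def stance(self) -> slice:
        return slice(self.hs_frame, self.to_frame)

    @property
    def stance_frames(self) -> int:
        return self.to_frame - self.hs_frame

    @property
    def cycle_frames(self) -> int | None:
        if self.next_hs_frame is None:
            return None
        return self.next_hs_frame - self.hs_frame


@dataclass(frozen=True)
class SplitPlan:
    """Reproducible step-level train/test partition."""

    train_steps: tuple[int, ...]
    test_steps: tuple[int, ...]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        if set(self.train_steps) & set(self.test_steps):
            raise ParameterError("train and test step sets must be disjoint")


def _first_prominent_peak(x: np.ndarray, search_frames: int) -> int:
    """Index of the first peak in ``x[:search_frames]`` whose height is
    at least half the window maximum."""
    w = np.asarray(x[:search_frames], dtype=float)
    base = np.median(w)
    rel = w - base
    top = rel.max()
    if top <= 0:
        raise SynchronizationError("no synchronization peak found")
    peaks, props = find_peaks(rel, height=0.5 * top, prominence=0.25 * top)
    if len(peaks) == 0:
        raise SynchronizationError("no peak above prominence threshold")
    return int(peaks[0])


def synchronize(
    sensors: dict[str, SensorStream],
    plantar: PlantarStream,
    search_s: float = 5.0,
) -> tuple[dict[str, SensorStream], PlantarStream, int]:
    """Align the IMU streams to the plantar clock via the stomp spike.

    Finds the first prominent peak of the heel accelerometer magnitude
    and of the vertical GRF within the opening ``search_s`` seconds, and
    shifts every sensor stream so the two peaks coincide.

    Returns ``(aligned_sensors, plantar, lag)`` where ``lag`` is the
    recovered sensor-minus-plantar offset in frames.
    """
    if "H" not in sensors:
        raise SynchronizationError("heel sensor required for synchronization")
    fs = plantar.sample_rate_hz
    search = int(round(search_s * fs))
    heel_peak = _first_prominent_peak(sensors["H"].accel_magnitude(), search)
    grf_peak = _first_prominent_peak(plantar.grf_n, search)
    lag = heel_peak - grf_peak
    aligned = {site: s.shifted(-lag) for site, s in sensors.items()}
    return aligned, plantar, lag


def clean_swing_noise(plantar: PlantarStream, threshold_n: float) -> PlantarStream:
    """Zero sub-threshold GRF and mark its COP undefined.

    Any frame with GRF below ``threshold_n`` is treated as unloaded:
    GRF set to 0 and COP to NaN.  Frames at or above the threshold are
    untouched.
    """
    if threshold_n <= 0:
        raise ParameterError("threshold_n must be > 0")
    out = plantar.copy()
    low = out.grf_n < threshold_n
    out.grf_n[low] = 0.0
    out.cop_ap_cm[low] = np.nan
    out.cop_ml_cm[low] = np.nan
    return out


def detect_gait_events(
    plantar: PlantarStream,
    hs_threshold_n: float = 10.0,
    to_threshold_n: float = 25.0,
    min_stance_s: float = 0.3,
    ignore_before_frame: int = 0,
) -> list[GaitStep]:
    """Detect steps from the cleaned vertical GRF.

    Each contiguous supra-zero GRF epoch yields one candidate step:
    heel strike at the first frame with GRF >= ``hs_threshold_n``, toe
    off at the first frame after the epoch's maximum where GRF falls
    below ``to_threshold_n``.  Epochs shorter than ``min_stance_s`` are
    discarded as artifacts (this also rejects the stomp spike), as are
    epochs before ``ignore_before_frame``.

    Returns steps in temporal order with ``next_hs_frame`` linked; the
    last step has no successor.
    """
    grf = plantar.grf_n
    loaded = grf > 0
    if not loaded.any():
        return []
    edges = np.diff(loaded.astype(np.int8))
    starts = list(np.flatnonzero(edges == 1) + 1)
    ends = list(np.flatnonzero(edges == -1) + 1)
    if loaded[0]:
        starts.insert(0, 0)
    if loaded[-1]:
        ends.append(len(grf))

    min_frames = int(round(min_stance_s * plantar.sample_rate_hz))
    events: list[tuple[int, int]] = []
    for s, e in zip(starts, ends):
        if s < ignore_before_frame:
            continue
        seg = grf[s:e]
        above = np.flatnonzero(seg >= hs_threshold_n)
        if len(above) == 0:
            continue
        hs = s + int(above[0])
        peak = s + int(np.argmax(seg))
        below = np.flatnonzero(grf[peak:e] < to_threshold_n)
        to = peak + int(below[0]) if len(below) else e
        if to - hs < min_frames:
            continue
        events.append((hs, to))

    steps: list[GaitStep] = []
    for i, (hs, to) in enumerate(events):
        nxt = events[i + 1][0] if i + 1 < len(events) else None
        steps.append(GaitStep(hs_frame=hs, to_frame=to, next_hs_frame=nxt))
    return steps


def trim_steps(
    steps: list[GaitStep],
    trip_boundaries: list[int] | None = None,
    n_edge: int = 3,
) -> list[GaitStep]:
    """Drop the first and last ``n_edge`` steps of each trip.

    ``trip_boundaries`` are frame indices separating consecutive trips
    (a step belongs to the trip whose boundary interval contains its
    heel strike); ``None`` means a single trip.  A trip with too few
    steps (≤ 2·n_edge) contributes nothing and triggers a warning.
    """
    if n_edge < 0:
        raise ParameterError("n_edge must be >= 0")
    bounds = sorted(trip_boundaries or [])
    trips: dict[int, list[GaitStep]] = {}
    for step in steps:
        trip = int(np.searchsorted(bounds, step.hs_frame, side="right"))
        trips.setdefault(trip, []).append(step)
    kept: list[GaitStep] = []
    for trip in sorted(trips):
        members = trips[trip]
        if len(members) <= 2 * n_edge:
            warnings.warn(
                f"trip {trip}: only {len(members)} steps, fewer than the "
                f"2*{n_edge} edge steps to trim; trip discarded",
                stacklevel=2,
            )
            continue
        kept.extend(members[n_edge : len(members) - n_edge])
    return kept


def split_steps(
    steps: list[GaitStep], fraction: float = 0.7, seed: int = 0
) -> SplitPlan:
    """Random step-level train/test partition.

    |train| = round(fraction · n).  Splitting at step level (not frame
    level) keeps overlapping lookback windows from leaking between the
    two sets.
    """
    if not 0 < fraction < 1:
        raise ParameterError(f"fraction must be in (0, 1), got {fraction}")
    n = len(steps)
    if n < 2:
        raise ParameterError("need at least 2 steps to split")
    n_train = int(round(fraction * n))
    n_train = min(max(n_train, 1), n - 1)
    perm = np.random.default_rng(seed).permutation(n)
    train = tuple(sorted(int(i) for i in perm[:n_train]))
    test = tuple(sorted(int(i) for i in perm[n_train:]))
    return SplitPlan(train_steps=train, test_steps=test, fraction=fraction, seed=seed)


def compute_cop_centroid(
    pressures: np.ndarray, coords_ap: np.ndarray, coords_ml: np.ndarray
) -> tuple[float, float]:
    """Pressure-weighted centroid of a sensor grid: COP = Σ pᵢxᵢ / Σ pᵢ.

    For users whose mat exports raw cell pressures rather than COP.
    """
    p = np.asarray(pressures, dtype=float)
    total = p.sum()
    if total <= 0:
        raise UndefinedCOPError("all cells zero: COP undefined")
    ap = float((p * np.asarray(coords_ap, dtype=float)).sum() / total)
    ml = float((p * np.asarray(coords_ml, dtype=float)).sum() / total)
    return ap, ml
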