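"""Synthetic multi-sensor gait sessions.

Generates coupled IMU / vertical-GRF / COP signals with the statistical
structure the downstream analysis assumes, so every stage of the
pipeline is testable without instrumented recordings.  The emulated
session mirrors a treadmill-free corridor walk: four IMU sites (heel H,
lateral L, toe T on the shoe; waist W), an insole plantar stream, a
floor **stomp** at session start used for synchronization, and a random
inter-stream lag between the IMU and insole clocks.

The waveforms are phenomenological, not rigid-body physics: every
channel is a deterministic function of a latent gait phase (sums of
phase-locked Gaussian bumps plus low-frequency sinusoids) scaled by a
shared per-step amplitude jitter, with additive Gaussian measurement
noise on the IMU channels.  That gives the two properties the analysis
needs — the IMU→COP mapping is learnable, and each site has its own
activity timing (heel quiet mid-stance, toe active throughout stance,
waist a low-amplitude oscillation).

Defaults are calibrated to the study conditions: 148 Hz sampling,
74 steps per session, stance ≈ 120 frames, cycle ≈ 163 frames (≈1.1 s),
AP COP path 17.48 cm, ML excursion 1.48 cm.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import SITES, PlantarStream, SensorStream, write_stream
from .preprocess import GaitStep


@dataclass
class GaitParams:
    """Calibration of one synthetic walking session.

    Lengths are in cm, forces in N, rates in Hz, counts in frames.
    ``lag_frames=None`` means the inter-stream lag is drawn uniformly
    in [-30, 30] when the session is generated.
    """

    sample_rate_hz: float = 148.0
    n_steps: int = 74
    stance_frames_mean: float = 120.0
    stance_frames_sd: float = 6.0
    cycle_frames_mean: float = 163.0
    body_weight_n: float = 541.0
    cop_ap_length_cm: float = 17.48
    cop_ml_excursion_cm: float = 1.48
    imu_noise_sd: float = 0.05
    step_scale_sd: float = 0.05
    lag_frames: int | None = None
    stomp_amplitude: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "sample_rate_hz": self.sample_rate_hz,
            "n_steps": self.n_steps,
            "stance_frames_mean": self.stance_frames_mean,
            "cycle_frames_mean": self.cycle_frames_mean,
            "body_weight_n": self.body_weight_n,
            "cop_ap_length_cm": self.cop_ap_length_cm,
            "cop_ml_excursion_cm": self.cop_ml_excursion_cm,
            "stomp_amplitude": self.stomp_amplitude,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ParameterError(f"{name} must be strictly positive, got {value}")
        for name, value in (
            ("stance_frames_sd", self.stance_frames_sd),
            ("imu_noise_sd", self.imu_noise_sd),
            ("step_scale_sd", self.step_scale_sd),
        ):
            if value < 0:
                raise ParameterError(f"{name} must be >= 0, got {value}")
        if self.stance_frames_mean >= self.cycle_frames_mean:
            raise ParameterError("stance_frames_mean must be < cycle_frames_mean")


@dataclass
class StepTemplate:
    """One gait cycle: stance (foot loaded) followed by swing.

    ``grf`` is zero exactly on swing frames; COP carries NaN there.
    ``phase`` is the latent gait phase in [0, 1] over the cycle; stance
    occupies the leading fraction.
    """

    grf: np.ndarray
    cop_ap: np.ndarray
    cop_ml: np.ndarray
    imu: dict[str, np.ndarray]
    phase: np.ndarray
    stance_frames: int


@dataclass
class Session:
    """A full synthetic walking session on the plantar (ground-truth) clock."""

    sensors: dict[str, SensorStream]
    plantar: PlantarStream
    truth_steps: list[GaitStep]
    params: GaitParams
    lag_frames: int = 0
    stomp_frame: int = 0  # stomp peak index on the plantar clock

    def to_csv_dir(self, out_dir: str | Path) -> None:
        """Export the session: one CSV per sensor site, one plantar CSV
        and one step-annotation CSV."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for site, stream in self.sensors.items():
            write_stream(stream, out_dir / f"sensor_{site}.csv")
        write_stream(self.plantar, out_dir / "plantar.csv")
        rows = [
            {
                "step_idx": i,
                "hs_frame": s.hs_frame,
                "to_frame": s.to_frame,
                "next_hs_frame": -1 if s.next_hs_frame is None else s.next_hs_frame,
            }
            for i, s in enumerate(self.truth_steps)
        ]
        pd.DataFrame(rows).to_csv(out_dir / "steps.csv", index=False)


# ---------------------------------------------------------------------------
# waveform tables
# ---------------------------------------------------------------------------

# Vertical GRF over stance phase u in [0, 1], as a fraction of body weight:
# classic double bump (loading response ~u=0.27, push-off ~u=0.73) over a
# small plateau so the foot is decisively loaded (>> 25 N) from the first
# stance frame to the last.
_GRF_BASE = 0.05
_GRF_BUMPS = ((0.27, 0.14, 0.93), (0.73, 0.14, 0.88), (0.50, 0.22, 0.33))


def _grf_shape(u: np.ndarray) -> np.ndarray:
    r = np.full_like(u, _GRF_BASE)
    for c, w, a in _GRF_BUMPS:
        r += a * np.exp(-(((u - c) / w) ** 2))
    return r


#: nominal GRF peak as a fraction of body weight (dense-grid evaluation)
GRF_PEAK_RATIO: float = float(_grf_shape(np.linspace(0, 1, 4001)).max())


def _ap_shape(u: np.ndarray) -> np.ndarray:
    # monotone heel→toe progression, slightly S-shaped; h(0)=0, h(1)=1
    return 0.6 * u + 0.4 * (3 * u**2 - 2 * u**3)


def _ml_shape(u: np.ndarray) -> np.ndarray:
    # single smooth lateral→medial→lateral arc with unit excursion
    return np.sin(np.pi * u)


# Per-site IMU components.  Channel order: ax, ay, az (g), gx, gy, gz (deg/s).
# "stance" bumps are located in stance phase u, "swing" bumps in swing phase
# v, sinusoids run over the whole cycle.  Amplitude vectors give each of the
# six channels its own footprint so channels are informative individually.
_SITE_STANCE_BUMPS: dict[str, tuple[tuple[float, float, tuple[float, ...]], ...]] = {
    # heel: impact spike at heel strike, a heel-off burst, silent mid-stance
    "H": (
        (0.03, 0.02, (2.2, 0.8, 3.0, 120.0, 50.0, 200.0)),
        (0.72, 0.06, (0.9, 0.35, 1.3, 80.0, 30.0, 120.0)),
    ),
    # lateral: early weight acceptance and late push-off, quiet mid-stance
    "L": (
        (0.08, 0.05, (1.2, 0.5, 1.6, 90.0, 40.0, 130.0)),
        (0.86, 0.07, (0.8, 0.4, 1.1, 70.0, 35.0, 100.0)),
    ),
    # toe: dynamic during the entire stance, big push-off burst
    "T": (
        (0.08, 0.05, (0.8, 0.3, 1.2, 60.0, 25.0, 90.0)),
        (0.35, 0.10, (0.5, 0.25, 0.9, 45.0, 30.0, 70.0)),
        (0.62, 0.10, (0.7, 0.2, 1.0, 55.0, 20.0, 80.0)),
        (0.92, 0.06, (1.8, 0.6, 2.5, 160.0, 60.0, 220.0)),
    ),
    "W": (),
}
_SITE_SWING_BUMPS: dict[str, tuple[tuple[float, float, tuple[float, ...]], ...]] = {
    "H": ((0.50, 0.18, (0.7, 0.3, 1.0, 90.0, 40.0, 140.0)),),
    "L": ((0.40, 0.16, (0.8, 0.35, 1.1, 100.0, 45.0, 150.0)),),
    "T": ((0.35, 0.15, (1.0, 0.4, 1.3, 120.0, 50.0, 180.0)),),
    "W": (),
}
_SITE_SINES: dict[str, tuple[tuple[float, float, tuple[float, ...]], ...]] = {
    "H": ((1.0, 0.2, (0.10, 0.06, 0.12, 8.0, 5.0, 10.0)),),
    "L": ((1.0, 0.5, (0.12, 0.08, 0.15, 9.0, 6.0, 12.0)),),
    "T": ((1.0, 0.0, (0.15, 0.10, 0.20, 10.0, 8.0, 15.0)),),
    # waist: low-amplitude smooth oscillation at stride and step frequency
    "W": (
        (1.0, 0.0, (0.12, 0.08, 0.10, 6.0, 4.0, 5.0)),
        (2.0, 0.3, (0.18, 0.10, 0.15, 8.0, 5.0, 7.0)),
    ),
}

#: gravity offset on the vertical accelerometer channel, in g
_AZ_BASELINE = 1.0


def _site_ref_amps(site: str) -> np.ndarray:
    """Per-channel reference amplitude of a site (for noise scaling)."""
    amps = np.zeros(6)
    for table in (_SITE_STANCE_BUMPS, _SITE_SWING_BUMPS, _SITE_SINES):
        for comp in table[site]:
            amps = np.maximum(amps, np.abs(comp[2]))
    return np.maximum(amps, 0.05)


def _site_waveform(site: str, u: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Deterministic 6-channel waveform over one cycle.

    ``u`` is the stance phase (NaN on swing frames), ``v`` the swing
    phase (NaN on stance frames).
    """
    n = len(u)
    out = np.zeros((n, 6))
    tau = np.arange(n) / n
    stance = ~np.isnan(u)
    swing = ~np.isnan(v)
    for c, w, amps in _SITE_STANCE_BUMPS[site]:
        bump = np.exp(-(((u[stance] - c) / w) ** 2))
        out[stance] += bump[:, None] * np.asarray(amps)
    for c, w, amps in _SITE_SWING_BUMPS[site]:
        bump = np.exp(-(((v[swing] - c) / w) ** 2))
        out[swing] += bump[:, None] * np.asarray(amps)
    for freq, ph, amps in _SITE_SINES[site]:
        s = np.sin(2 * np.pi * (freq * tau + ph))
        out += s[:, None] * np.asarray(amps)
    out[:, 2] += _AZ_BASELINE
    return out


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------


def generate_step(params: GaitParams, rng: np.random.Generator) -> StepTemplate:
    """Generate one gait cycle (stance then swing).

    The stance frame count is drawn from N(stance_frames_mean,
    stance_frames_sd) and rounded; the swing length is the fixed
    difference cycle_frames_mean - stance_frames_mean, so with zero
    jitter the cycle is exactly ``cycle_frames_mean`` frames.  A shared
    per-step amplitude factor ~ N(1, step_scale_sd) scales GRF, COP and
    IMU amplitudes together, so the IMU→COP mapping stays deterministic
    given (phase, jitter).
    """
    if not isinstance(params, GaitParams):
        raise ParameterError("params must be a GaitParams instance")
    stance = int(round(rng.normal(params.stance_frames_mean, params.stance_frames_sd)))
    stance = max(stance, 10)
    swing = int(round(params.cycle_frames_mean - params.stance_frames_mean))
    cycle = stance + swing
    scale = float(rng.normal(1.0, params.step_scale_sd))

    u = np.full(cycle, np.nan)
    v = np.full(cycle, np.nan)
    u[:stance] = np.arange(stance) / (stance - 1)
    v[stance:] = np.arange(swing) / max(swing - 1, 1)
    phase = np.arange(cycle) / cycle

    grf = np.zeros(cycle)
    grf[:stance] = params.body_weight_n * scale * _grf_shape(u[:stance])

    cop_ap = np.full(cycle, np.nan)
    cop_ml = np.full(cycle, np.nan)
    cop_ap[:stance] = params.cop_ap_length_cm * scale * _ap_shape(u[:stance])
    cop_ml[:stance] = params.cop_ml_excursion_cm * scale * _ml_shape(u[:stance])

    imu: dict[str, np.ndarray] = {}
    for site in SITES:
        wave = _site_waveform(site, u, v)
        wave[:, :] = (wave - [0, 0, _AZ_BASELINE, 0, 0, 0]) * scale + [
            0,
            0,
            _AZ_BASELINE,
            0,
            0,
            0,
        ]
        noise_sd = params.imu_noise_sd * _site_ref_amps(site)
        wave += rng.normal(0.0, 1.0, size=wave.shape) * noise_sd
        imu[site] = wave
    return StepTemplate(grf, cop_ap, cop_ml, imu, phase, stance)


def generate_session(params: GaitParams) -> Session:
    """Generate a full session: quiet lead-in, stomp spike, gap, then
    ``n_steps`` concatenated gait cycles, with the IMU streams delayed
    by ``lag_frames`` relative to the plantar stream.

    Truth step annotations are recorded on the plantar clock.
    """
    rng = np.random.default_rng(params.seed)
    fs = params.sample_rate_hz
    lag = (
        int(rng.integers(-30, 31)) if params.lag_frames is None else int(params.lag_frames)
    )

    lead = int(round(0.5 * fs))
    stomp_w = max(int(round(0.05 * fs)), 3)
    if stomp_w % 2 == 0:  # odd width → unique central peak frame
        stomp_w += 1
    gap = int(round(1.5 * fs))
    tail = int(round(0.5 * fs))

    steps = [generate_step(params, rng) for _ in range(params.n_steps)]
    n = lead + stomp_w + gap + sum(len(s.grf) for s in steps) + tail

    grf = np.zeros(n)
    cop_ap = np.full(n, np.nan)
    cop_ml = np.full(n, np.nan)

    margin = max(40, abs(lag) + 10)
    ext = {site: np.zeros((n + 2 * margin, 6)) for site in SITES}
    for site in SITES:
        ext[site][:, 2] = _AZ_BASELINE
        noise_sd = params.imu_noise_sd * _site_ref_amps(site)
        ext[site] += rng.normal(0.0, 1.0, size=ext[site].shape) * noise_sd

    # stomp: half-sine spike in both the plantar GRF and the heel IMU
    stomp_env = np.sin(np.pi * (np.arange(stomp_w) + 0.5) / stomp_w)
    stomp_peak = lead + stomp_w // 2
    grf[lead : lead + stomp_w] = (
        params.stomp_amplitude * params.body_weight_n * GRF_PEAK_RATIO * stomp_env
    )
    heel_amp = _site_ref_amps("H")[2]  # az reference amplitude
    ext["H"][margin + lead : margin + lead + stomp_w, 2] += (
        params.stomp_amplitude * heel_amp * stomp_env
    )

    truth: list[GaitStep] = []
    pos = lead + stomp_w + gap
    offsets = []
    for tpl in steps:
        m = len(tpl.grf)
        grf[pos : pos + m] = tpl.grf
        cop_ap[pos : pos + m] = tpl.cop_ap
        cop_ml[pos : pos + m] = tpl.cop_ml
        for site in SITES:
            block = ext[site][margin + pos : margin + pos + m]
            block += tpl.imu[site]
            block[:, 2] -= _AZ_BASELINE  # baseline already present
        offsets.append((pos, tpl.stance_frames))
        pos += m
    for i, (off, stance) in enumerate(offsets):
        nxt = offsets[i + 1][0] if i + 1 < len(offsets) else None
        truth.append(GaitStep(hs_frame=off, to_frame=off + stance, next_hs_frame=nxt))

    sensors = {
        site: SensorStream(
            site=site,
            sample_rate_hz=fs,
            data=ext[site][margin - lag : margin - lag + n],
        )
        for site in SITES
    }
    plantar = PlantarStream(fs, grf, cop_ap, cop_ml)
    return Session(sensors, plantar, truth, params, lag_frames=lag, stomp_frame=stomp_peak)


def corrupt_swing(
    plantar: PlantarStream, noise_sd: float, rng: np.random.Generator
) -> PlantarStream:
    """Add small positive spurious GRF on a random subset of swing frames.

    Emulates the insole noise that the cleaning stage removes; COP stays
    undefined on the corrupted frames.
    """
    out = plantar.copy()
    if noise_sd == 0:
        return out
    swing = out.grf_n == 0
    hit = swing & (rng.random(len(out)) < 0.3)
    out.grf_n[hit] += np.abs(rng.normal(0.0, noise_sd, size=int(hit.sum())))
    return out
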