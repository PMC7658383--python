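"""Sensor-placement sweep: every subset of {H, L, T, W} through the
full pipeline, per direction, with NRMSE/Jaccard aggregation.

For a 4-site universe the sweep covers the 15 non-empty subsets
(4 one-sensor, 6 two-sensor, 4 three-sensor, 1 four-sensor sets).  One
train/test split per subject per seed is shared across all subsets so
that placement effects are compared on identical steps; models are
trained per subject and per direction, and metrics are aggregated over
all test steps.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ParameterError
from .io import SITES, PlantarStream, SensorStream, read_stream
from .metrics import CurvePair, aggregate, jaccard, nrmse
from .model import ModelConfig, predict_trajectory, train
from .preprocess import (
    clean_swing_noise,
    detect_gait_events,
    split_steps,
    synchronize,
    trim_steps,
)
from .windowing import (
    WindowSpec,
    build_samples,
    compute_stats,
    mean_step_period,
    standardize,
)

logger = logging.getLogger("copgait.sweep")


def enumerate_combinations(universe: tuple[str, ...] = SITES) -> list[tuple[str, ...]]:
    """All non-empty site subsets, ordered by size then lexically.

    For the 4-site universe this is exactly the 15 studied sets:
    H, L, T, W; H+L, H+T, H+W, L+T, L+W, T+W; H+L+T, H+L+W, H+T+W,
    L+T+W; H+L+T+W.
    """
    if not universe:
        raise ParameterError("universe must be non-empty")
    sites = sorted(set(universe))
    out: list[tuple[str, ...]] = []
    for size in range(1, len(sites) + 1):
        out.extend(itertools.combinations(sites, size))
    return out


def combo_label(sites: tuple[str, ...]) -> str:
    return "+".join(sites)


@dataclass
class SweepConfig:
    """Configuration of one sweep run.

    Provide either ``subjects`` (synthetic session calibrations, one
    per simulated participant) or ``session_dirs`` (directories of
    exported CSV sessions).  ``edge_trim=0`` by default because the
    synthetic generator emits already-trimmed steady-state walks; set
    it to 3 with ``trip_boundaries`` for raw corridor recordings.
    """

    subjects: list | None = None
    session_dirs: list[str | Path] | None = None
    sites_universe: tuple[str, ...] = SITES
    directions: tuple[str, ...] = ("AP", "ML")
    combinations: list[tuple[str, ...]] | None = None
    model: ModelConfig = field(default_factory=ModelConfig)
    split_fraction: float = 0.7
    split_seed: int = 0
    hs_threshold_n: float = 10.0
    to_threshold_n: float = 25.0
    swing_clean_threshold_n: float = 10.0
    edge_trim: int = 0
    trip_boundaries: list[int] | None = None
    output_dir: str | Path | None = None
    make_plots: bool = False

    def __post_init__(self) -> None:
        if not self.sites_universe:
            raise ParameterError("sites_universe must be non-empty")
        if not self.directions:
            raise ParameterError("need at least one direction")


def _load_session_dir(path: Path) -> tuple[dict[str, SensorStream], PlantarStream]:
    sensors = {}
    for site in SITES:
        f = path / f"sensor_{site}.csv"
        if f.exists():
            sensors[site] = read_stream(f, "sensor", site=site)
    plantar = read_stream(path / "plantar.csv", "plantar")
    return sensors, plantar


def _prepare_subject(config: SweepConfig, sensors, plantar):
    """Shared per-subject preprocessing: sync, clean, detect, trim, split."""
    sensors, plantar, lag = synchronize(sensors, plantar)
    cleaned = clean_swing_noise(plantar, config.swing_clean_threshold_n)
    # skip the stomp neighbourhood: it precedes the first step by design
    stomp = int(np.argmax(cleaned.grf_n[: int(5 * plantar.sample_rate_hz)]))
    ignore = stomp + int(round(1.0 * plantar.sample_rate_hz))
    steps = detect_gait_events(
        cleaned,
        hs_threshold_n=config.hs_threshold_n,
        to_threshold_n=config.to_threshold_n,
        ignore_before_frame=ignore,
    )
    if config.edge_trim > 0:
        steps = trim_steps(steps, config.trip_boundaries, n_edge=config.edge_trim)
    plan = split_steps(steps, config.split_fraction, config.split_seed)
    train_steps = [steps[i] for i in plan.train_steps]
    test_steps = [steps[i] for i in plan.test_steps]
    lookback = mean_step_period(train_steps)
    logger.info(
        "subject preprocessed: lag=%d, %d steps (%d train / %d test), lookback=%d",
        lag,
        len(steps),
        len(train_steps),
        len(test_steps),
        lookback,
    )
    return sensors, cleaned, train_steps, test_steps, plan, lookback


def run_combination(
    sensors: dict[str, SensorStream],
    plantar: PlantarStream,
    train_steps: list,
    test_steps: list,
    lookback: int,
    sites: tuple[str, ...],
    direction: str,
    model_config: ModelConfig,
) -> tuple[pd.DataFrame, list[tuple[np.ndarray, np.ndarray, np.ndarray]]]:
    """Train one subset×direction model and score every test step.

    Returns the per-step metric rows and, for plotting, the list of
    (frames, measured, predicted) trajectories.
    """
    spec = WindowSpec(lookback_frames=lookback, sites=sites, direction=direction)
    ds_train = build_samples(sensors, plantar, train_steps, spec)
    stats = compute_stats(ds_train)
    ds_train = standardize(ds_train, stats)
    fitted = train(ds_train, model_config, channel_stats=stats)
    rows = []
    curves = []
    label = combo_label(spec.sites)
    for k, step in enumerate(test_steps):
        frames, pred = predict_trajectory(fitted, sensors, plantar, step)
        measured = plantar.cop(direction)[frames]
        pair = CurvePair(measured=measured, predicted=pred, direction=direction)
        base = dict(
            sites=label, direction=direction, step=k, feature_dim=spec.feature_dim
        )
        rows.append(dict(base, metric="nrmse", value=nrmse(pair)))
        rows.append(dict(base, metric="jaccard", value=jaccard(pair)))
        curves.append((frames, measured, pred))
    return pd.DataFrame(rows), curves


def run_sweep(config: SweepConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full placement sweep.

    Returns ``(report, per_step)``: the aggregated mean ± SD table per
    (sites, direction, metric), and the per-step metric archive.  If
    ``config.output_dir`` is set, writes ``report.csv``,
    ``report.json``, ``per_step.csv`` and (optionally) trajectory
    overlay plots per combination.
    """
    from .synthetic import generate_session

    combos = config.combinations or enumerate_combinations(config.sites_universe)
    subjects: list[tuple[dict[str, SensorStream], PlantarStream]] = []
    if config.subjects:
        for params in config.subjects:
            sess = generate_session(params)
            subjects.append((sess.sensors, sess.plantar))
    elif config.session_dirs:
        for d in config.session_dirs:
            subjects.append(_load_session_dir(Path(d)))
    else:
        raise ParameterError("config needs subjects or session_dirs")

    all_rows = []
    curves_by_combo: dict[tuple[str, str], list] = {}
    for si, (sensors, plantar) in enumerate(subjects):
        sensors, cleaned, tr, te, plan, lookback = _prepare_subject(
            config, sensors, plantar
        )
        for ci, sites in enumerate(combos):
            for di, direction in enumerate(config.directions):
                seed = config.model.seed + 100_000 * si + 100 * ci + di
                mc = replace(config.model, seed=seed)
                try:
                    rows, curves = run_combination(
                        sensors, cleaned, tr, te, lookback, sites, direction, mc
                    )
                except Exception:
                    logger.exception(
                        "combination %s %s failed for subject %d; continuing",
                        combo_label(sites),
                        direction,
                        si,
                    )
                    continue
                rows.insert(0, "subject", si)
                all_rows.append(rows)
                curves_by_combo.setdefault((combo_label(sites), direction), []).extend(
                    curves
                )
                logger.info(
                    "subject %d %s %s: mean jaccard %.3f",
                    si,
                    combo_label(sites),
                    direction,
                    rows.loc[rows.metric == "jaccard", "value"].mean(),
                )

    per_step = (
        pd.concat(all_rows, ignore_index=True)
        if all_rows
        else pd.DataFrame(columns=["subject", "sites", "direction", "metric", "step", "value"])
    )
    report = aggregate(per_step)

    if config.output_dir is not None:
        out = Path(config.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_csv(out / "report.csv", index=False)
        with open(out / "report.json", "w") as fh:
            json.dump(report.to_dict(orient="records"), fh, indent=1)
        per_step.to_csv(out / "per_step.csv", index=False)
        if config.make_plots:
            _write_overlays(curves_by_combo, out)
    return report, per_step


def _write_overlays(curves_by_combo: dict, out: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for (label, direction), curves in curves_by_combo.items():
        fig, ax = plt.subplots(figsize=(6, 3))
        for j, (frames, measured, pred) in enumerate(curves[:6]):
            x = np.arange(len(measured))
            ax.plot(x, measured, "k-", lw=1, label="measured" if j == 0 else None)
            ax.plot(x, pred, "r--", lw=1, label="predicted" if j == 0 else None)
        ax.set_xlabel("stance frame")
        ax.set_ylabel(f"COP {direction} (cm)")
        ax.set_title(f"{label} — {direction}")
        ax.legend(frameon=False, fontsize=8)
        fig.tight_layout()
        fig.savefig(out / f"overlay_{label.replace('+', '')}_{direction}.png", dpi=110)
        plt.close(fig)
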