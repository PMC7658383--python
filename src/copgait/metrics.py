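"""Evaluation statistics: NRMSE and the area-based Jaccard similarity.

NRMSE is the root-mean-square error between measured and predicted COP
normalized by the measured curve's range and expressed in percent:

    NRMSE(%) = 100 · sqrt( Σₜ (COP_meas(t) − COP_pred(t))² / N )
                     / (max COP_meas − min COP_meas)

The Jaccard similarity treats each stance-phase COP curve as the area
under it: both curves are shifted so their first sample is zero (then
offset together by their common minimum so the areas are well defined),
and the index is the area under the pointwise minimum divided by the
area under the pointwise maximum.  1 means identical profiles; values
fall toward 0 as the profiles diverge.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ParameterError

_METRIC_EPS = 0.0  # exact zero-range check; callers see a clear error


@dataclass(frozen=True)
class CurvePair:
    """Measured and predicted COP series over one stance phase (cm)."""

    measured: np.ndarray
    predicted: np.ndarray
    direction: str = "AP"

    def __post_init__(self) -> None:
        m = np.asarray(self.measured, dtype=float)
        p = np.asarray(self.predicted, dtype=float)
        if m.ndim != 1 or p.ndim != 1 or len(m) != len(p):
            raise ParameterError("measured and predicted must be equal-length 1-D")
        if len(m) < 2:
            raise ParameterError("curves need at least 2 samples")
        if not (np.isfinite(m).all() and np.isfinite(p).all()):
            raise ParameterError("curves must be finite")
        object.__setattr__(self, "measured", m)
        object.__setattr__(self, "predicted", p)


def nrmse(pair: CurvePair) -> float:
    """Range-normalized RMSE in percent; N is the pair's sample count."""
    m, p = pair.measured, pair.predicted
    rng = m.max() - m.min()
    if rng <= _METRIC_EPS:
        raise ParameterError("measured curve has zero range: NRMSE undefined")
    rmse = float(np.sqrt(np.mean((m - p) ** 2)))
    return 100.0 * rmse / float(rng)


def jaccard(pair: CurvePair) -> float:
    """Area-based Jaccard index of two aligned COP curves, in [0, 1].

    Both curves are zero-shifted at their origin; a common offset by
    the joint minimum makes them non-negative so the trapezoidal areas
    of the pointwise min (intersection) and max (union) are meaningful.
    Two identically-zero curves give 1 by convention.
    """
    a = pair.measured - pair.measured[0]
    b = pair.predicted - pair.predicted[0]
    lo = min(a.min(), b.min())
    a = a - lo
    b = b - lo
    inter = float(np.trapezoid(np.minimum(a, b)))
    union = float(np.trapezoid(np.maximum(a, b)))
    if union == 0.0:
        return 1.0
    return inter / union


def aggregate(per_step: pd.DataFrame) -> pd.DataFrame:
    """Aggregate per-step metric values into a per-combination table.

    Expects columns ``sites`` (e.g. ``"H+T"``), ``direction``,
    ``metric`` and ``value``; returns one row per
    (sites, direction, metric) with mean, sample SD and n, ordered by
    subset size then lexically.  Groups with a single value report
    SD = 0 and carry ``n = 1``; empty groups are simply absent (with a
    warning if the input is empty).
    """
    required = {"sites", "direction", "metric", "value"}
    missing = required - set(per_step.columns)
    if missing:
        raise ParameterError(f"per_step table missing columns {sorted(missing)}")
    if per_step.empty:
        warnings.warn("aggregate: empty per-step table", stacklevel=2)
        return pd.DataFrame(columns=["sites", "direction", "metric", "mean", "sd", "n"])
    rows = []
    for (sites, direction, metric), grp in per_step.groupby(
        ["sites", "direction", "metric"], sort=False
    ):
        vals = grp["value"].to_numpy(dtype=float)
        sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
        rows.append(
            {
                "sites": sites,
                "direction": direction,
                "metric": metric,
                "mean": float(np.mean(vals)),
                "sd": sd,
                "n": len(vals),
            }
        )
    out = pd.DataFrame(rows)
    out["_size"] = out["sites"].str.count(r"\+") + 1
    out = out.sort_values(["_size", "sites", "direction", "metric"]).drop(columns="_size")
    return out.reset_index(drop=True)
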