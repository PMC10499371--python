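"""Equity and coverage diagnostics for a designed sensor network.

Summaries follow the reporting style of monitoring-network audits: the mean
and median of the equity metric over the selected cells, the fraction of
sensors in majority (s >= 0.5) cells, median income on the raw dollar
scale, and the network's mean long-term pollutant level.  Cumulative
frequency distributions compare the network against a dense uniform
baseline — one sensor in every grid cell — which is what an idealized,
bias-free network would sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .field_data import FieldMatrix, GridGeometry
from .placement import PlacementResult

__all__ = ["NetworkSummary", "sensor_cdf", "network_summary", "coverage_of_events"]


@dataclass(frozen=True)
class NetworkSummary:
    """Per-network statistics over the selected cells only."""

    n_sensors: int
    mean_s: float
    median_s: float
    majority_fraction: float          # fraction of sensors with s >= 0.5
    median_income: float | None = None  # raw (un-inverted) scale
    mean_field: float | None = None     # mean long-term-average concentration

    def as_dict(self) -> dict:
        return {
            "n_sensors": self.n_sensors,
            "mean_s": self.mean_s,
            "median_s": self.median_s,
            "majority_fraction": self.majority_fraction,
            "median_income": self.median_income,
            "mean_field": self.mean_field,
        }


def _sensor_positions(placement: PlacementResult, geometry: GridGeometry) -> np.ndarray:
    return geometry.index_of(placement.pivots)


def _ecdf(values: np.ndarray) -> pd.DataFrame:
    values = np.sort(np.asarray(values, dtype=float))
    k = values.size
    return pd.DataFrame({"value": values, "cumulative_frequency": np.arange(1, k + 1) / k})


def sensor_cdf(
    placement: PlacementResult,
    metric: np.ndarray,
    geometry: GridGeometry,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cumulative frequency distribution of a per-cell metric at the sensors.

    Returns ``(network, baseline)`` ECDFs with plotting positions ``i/k``
    (right-continuous).  The baseline is the dense uniform network over all
    unmasked cells.
    """
    if placement.k == 0:
        raise ValueError("empty placement")
    metric = np.asarray(metric, dtype=float)
    if metric.shape[0] != geometry.n_cells:
        raise ValueError("metric must align with geometry")
    pos = _sensor_positions(placement, geometry)
    return _ecdf(metric[pos]), _ecdf(metric)


def network_summary(
    placement: PlacementResult,
    s: np.ndarray,
    geometry: GridGeometry,
    income: np.ndarray | None = None,
    field: FieldMatrix | None = None,
) -> NetworkSummary:
    """Equity statistics of a sensor network.

    ``s`` is the rescaled metric (1 = most nonwhite / lowest income);
    income, when supplied, is reported as a median on the raw scale; the
    field contributes the network's mean long-term (time-mean)
    concentration.
    """
    s = np.asarray(s, dtype=float)
    if s.shape[0] != geometry.n_cells:
        raise ValueError("s must align with geometry")
    pos = _sensor_positions(placement, geometry)
    s_sel = s[pos]
    median_income = None
    if income is not None:
        income = np.asarray(income, dtype=float)
        if income.shape[0] != geometry.n_cells:
            raise ValueError("income must align with geometry")
        median_income = float(np.median(income[pos]))
    mean_field = None
    if field is not None:
        if field.geometry.n_cells != geometry.n_cells:
            raise ValueError("field must align with geometry")
        mean_field = float(field.X.mean(axis=1)[pos].mean())
    return NetworkSummary(
        n_sensors=int(placement.k),
        mean_s=float(s_sel.mean()),
        median_s=float(np.median(s_sel)),
        majority_fraction=float(np.mean(s_sel >= 0.5)),
        median_income=median_income,
        mean_field=mean_field,
    )


def coverage_of_events(
    placement: PlacementResult,
    ground_truth: pd.DataFrame,
    geometry: GridGeometry,
    radius: int = 2,
) -> float:
    """Fraction of planted events with a sensor within a Chebyshev radius."""
    if len(ground_truth) == 0:
        raise ValueError("empty ground truth")
    pos = _sensor_positions(placement, geometry)
    rows, cols = geometry.rows[pos], geometry.cols[pos]
    covered = 0
    for _, ev in ground_truth.iterrows():
        cheb = np.maximum(
            np.abs(rows - int(ev["center_row"])), np.abs(cols - int(ev["center_col"]))
        )
        covered += int(cheb.min() <= radius)
    return covered / len(ground_truth)


def plot_sensor_cdf(network: pd.DataFrame, baseline: pd.DataFrame, ax=None, label="network"):
    """ECDF of the network against the dense uniform baseline."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.step(network["value"], network["cumulative_frequency"], where="post", label=label)
    ax.step(
        baseline["value"],
        baseline["cumulative_frequency"],
        where="post",
        linestyle="--",
        label="dense uniform",
    )
    ax.set_xlabel("metric value")
    ax.set_ylabel("cumulative frequency")
    ax.legend()
    return ax


def plot_sensor_map(placement: PlacementResult, s: np.ndarray, geometry: GridGeometry, ax=None):
    """Sensors scattered over the equity-metric surface."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = geometry.unflatten(np.asarray(s, dtype=float))
    im = ax.imshow(grid, origin="upper", cmap="viridis", vmin=0, vmax=1)
    pos = _sensor_positions(placement, geometry)
    ax.scatter(geometry.cols[pos], geometry.rows[pos], s=18, c="red", marker="o", edgecolors="white")
    ax.figure.colorbar(im, ax=ax, label="equity metric s")
    return ax
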