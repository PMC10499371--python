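"""Synthetic city: a gridded pollutant field plus segregated demographics.

Emulates the structure the placement method assumes in real data — a
seasonal + slowly trending urban background with an urban-core
concentration bump, localized transient pollution events on dyadic
timescales (8 days up to years, mirroring the decomposition's window
ladder), independent Gaussian cell-day noise, and spatially segregated
demographic surfaces (nonwhite proportion in [0, 1], income anti-correlated
with it).  Components are kept separately so ``field = background + events
+ noise`` holds exactly and every planted event is available as ground
truth for validation.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .field_data import FieldMatrix, GridGeometry

__all__ = ["EventSpec", "CityConfig", "SyntheticCity", "generate_city", "plant_event"]

DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class EventSpec:
    """A localized transient: space-time Gaussian bump, boxcar in time."""

    center: tuple[int, int]     # (row, col)
    sigma: float                # spatial extent, cells
    start: int                  # day index
    duration: int               # days; dyadic durations align with the window ladder
    amplitude: float            # peak enhancement, ug m-3


#: Default episode set: six events across the dyadic timescale ladder with
#: peak enhancements in the 10-40 ug m-3 range typical of urban pollution
#: episodes (haze events, inversions, industrial releases), from short
#: 8-day episodes to a years-long smoulder.
DEFAULT_EVENTS = (
    EventSpec(center=(6, 6), sigma=2.0, start=300, duration=8, amplitude=40.0),
    EventSpec(center=(24, 9), sigma=2.5, start=1000, duration=16, amplitude=30.0),
    EventSpec(center=(8, 25), sigma=2.0, start=1800, duration=32, amplitude=25.0),
    EventSpec(center=(25, 25), sigma=3.0, start=2500, duration=64, amplitude=20.0),
    EventSpec(center=(16, 4), sigma=2.5, start=1200, duration=256, amplitude=15.0),
    EventSpec(center=(10, 16), sigma=3.0, start=2048, duration=1024, amplitude=10.0),
)


@dataclass(frozen=True)
class CityConfig:
    """Generator settings.  Defaults give a 32 x 32 city observed daily for 4096 days.

    Concentrations are in ug m-3.  ``background_mean`` ~ 10 with a +/- 3
    seasonal cycle and a slow decline mimic a decade of urban fine-particle
    data; ``noise_sigma`` = 2 is day-to-day weather-driven scatter.
    """

    n_rows: int = 32
    n_cols: int = 32
    n_days: int = 4096
    background_mean: float = 10.0
    seasonal_amplitude: float = 3.0
    seasonal_phase: float = 0.0          # day of maximum offset, shifts the sinusoid
    seasonal_period: float = DAYS_PER_YEAR
    trend_per_year: float = -0.2
    core_center: tuple[int, int] = (16, 16)
    core_width: float = 6.0              # cells
    core_height: float = 4.0             # ug m-3 static urban-core enhancement
    events: tuple[EventSpec, ...] = DEFAULT_EVENTS
    noise_sigma: float = 2.0
    demographics: str = "quadrant"       # quadrant | gradient | two_cluster
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_rows < 2 or self.n_cols < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.n_days < 2:
            raise ValueError("n_days must be >= 2")
        if self.demographics not in ("quadrant", "gradient", "two_cluster"):
            raise ValueError(f"unknown demographics pattern {self.demographics!r}")
        for ev in self.events:
            r, c = ev.center
            if not (0 <= r < self.n_rows and 0 <= c < self.n_cols):
                raise ValueError(f"event center {ev.center} outside grid")
            if ev.duration <= 0:
                raise ValueError("event duration must be positive")
            if ev.start < 0 or ev.start + ev.duration > self.n_days:
                raise ValueError(f"event at day {ev.start} (+{ev.duration}) outside time range")


@dataclass
class SyntheticCity:
    """Generated field, demographic surfaces, and ground truth."""

    field: FieldMatrix
    s_race: np.ndarray           # nonwhite metric in [0, 1], aligned to geometry
    income: np.ndarray           # median household income, > 0
    ground_truth: pd.DataFrame   # one row per planted event
    components: dict             # background / events / noise, each n_cells x n_days
    config: CityConfig

    @property
    def geometry(self) -> GridGeometry:
        return self.field.geometry


def _spatial_gaussian(geometry: GridGeometry, center: tuple[int, int], sigma: float) -> np.ndarray:
    d2 = (geometry.rows - center[0]) ** 2 + (geometry.cols - center[1]) ** 2
    return np.exp(-d2 / (2.0 * sigma**2))


def plant_event(
    components: dict,
    ground_truth: list,
    geometry: GridGeometry,
    center: tuple[int, int],
    sigma: float,
    start: int,
    duration: int,
    amplitude: float,
) -> None:
    """Add one space-time Gaussian event to the events component (in place).

    The enhancement is ``amplitude * exp(-d^2 / (2 sigma^2))`` at grid
    distance ``d`` from the center, held for ``duration`` days from
    ``start``; the event is appended to the ground-truth manifest.
    """
    n_days = components["events"].shape[1]
    if not (0 <= center[0] < geometry.n_rows and 0 <= center[1] < geometry.n_cols):
        raise ValueError(f"event center {center} outside grid")
    if start < 0 or duration <= 0 or start + duration > n_days:
        raise ValueError("event outside time range")
    profile = amplitude * _spatial_gaussian(geometry, center, sigma)
    components["events"][:, start : start + duration] += profile[:, None]
    ground_truth.append(
        {
            "event": len(ground_truth),
            "center_row": center[0],
            "center_col": center[1],
            "sigma": sigma,
            "start": start,
            "duration": duration,
            "amplitude": amplitude,
        }
    )


def _demographic_surface(config: CityConfig, rng: np.random.Generator) -> np.ndarray:
    """Segregated nonwhite-metric grid in [0, 1], smoothed at the edges."""
    nr, nc = config.n_rows, config.n_cols
    if config.demographics == "quadrant":
        s = np.full((nr, nc), 0.1)
        s[: nr // 2, : nc // 2] = 0.9
    elif config.demographics == "gradient":
        s = np.tile(np.linspace(0.9, 0.1, nc), (nr, 1))
    else:  # two_cluster
        geometry = GridGeometry(nr, nc, np.arange(nr * nc))
        s = np.full((nr, nc), 0.1)
        for center in ((nr // 4, nc // 4), (3 * nr // 4, 3 * nc // 4)):
            s += 0.8 * _spatial_gaussian(geometry, center, min(nr, nc) / 6).reshape(nr, nc)
    s = gaussian_filter(s, sigma=1.0, mode="nearest")
    s = s + rng.normal(0.0, 0.03, size=s.shape)
    return np.clip(s, 0.0, 1.0)


def generate_city(config: CityConfig | None = None) -> SyntheticCity:
    """Deterministically generate a synthetic city from a config and seed."""
    config = config or CityConfig()
    rng = np.random.default_rng(config.seed)
    nr, nc, T = config.n_rows, config.n_cols, config.n_days
    geometry = GridGeometry(n_rows=nr, n_cols=nc, cell_ids=np.arange(nr * nc))
    n_cells = geometry.n_cells

    t = np.arange(T, dtype=float)
    seasonal = config.seasonal_amplitude * np.sin(
        2.0 * np.pi * (t - config.seasonal_phase) / config.seasonal_period
    )
    trend = config.trend_per_year * t / DAYS_PER_YEAR
    core = config.core_height * _spatial_gaussian(geometry, config.core_center, config.core_width)
    background = (config.background_mean + core)[:, None] + (seasonal + trend)[None, :]

    components = {
        "background": background,
        "events": np.zeros((n_cells, T)),
        "noise": rng.normal(0.0, config.noise_sigma, size=(n_cells, T))
        if config.noise_sigma > 0
        else np.zeros((n_cells, T)),
    }
    truth: list[dict] = []
    for ev in config.events:
        plant_event(
            components, truth, geometry, ev.center, ev.sigma, ev.start, ev.duration, ev.amplitude
        )

    X = components["background"] + components["events"] + components["noise"]
    field = FieldMatrix(X=X, geometry=geometry, dt=1.0, time_origin="day 0")

    s_grid = _demographic_surface(config, rng)
    s_race = s_grid.reshape(-1)[geometry.cell_ids]
    # income anti-correlated with the race metric plus household-level scatter
    income = 20_000.0 + 120_000.0 * (1.0 - s_race) + rng.normal(0.0, 5_000.0, size=n_cells)
    income = np.clip(income, 5_000.0, None)

    ground_truth = pd.DataFrame(
        truth,
        columns=["event", "center_row", "center_col", "sigma", "start", "duration", "amplitude"],
    )
    return SyntheticCity(
        field=field,
        s_race=s_race,
        income=income,
        ground_truth=ground_truth,
        components=components,
        config=config,
    )
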