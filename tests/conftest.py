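"""Shared fixtures.

The default synthetic city (32 x 32 cells, 4096 days, six planted events)
and its decomposition are expensive, so they are computed once per session
and shared by the module and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import mrdmdcc as m
from mrdmdcc.mrdmd import ModalLibrary


def make_library(matrix: np.ndarray) -> ModalLibrary:
    """Wrap a plain matrix as a modal library (cells x modes)."""
    matrix = np.asarray(matrix, dtype=float)
    return ModalLibrary(matrix=matrix, provenance=pd.DataFrame(index=range(matrix.shape[1])))


@pytest.fixture(scope="session")
def default_city() -> m.SyntheticCity:
    return m.generate_city()  # default config, seed 0


@pytest.fixture(scope="session")
def default_library(default_city) -> ModalLibrary:
    config = m.DecompositionConfig()
    tree = m.mrdmd_decompose(default_city.field, config)
    return m.build_library(tree, config, default_city.geometry)


@pytest.fixture(scope="session")
def step_cost(default_city) -> m.CostSurface:
    return m.build_penalty(default_city.s_race, mode="step", threshold=0.5, metric_name="race")


@pytest.fixture(scope="session")
def gamma_placements(default_library, step_cost) -> dict[float, m.PlacementResult]:
    """Cost-constrained placements of 250 sensors across the gamma ladder."""
    out = {}
    for gamma in (0.0, 0.1, 0.25, 0.3, 0.5):
        out[gamma] = m.cc_pivot_select(
            default_library, step_cost, m.PlacementConfig(k=250, gamma=gamma)
        )
    return out


@pytest.fixture(scope="session")
def two_tone() -> dict:
    """Annual sinusoid (pattern peaked at (4, 4)) + one 8-day transient at (12, 10).

    The transient is aligned to a finest-level window of the (M=512, L=7)
    ladder and the seasonal phase is nonzero, as in any realistic series.
    """
    nr = nc = 16
    T = 512
    geometry = m.GridGeometry(nr, nc, np.arange(nr * nc))
    t = np.arange(T, dtype=float)
    rows, cols = geometry.rows, geometry.cols
    annual_pattern = np.exp(-((rows - 4) ** 2 + (cols - 4) ** 2) / (2 * 3.0**2))
    smooth = 10.0 + 3.0 * annual_pattern[:, None] * np.sin(
        2 * np.pi * (t + 100.0) / 365.25
    )[None, :]
    center = (12, 10)
    amplitude = 30.0
    event_pattern = amplitude * np.exp(
        -((rows - center[0]) ** 2 + (cols - center[1]) ** 2) / (2 * 1.5**2)
    )
    start, duration = 304, 8
    X = smooth.copy()
    X[:, start : start + duration] += event_pattern[:, None]
    field = m.FieldMatrix(X=X, geometry=geometry)
    config = m.DecompositionConfig(levels=7, training_window=512)
    tree = m.mrdmd_decompose(field, config)
    return {
        "field": field,
        "smooth": smooth,
        "tree": tree,
        "config": config,
        "center": center,
        "center_flat": center[0] * nc + center[1],
        "start": start,
        "duration": duration,
        "amplitude": amplitude,
        "n_cols": nc,
    }
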