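"""Environmental-justice metrics and the sensor-placement penalty vector.

Census-style surfaces are rescaled to a per-cell metric ``s`` in [0, 1]
where 1 marks the communities the network should prioritize (most nonwhite,
or lowest income after inversion).  The cost-constrained pivot subtracts
``gamma * eta`` from each candidate's score, so the penalty ``eta`` must be
LOW where ``s`` is high: the default step penalty is 0 inside majority
(``s >= tau``) cells and 1 elsewhere, and a linear variant ``eta = 1 - s``
is exposed because the exact shape of the step is a modelling choice.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["CostSurface", "rescale_nonwhite", "rescale_income", "build_penalty"]


@dataclass(frozen=True)
class CostSurface:
    """Rescaled social metric ``s`` and its derived penalty ``eta``."""

    s: np.ndarray
    eta: np.ndarray
    mode: str
    metric_name: str = "custom"
    threshold: float | None = None

    def __post_init__(self) -> None:
        s = np.asarray(self.s, dtype=float)
        eta = np.asarray(self.eta, dtype=float)
        object.__setattr__(self, "s", s)
        object.__setattr__(self, "eta", eta)
        if s.shape != eta.shape or s.ndim != 1:
            raise ValueError("s and eta must be aligned 1-D vectors")
        if np.any(s < 0) or np.any(s > 1) or not np.all(np.isfinite(s)):
            raise ValueError("s must lie in [0, 1]")
        if np.any(eta < 0) or not np.all(np.isfinite(eta)):
            raise ValueError("eta must be non-negative")
        if self.mode == "step" and not np.all(np.isin(eta, (0.0, 1.0))):
            raise ValueError("step-mode eta must be 0/1")

    @property
    def n_cells(self) -> int:
        return self.s.size


def rescale_nonwhite(white_prop: np.ndarray) -> np.ndarray:
    """Nonwhite proportion: ``s = 1 - white_prop``.

    ``s = 1`` is an all-nonwhite cell, ``s = 0`` all non-Hispanic White.
    """
    white_prop = np.asarray(white_prop, dtype=float)
    if np.any(white_prop < 0) or np.any(white_prop > 1) or not np.all(np.isfinite(white_prop)):
        raise ValueError("white_prop must lie in [0, 1]")
    return 1.0 - white_prop


def rescale_income(income: np.ndarray, income_max: float | None = None) -> np.ndarray:
    """Invert and normalize income so 0 = highest income, 1 = lowest.

    ``s = 1 - min(income, income_max) / income_max``.  ``income_max`` is a
    per-city cap (a census top-code such as $250,000); it defaults to the
    observed maximum of the supplied surface.
    """
    income = np.asarray(income, dtype=float)
    if np.any(income < 0) or not np.all(np.isfinite(income)):
        raise ValueError("income must be non-negative and finite")
    if income_max is None:
        income_max = float(income.max())
    if income_max <= 0:
        raise ValueError("income_max must be positive")
    return np.clip(1.0 - np.minimum(income, income_max) / income_max, 0.0, 1.0)


def build_penalty(
    s: np.ndarray,
    mode: str = "step",
    threshold: float = 0.5,
    metric_name: str = "custom",
) -> CostSurface:
    """Turn the metric ``s`` into a penalty vector.

    step mode: ``eta_i = 0`` where ``s_i >= threshold`` (no penalty inside
    majority/target communities), else 1.  linear mode: ``eta_i = 1 - s_i``.
    Both are monotone non-increasing in ``s``.
    """
    s = np.asarray(s, dtype=float)
    if np.any(s < 0) or np.any(s > 1) or not np.all(np.isfinite(s)):
        raise ValueError("s must lie in [0, 1]")
    if mode == "step":
        if not (0.0 < threshold < 1.0):
            raise ValueError("threshold must lie in (0, 1)")
        eta = np.where(s >= threshold, 0.0, 1.0)
        return CostSurface(s=s, eta=eta, mode="step", threshold=threshold, metric_name=metric_name)
    if mode == "linear":
        return CostSurface(s=s, eta=1.0 - s, mode="linear", metric_name=metric_name)
    raise ValueError(f"mode must be 'step' or 'linear', got {mode!r}")
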