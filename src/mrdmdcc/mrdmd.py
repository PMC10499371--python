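"""Multiresolution DMD over dyadic windows and assembly of the modal library.

The recursion halves the time domain at each level: level 1 spans the whole
training window of ``M`` snapshots, level ``l`` has ``2^(l-1)`` windows.  At
each node a DMD is run on the current *residual*; modes slow enough to
complete at most ``slow_cycles`` oscillations within the window
(``freq <= slow_cycles / (m dt)``) are retained as that node's slow set and
their reconstruction is subtracted before recursing on the two halves.
Coarse levels therefore hold background and seasonal structure while
short transient events surface only in the fine windows that contain them.

All retained modes are stacked into a real modal library ``psi_r`` (one
column per real mode, two — Re and Im — per complex-conjugate pair), the
tailored basis that QR pivoting consumes.  With daily data, an ``M = 4096``
window and 10 levels span timescales from 11.2 years down to 8 days.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .dmd import DMDResult, RankRule, dmd, reconstruct
from .field_data import CSV_HEADER_NOTE, FieldMatrix, GridGeometry

logger = logging.getLogger(__name__)

__all__ = [
    "DecompositionConfig",
    "MrDMDNode",
    "ModalLibrary",
    "window_schedule",
    "mrdmd_decompose",
    "build_library",
]

#: relative tolerance treating an eigenvalue as real / a frequency as slow
_IMAG_TOL = 1e-10


@dataclass(frozen=True)
class DecompositionConfig:
    """Knobs of the multiresolution decomposition.

    ``training_window`` (M, snapshots) and ``levels`` (L) set the dyadic
    ladder; M >= 3 * 2^(L-1) is recommended so every leaf window supports a
    DMD.  ``slow_cycles`` (rho) is the slow-mode criterion: keep modes with
    at most rho oscillations per window.  ``stride`` > 1 would subsample
    coarse windows; it defaults off so results are exactly reproducible.
    """

    levels: int = 10
    training_window: int = 4096
    slow_cycles: float = 1.0
    rank_rule: RankRule = field(default_factory=RankRule)
    library_representation: str = "split_complex"  # or "magnitude"
    column_weighting: str = "unit"  # or "amplitude"
    fit_all_snapshots: bool = False
    stride: int = 1

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ValueError("levels must be >= 1")
        if self.training_window < 2:
            raise ValueError("training_window must be >= 2")
        if self.slow_cycles <= 0:
            raise ValueError("slow_cycles must be positive")
        if self.library_representation not in ("split_complex", "magnitude"):
            raise ValueError("library_representation must be split_complex or magnitude")
        if self.column_weighting not in ("unit", "amplitude"):
            raise ValueError("column_weighting must be unit or amplitude")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")


@dataclass
class MrDMDNode:
    """One dyadic window: its slow modes and (0 or 2) child windows."""

    level: int
    window: tuple[int, int]
    slow: DMDResult
    children: list["MrDMDNode"] = field(default_factory=list)

    def walk(self):
        """Preorder traversal (coarse to fine, left to right)."""
        yield self
        for child in self.children:
            yield from child.walk()

    @property
    def n_modes_total(self) -> int:
        return sum(node.slow.rank for node in self.walk())


@dataclass
class ModalLibrary:
    """Real ``n_cells x r_total`` basis with per-column provenance.

    Provenance columns: level, window_index (position of the window within
    its level), window_start, window_end, frequency (cycles/day),
    abs_lambda, abs_b, component (re|im|mag).
    """

    matrix: np.ndarray
    provenance: pd.DataFrame
    geometry: GridGeometry | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] == 0:
            raise ValueError("library must be 2-D with at least one column")
        if len(self.provenance) != self.matrix.shape[1]:
            raise ValueError("provenance length must equal number of columns")
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("library has non-finite entries")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def r_total(self) -> int:
        return self.matrix.shape[1]

    def to_csv(self, path, provenance_path=None) -> None:
        """Export the basis (rows = cells) and, optionally, its provenance."""
        with open(path, "w") as fh:
            fh.write(CSV_HEADER_NOTE)
            df = pd.DataFrame(self.matrix, columns=[f"mode_{j}" for j in range(self.r_total)])
            if self.geometry is not None:
                df.insert(0, "cell_id", self.geometry.cell_ids)
                df.insert(1, "cell_row", self.geometry.rows)
                df.insert(2, "cell_col", self.geometry.cols)
            df.to_csv(fh, index=False)
        if provenance_path is not None:
            self.provenance.to_csv(provenance_path, index=False)

    @classmethod
    def from_csv(cls, path, provenance_path=None) -> "ModalLibrary":
        """Load a basis written by :meth:`to_csv`.

        Grid extent is inferred from the largest row/col present, so a
        fully masked trailing row or column cannot be recovered; pivot cell
        ids are unaffected.
        """
        df = pd.read_csv(path, comment="#")
        geometry = None
        if {"cell_id", "cell_row", "cell_col"} <= set(df.columns):
            n_rows = int(df["cell_row"].max()) + 1
            n_cols = int(df["cell_col"].max()) + 1
            geometry = GridGeometry(n_rows, n_cols, df["cell_id"].to_numpy(dtype=np.int64))
            df = df.drop(columns=["cell_id", "cell_row", "cell_col"])
        provenance = (
            pd.read_csv(provenance_path)
            if provenance_path is not None
            else pd.DataFrame(index=range(df.shape[1]))
        )
        return cls(matrix=df.to_numpy(dtype=float), provenance=provenance, geometry=geometry)


def window_schedule(M: int, L: int) -> list[tuple[int, int, int]]:
    """Dyadic window layout: ``(level, start, end)`` triples.

    Level 1 is ``[0, M)``; each window splits into floor halves at the next
    level, so level ``l`` tiles ``[0, M)`` with ``2^(l-1)`` windows.
    """
    if M < 2:
        raise ValueError("M must be >= 2")
    if L < 1:
        raise ValueError("L must be >= 1")
    schedule = [(1, 0, M)]
    frontier = [(0, M)]
    for level in range(2, L + 1):
        nxt = []
        for start, end in frontier:
            mid = start + (end - start) // 2
            nxt.extend([(start, mid), (mid, end)])
        if any(end - start < 2 for start, end in nxt):
            raise ValueError(
                f"finest window shorter than 2 snapshots at level {level} (M={M}, L={L})"
            )
        schedule.extend((level, s, e) for s, e in nxt)
        frontier = nxt
    return schedule


def _slow_subset(result: DMDResult, cutoff: float) -> DMDResult:
    keep = result.freq <= cutoff * (1 + 1e-12) + _IMAG_TOL
    return replace(
        result,
        modes=result.modes[:, keep],
        eigenvalues=result.eigenvalues[keep],
        freq=result.freq[keep],
        amplitudes=result.amplitudes[keep],
        rank=int(np.count_nonzero(keep)),
    )


def mrdmd_decompose(field_matrix: FieldMatrix, config: DecompositionConfig) -> MrDMDNode:
    """Recursive decomposition of the last ``training_window`` snapshots.

    Window indices in the returned tree are relative to the start of the
    training window.  Each node's DMD runs on the residual left by all
    coarser levels; the residual remaining after every level is attached to
    the root as ``root.final_residual`` for diagnostics.
    """
    M, L = config.training_window, config.levels
    if field_matrix.n_times < M:
        raise ValueError(f"field has {field_matrix.n_times} snapshots, needs >= {M}")
    window_schedule(M, L)  # validates the (M, L) pair up front
    offset = field_matrix.n_times - M
    residual = field_matrix.window(offset, field_matrix.n_times).copy()
    dt = field_matrix.dt

    def recurse(level: int, start: int, end: int) -> MrDMDNode:
        m = end - start
        sub = residual[:, start:end:config.stride]
        slow = DMDResult.empty(field_matrix.n_cells, window=(start, end), level=level)
        if sub.shape[1] >= 3 and np.any(sub):
            try:
                full = dmd(
                    sub,
                    rank_rule=config.rank_rule,
                    dt=dt * config.stride,
                    window=(start, end),
                    level=level,
                    fit_all_snapshots=config.fit_all_snapshots,
                )
            except ValueError as exc:
                logger.info("level %d window [%d, %d): DMD skipped (%s)", level, start, end, exc)
                full = slow
            cutoff = config.slow_cycles / (m * dt)
            slow = _slow_subset(full, cutoff)
            if not slow.is_empty:
                if config.stride > 1:
                    # resample the slow dynamics on the un-strided time axis
                    lam = slow.eigenvalues ** (1.0 / config.stride)
                    recon = reconstruct(replace(slow, eigenvalues=lam), m)
                else:
                    recon = reconstruct(slow, m)
                residual[:, start:end] -= recon
                if not np.all(np.isfinite(residual[:, start:end])):
                    raise FloatingPointError(
                        f"non-finite residual at level {level} window [{start}, {end})"
                    )
        else:
            logger.info("level %d window [%d, %d): too short or zero, stored empty", level, start, end)
        node = MrDMDNode(level=level, window=(start, end), slow=slow)
        if level < L:
            mid = start + m // 2
            node.children = [recurse(level + 1, start, mid), recurse(level + 1, mid, end)]
        return node

    root = recurse(1, 0, M)
    root.final_residual = residual  # diagnostics: what no level captured
    return root


def _phase_align(column: np.ndarray) -> np.ndarray:
    """Rotate a complex mode so its largest-magnitude entry is real positive."""
    i = int(np.argmax(np.abs(column)))
    phase = column[i] / abs(column[i]) if column[i] != 0 else 1.0
    return column / phase


def build_library(
    tree: MrDMDNode, config: DecompositionConfig, geometry: GridGeometry | None = None
) -> ModalLibrary:
    """Stack all retained modes into the real basis ``psi_r``.

    In the default ``split_complex`` representation a real mode contributes
    Re(phi); each complex-conjugate pair contributes Re(phi) and Im(phi)
    from the member with non-negative frequency, so no information is
    duplicated or lost.  ``magnitude`` keeps a single |phi| column per kept
    mode.  Columns are unit-normalized (``unit`` weighting) or scaled by
    |b| (``amplitude``).  Traversal order is deterministic: preorder,
    coarse to fine, left to right, mode index within a node.
    """
    columns: list[np.ndarray] = []
    records: list[dict] = []
    window_index: dict[int, dict[tuple[int, int], int]] = {}
    for node in tree.walk():
        per_level = window_index.setdefault(node.level, {})
        per_level.setdefault(node.window, len(per_level))
        res = node.slow
        if res.is_empty:
            continue
        for j in range(res.rank):
            lam = res.eigenvalues[j]
            if lam.imag < -_IMAG_TOL * abs(lam):
                continue  # negative-frequency member of a conjugate pair
            phi = _phase_align(res.modes[:, j])
            meta = {
                "level": node.level,
                "window_index": per_level[node.window],
                "window_start": node.window[0],
                "window_end": node.window[1],
                "frequency": float(res.freq[j]),
                "abs_lambda": float(abs(lam)),
                "abs_b": float(abs(res.amplitudes[j])),
            }
            is_complex = lam.imag > _IMAG_TOL * abs(lam)
            if config.library_representation == "magnitude":
                parts = [("mag", np.abs(phi))]
            elif is_complex:
                parts = [("re", phi.real), ("im", phi.imag)]
            else:
                parts = [("re", phi.real)]
            for component, col in parts:
                norm = float(np.linalg.norm(col))
                if norm <= 1e-14:
                    continue
                col = col / norm
                if config.column_weighting == "amplitude":
                    col = col * meta["abs_b"]
                columns.append(col)
                records.append({**meta, "component": component})
    if not columns:
        raise ValueError("decomposition retained no modes; cannot build a library")
    return ModalLibrary(
        matrix=np.column_stack(columns),
        provenance=pd.DataFrame.from_records(records),
        geometry=geometry,
    )
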