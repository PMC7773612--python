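"""Spatial constituent maps: grid assembly, neighbour-mean fill, interpolation.

Per-location constituent values (measured or PLS-predicted) are placed on the
measurement lattice — a 9x14 grid for the mapped specimen, of which 55 cells
carry measurements because the probe cannot reach specimen edges.  Unmeasured
cells adjacent to valued cells are imputed as the mean of their valued
neighbours, sweeping until no reachable cell remains.  The filled grid is
centred in a square zero canvas (default 20x20) and bilinearly interpolated on
the node lattice at a configurable spacing; the default spacing 0.01 turns a
20x20 canvas into a 1901x1901 pixel map ((20-1)/0.01 + 1 per side).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator

__all__ = [
    "GridMap",
    "CanvasMap",
    "assemble_grid",
    "fill_missing_neighbors",
    "embed_and_interpolate",
    "error_map",
]

MEASURED, IMPUTED, BACKGROUND = "measured", "imputed", "background"


@dataclass
class GridMap:
    """Sparse constituent grid: values, measured mask, per-cell provenance."""

    values: np.ndarray
    measured: np.ndarray
    provenance: np.ndarray  # object array of {measured, imputed, background}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.measured = np.asarray(self.measured, dtype=bool)
        if self.values.shape != self.measured.shape or self.values.shape != self.provenance.shape:
            raise ValueError("values, mask and provenance shapes must agree")
        if np.any(self.measured & (self.provenance != MEASURED)):
            raise ValueError("measured cells must carry 'measured' provenance")
        valued = self.provenance != BACKGROUND
        if not np.all(np.isfinite(self.values[valued])):
            raise ValueError("measured/imputed cells must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def copy(self) -> "GridMap":
        return GridMap(self.values.copy(), self.measured.copy(), self.provenance.copy())


@dataclass
class CanvasMap:
    """Grid embedded in a square canvas plus its interpolated high-res map."""

    canvas: np.ndarray
    interpolated: np.ndarray
    spacing: float
    offset: tuple[int, int]
    background: float = 0.0


def assemble_grid(
    predictions: np.ndarray,
    coordinates: list[tuple[int, int]],
    shape: tuple[int, int] = (9, 14),
) -> GridMap:
    """Place per-location values onto the grid; remaining cells are unmeasured."""
    predictions = np.asarray(predictions, dtype=float).ravel()
    if len(coordinates) != predictions.size:
        raise ValueError("one coordinate per prediction required")
    if len(set(coordinates)) != len(coordinates):
        raise ValueError("duplicate grid coordinate")
    values = np.full(shape, np.nan)
    measured = np.zeros(shape, dtype=bool)
    prov = np.full(shape, BACKGROUND, dtype=object)
    for v, (r, c) in zip(predictions, coordinates):
        if not (0 <= r < shape[0] and 0 <= c < shape[1]):
            raise ValueError(f"coordinate ({r}, {c}) outside grid {shape}")
        values[r, c] = v
        measured[r, c] = True
        prov[r, c] = MEASURED
    return GridMap(values, measured, prov)


def fill_missing_neighbors(grid: GridMap, connectivity: int = 4) -> GridMap:
    """Impute unmeasured cells as the mean of their valued neighbours.

    Sweeps repeat until no unmeasured cell touches a valued cell, so interior
    holes reachable only through imputed cells are filled too; each sweep is
    computed from the previous state only, making the result order-
    independent.  Cells never reached keep background provenance.  Default
    neighbourhood is 4-connected; pass ``connectivity=8`` to include
    diagonals.
    """
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    if not grid.measured.any():
        raise ValueError("cannot impute a grid with zero measured cells")
    out = grid.copy()
    rows, cols = out.shape
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    while True:
        valued = out.provenance != BACKGROUND
        updates: list[tuple[int, int, float]] = []
        for r in range(rows):
            for c in range(cols):
                if valued[r, c]:
                    continue
                neigh = [
                    out.values[r + dr, c + dc]
                    for dr, dc in offsets
                    if 0 <= r + dr < rows and 0 <= c + dc < cols and valued[r + dr, c + dc]
                ]
                if neigh:
                    updates.append((r, c, float(np.mean(neigh))))
        if not updates:
            break
        for r, c, v in updates:
            out.values[r, c] = v
            out.provenance[r, c] = IMPUTED
    return out


def embed_and_interpolate(
    grid: GridMap,
    canvas_side: int = 20,
    spacing: float = 0.01,
    background: float = 0.0,
) -> CanvasMap:
    """Centre the grid in a square zero canvas and bilinearly interpolate.

    The canvas nodes sit at 1-based lattice coordinates 1..canvas_side; the
    interpolated map samples that lattice at ``spacing`` per axis, giving
    (canvas_side - 1)/spacing + 1 pixels per side — 1901x1901 for the default
    20-node canvas at spacing 0.01.  Background cells (and cells never reached
    by imputation) carry the background value.
    """
    rows, cols = grid.shape
    if rows > canvas_side or cols > canvas_side:
        raise ValueError(f"grid {grid.shape} does not fit a {canvas_side}x{canvas_side} canvas")
    r0 = (canvas_side - rows) // 2
    c0 = (canvas_side - cols) // 2
    canvas = np.full((canvas_side, canvas_side), float(background))
    filled = np.where(grid.provenance != BACKGROUND, grid.values, background)
    canvas[r0 : r0 + rows, c0 : c0 + cols] = filled
    nodes = np.arange(1, canvas_side + 1, dtype=float)
    n_out = int(round((canvas_side - 1) / spacing)) + 1
    fine = np.linspace(1.0, float(canvas_side), n_out)
    interp = RegularGridInterpolator((nodes, nodes), canvas, method="linear")
    rr, cc = np.meshgrid(fine, fine, indexing="ij")
    hi = interp(np.stack([rr.ravel(), cc.ravel()], axis=1)).reshape(n_out, n_out)
    return CanvasMap(canvas, hi, spacing, (r0, c0), float(background))


def error_map(measured: GridMap, predicted: GridMap) -> tuple[np.ndarray, dict]:
    """Per-cell relative percent error over measured cells, plus summary stats.

    error(r, c) = 100 * |pred - meas| / meas on cells measured in both grids;
    a zero measured value excludes the cell (noted in the summary).  Returns
    (error grid with NaN elsewhere, summary dict with min/max/mean/median and
    cell counts).
    """
    if measured.shape != predicted.shape:
        raise ValueError("grid shapes differ")
    if not np.array_equal(measured.measured, predicted.measured):
        raise ValueError("measured masks differ")
    err = np.full(measured.shape, np.nan)
    mask = measured.measured & (measured.values != 0)
    excluded = int(np.sum(measured.measured & (measured.values == 0)))
    err[mask] = 100.0 * np.abs(predicted.values[mask] - measured.values[mask]) / measured.values[mask]
    vals = err[mask]
    summary = {
        "min": float(vals.min()) if vals.size else np.nan,
        "max": float(vals.max()) if vals.size else np.nan,
        "mean": float(vals.mean()) if vals.size else np.nan,
        "median": float(np.median(vals)) if vals.size else np.nan,
        "n_cells": int(vals.size),
        "n_excluded_zero": excluded,
    }
    return err, summary


def save_canvas_map(cm: CanvasMap, prefix: str | Path) -> None:
    """Write canvas and metadata as CSV + JSON sidecar (interpolated map omitted
    from disk by default — 1901x1901 CSVs are large; regenerate on demand)."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".canvas.csv"), cm.canvas, delimiter=",")
    meta = {
        "spacing": cm.spacing,
        "offset": list(cm.offset),
        "background": cm.background,
        "interpolated_shape": list(cm.interpolated.shape),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))
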