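"""Environmental raster stacks: loading, cropping, and correlation filtering.

A :class:`RasterStack` is a set of named layers on a shared planar grid with a
shared missing-value mask.  Cells are indexed row-major from the top-left;
coordinates refer to cell centers; extents are half-open
``[xmin, xmax) x [ymin, ymax)``.

Stacks are stored on disk as a directory containing ``stack.json`` (metadata)
plus one plain-text ``<layer>.asc`` grid per layer (``nan`` marks missing
cells), so every artifact stays text-only and diffable.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

__all__ = [
    "RasterStack",
    "CorrelationReport",
    "crop_stack",
    "filter_correlated",
    "read_stack",
    "write_stack",
]


@dataclass
class RasterStack:
    """Named environmental layers on a shared grid.

    Parameters
    ----------
    names
        Unique layer names, one per band.
    values
        Array of shape ``(n_layers, n_rows, n_cols)``.
    mask
        Boolean validity mask of shape ``(n_rows, n_cols)``; ``True`` marks a
        usable cell.  Shared by all layers.
    cell_size
        Edge length of a (square) cell in map units.
    origin
        ``(x, y)`` of the grid's top-left *corner*; x grows rightward along
        columns, y shrinks downward along rows.
    crs
        Optional free-text CRS tag, carried through but never interpreted.
    """

    names: list[str]
    values: np.ndarray
    mask: np.ndarray | None = None
    cell_size: float = 1.0
    origin: tuple[float, float] = (0.0, 0.0)
    crs: str | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must have shape (n_layers, n_rows, n_cols)")
        if len(self.names) != self.values.shape[0]:
            raise ValueError("one name per layer required")
        if len(set(self.names)) != len(self.names):
            raise ValueError("layer names must be unique")
        if self.mask is None:
            self.mask = ~np.any(np.isnan(self.values), axis=0)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape[1:]:
            raise ValueError("mask shape must match grid shape")

    # -- geometry -----------------------------------------------------------

    @property
    def n_layers(self) -> int:
        return self.values.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[1:]

    @property
    def n_valid(self) -> int:
        return int(self.mask.sum())

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center coordinates as 2-D arrays over the grid."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 - (np.arange(rows) + 0.5) * self.cell_size
        return np.meshgrid(xs, ys)

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map point coordinates to (row, col) indices (may fall off-grid)."""
        x0, y0 = self.origin
        col = np.floor((np.asarray(x) - x0) / self.cell_size).astype(int)
        row = np.floor((y0 - np.asarray(y)) / self.cell_size).astype(int)
        return row, col

    def in_bounds(self, row: np.ndarray, col: np.ndarray) -> np.ndarray:
        rows, cols = self.shape
        return (row >= 0) & (row < rows) & (col >= 0) & (col < cols)

    def env_at_cells(self, flat_idx: np.ndarray) -> np.ndarray:
        """Layer values at flattened cell indices, shape (n_points, n_layers)."""
        flat = self.values.reshape(self.n_layers, -1)
        return flat[:, np.asarray(flat_idx, dtype=int)].T

    def valid_flat_indices(self) -> np.ndarray:
        return np.flatnonzero(self.mask.ravel())

    def select_layers(self, names: Sequence[str]) -> "RasterStack":
        idx = [self.names.index(n) for n in names]
        return RasterStack(
            names=list(names),
            values=self.values[idx],
            mask=self.mask.copy(),
            cell_size=self.cell_size,
            origin=self.origin,
            crs=self.crs,
        )


@dataclass
class CorrelationReport:
    """Record of the greedy correlation-filtering pass."""

    matrix: np.ndarray
    layer_names: list[str]
    removal_order: list[str]
    retained: list[str]
    threshold: float
    constant_layers: list[str] = field(default_factory=list)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.matrix, index=self.layer_names, columns=self.layer_names)


def crop_stack(stack: RasterStack, extent: tuple[float, float, float, float]) -> RasterStack:
    """Crop to cells whose centers fall in ``[xmin, xmax) x [ymin, ymax)``."""
    xmin, ymin, xmax, ymax = extent
    xs, ys = stack.cell_centers()
    col_keep = (xs[0] >= xmin) & (xs[0] < xmax)
    row_keep = (ys[:, 0] >= ymin) & (ys[:, 0] < ymax)
    if not col_keep.any() or not row_keep.any():
        raise ValueError("extent does not intersect the grid")
    r0, r1 = np.flatnonzero(row_keep)[[0, -1]]
    c0, c1 = np.flatnonzero(col_keep)[[0, -1]]
    x0 = stack.origin[0] + c0 * stack.cell_size
    y0 = stack.origin[1] - r0 * stack.cell_size
    return RasterStack(
        names=list(stack.names),
        values=stack.values[:, r0 : r1 + 1, c0 : c1 + 1].copy(),
        mask=stack.mask[r0 : r1 + 1, c0 : c1 + 1].copy(),
        cell_size=stack.cell_size,
        origin=(x0, y0),
        crs=stack.crs,
    )


def pearson_matrix(stack: RasterStack) -> tuple[np.ndarray, list[str]]:
    """Pairwise-complete Pearson correlation over valid cells.

    Zero-variance layers get r = 0 against everything (and are reported).
    """
    data = stack.values.reshape(stack.n_layers, -1)[:, stack.mask.ravel()]
    sd = data.std(axis=1)
    constant = [stack.names[i] for i in np.flatnonzero(sd == 0)]
    centered = data - data.mean(axis=1, keepdims=True)
    denom = np.sqrt((centered**2).sum(axis=1))
    denom_safe = np.where(denom == 0, 1.0, denom)
    normed = centered / denom_safe[:, None]
    r = normed @ normed.T
    r[sd == 0, :] = 0.0
    r[:, sd == 0] = 0.0
    np.fill_diagonal(r, 1.0)
    return r, constant


def filter_correlated(
    stack: RasterStack, threshold: float = 0.80
) -> tuple[RasterStack, CorrelationReport]:
    """Drop layers until no retained pair has ``|r| > threshold``.

    Greedy rule: repeatedly take the retained pair with the highest ``|r|``
    above the threshold and drop the member with the larger mean ``|r|``
    against all other retained layers; ties drop the later layer in stack
    order.  Absolute correlation is used throughout — a strong negative
    correlation is just as redundant as a positive one.
    """
    if stack.n_layers < 1:
        raise ValueError("stack must have at least one layer")
    r, constant = pearson_matrix(stack)
    names = list(stack.names)
    retained = list(range(len(names)))
    removed: list[str] = []

    while len(retained) > 1:
        sub = np.abs(r[np.ix_(retained, retained)])
        np.fill_diagonal(sub, 0.0)
        i, j = np.unravel_index(np.argmax(sub), sub.shape)
        if sub[i, j] <= threshold:
            break
        mean_i = sub[i].sum() / (len(retained) - 1)
        mean_j = sub[j].sum() / (len(retained) - 1)
        if mean_i > mean_j:
            drop_local = i
        elif mean_j > mean_i:
            drop_local = j
        else:  # tie: drop the later layer in stack order
            drop_local = max(i, j)
        drop = retained[drop_local]
        removed.append(names[drop])
        retained.remove(drop)

    kept_names = [names[i] for i in retained]
    report = CorrelationReport(
        matrix=r,
        layer_names=names,
        removal_order=removed,
        retained=kept_names,
        threshold=threshold,
        constant_layers=constant,
    )
    return stack.select_layers(kept_names), report


# -- text I/O ---------------------------------------------------------------


def write_stack(stack: RasterStack, path: str | Path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "names": stack.names,
        "shape": list(stack.shape),
        "cell_size": stack.cell_size,
        "origin": list(stack.origin),
        "crs": stack.crs,
    }
    (path / "stack.json").write_text(json.dumps(meta, indent=2))
    for name, layer in zip(stack.names, stack.values):
        out = np.where(stack.mask, layer, np.nan)
        np.savetxt(path / f"{name}.asc", out, fmt="%.8g")


def read_stack(path: str | Path) -> RasterStack:
    path = Path(path)
    meta = json.loads((path / "stack.json").read_text())
    layers = [np.loadtxt(path / f"{name}.asc", ndmin=2) for name in meta["names"]]
    values = np.stack(layers)
    return RasterStack(
        names=meta["names"],
        values=values,
        mask=~np.any(np.isnan(values), axis=0),
        cell_size=meta["cell_size"],
        origin=tuple(meta["origin"]),
        crs=meta.get("crs"),
    )
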