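"""Background-region constructions for the niche similarity test.

Three definitions of the environment "available" to a lineage: the minimum
convex polygon of its occurrences, and the cells whose logistic habitat
suitability exceeds 0.5 or 0.75.  Regions are stored as cell sets (the
authoritative representation used for sampling); polygons are derived for
export only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import MultiPoint, box
from shapely.ops import unary_union

from .climate_prep import RasterStack
from .sdm import SuitabilitySurface
from .synthetic_data import OccurrenceSet

__all__ = ["BackgroundRegion", "mcp_region", "threshold_region"]


@dataclass
class BackgroundRegion:
    method: str  # mcp | thresh50 | thresh75 | custom
    cells: np.ndarray  # flat indices into the parent grid
    source_lineage: str | None = None
    polygon: object | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.cells = np.unique(np.asarray(self.cells, dtype=int))
        if self.cells.size == 0:
            raise ValueError("background region must contain at least one cell")

    def __len__(self) -> int:
        return self.cells.size


def mcp_region(occ: OccurrenceSet, stack: RasterStack) -> BackgroundRegion:
    """Minimum convex polygon of the occurrence points, as a cell set.

    Member cells are the non-missing cells whose centers fall inside or on
    the hull.  Degenerate inputs (fewer than 3 distinct points, or collinear
    points) buffer the hull by one cell width so the region is 2-D.
    """
    pts = MultiPoint(list(zip(occ.x, occ.y)))
    hull = pts.convex_hull
    if hull.geom_type != "Polygon":  # point or line: degenerate
        hull = hull.buffer(stack.cell_size)
    xs, ys = stack.cell_centers()
    centers = shapely.points(xs.ravel(), ys.ravel())
    inside = shapely.intersects(hull, centers) & stack.mask.ravel()
    cells = np.flatnonzero(inside)
    if cells.size == 0:
        raise ValueError("convex hull covers no valid cell centers")
    return BackgroundRegion(
        method="mcp", cells=cells, source_lineage=occ.lineage, polygon=hull
    )


def threshold_region(
    surface: SuitabilitySurface,
    tau: float,
    stack: RasterStack | None = None,
    source_lineage: str | None = None,
    build_polygon: bool = False,
) -> BackgroundRegion:
    """Cells whose logistic suitability is strictly greater than ``tau``."""
    logit = surface.logistic
    sel = np.where(np.isnan(logit), False, logit > tau) & surface.mask
    cells = np.flatnonzero(sel.ravel())
    if cells.size == 0:
        raise ValueError(
            f"no cell has logistic suitability > {tau}; consider a lower threshold"
        )
    poly = None
    if build_polygon and stack is not None:
        xs, ys = stack.cell_centers()
        h = stack.cell_size / 2
        boxes = [
            box(x - h, y - h, x + h, y + h)
            for x, y in zip(xs.ravel()[cells], ys.ravel()[cells])
        ]
        poly = unary_union(boxes)
    method = {0.5: "thresh50", 0.75: "thresh75"}.get(tau, "custom")
    return BackgroundRegion(
        method=method,
        cells=cells,
        source_lineage=source_lineage or surface.meta.get("lineage"),
        polygon=poly,
        meta={"tau": tau},
    )
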