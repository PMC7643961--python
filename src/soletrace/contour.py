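"""Closed 2-D otolith outlines: container, size measures and scalar shape indices.

An otolith outline is an ordered, simple (non self-intersecting) closed polygon
in mm. From it we take the four classical size measures — length ``L0`` (maximum
Feret diameter), width ``l0`` (maximal extent perpendicular to the L0 axis),
perimeter ``P0`` and area ``A0`` — and the five scalar shape indices built from
them (ellipticity, circularity, rectangularity, roundness, form coefficient).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

__all__ = [
    "Contour",
    "OtolithMeasures",
    "measure_otolith",
    "shape_indices",
    "shape_index_table",
    "redundancy_screen",
    "SHAPE_INDEX_NAMES",
]

SHAPE_INDEX_NAMES = (
    "ellipticity",
    "circularity",
    "rectangularity",
    "roundness",
    "form_coefficient",
)


def signed_area(points: np.ndarray) -> float:
    """Shoelace signed area of a closed polygon (positive = counterclockwise)."""
    x, y = points[:, 0], points[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


@dataclass
class Contour:
    """Ordered closed 2-D outline of one otolith.

    Points are stored counterclockwise (positive signed area) without a
    repeated closing vertex; the polygon is implicitly closed.
    """

    points: np.ndarray
    otolith_id: str = ""
    fish_id: str = ""
    side: str = "R"
    closed: bool = True

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise ValueError("points must be an (n, 2) array")
        # drop an explicit closing vertex if present
        if len(pts) > 1 and np.allclose(pts[0], pts[-1]):
            pts = pts[:-1]
        if len(np.unique(pts.round(12), axis=0)) < 3:
            raise ValueError("contour needs at least 3 distinct points")
        if self.side not in ("L", "R"):
            raise ValueError(f"side must be 'L' or 'R', got {self.side!r}")
        if signed_area(pts) < 0:
            pts = pts[::-1].copy()
        self.points = pts

    @property
    def n_points(self) -> int:
        return len(self.points)

    def mirrored(self) -> "Contour":
        """Reflection about the vertical axis (x -> -x), reoriented CCW."""
        pts = self.points.copy()
        pts[:, 0] = -pts[:, 0]
        other = {"L": "R", "R": "L"}[self.side]
        return replace(self, points=pts[::-1].copy(), side=other)

    def is_simple(self) -> bool:
        from shapely.geometry import Polygon

        return Polygon(self.points).is_simple


@dataclass(frozen=True)
class OtolithMeasures:
    """Size measures of one otolith: length, width, perimeter, area."""

    L0: float  # mm, maximum Feret diameter
    l0: float  # mm, maximal extent perpendicular to the L0 axis
    P0: float  # mm, polygonal perimeter
    A0: float  # mm^2, shoelace area

    def __post_init__(self) -> None:
        if min(self.L0, self.l0, self.P0, self.A0) <= 0:
            raise ValueError("all otolith measures must be positive")


def measure_otolith(contour: Contour) -> OtolithMeasures:
    """Compute ``L0``, ``l0``, ``P0`` and ``A0`` from a polygonal outline.

    ``L0`` is the maximum pairwise point distance (Feret diameter), found on
    the convex hull; ``l0`` the extent perpendicular to the L0 direction; ties
    in the Feret direction are broken by the smallest angle to the x-axis.
    """
    pts = contour.points
    area = signed_area(pts)
    if abs(area) < 1e-300:
        raise ValueError("degenerate polygon: zero area")
    hull_pts = pts[ConvexHull(pts).vertices]
    diff = hull_pts[:, None, :] - hull_pts[None, :, :]
    d2 = np.einsum("ijk,ijk->ij", diff, diff)
    dmax = d2.max()
    ii, jj = np.argwhere(np.isclose(d2, dmax, rtol=1e-12)).T
    vecs = hull_pts[ii] - hull_pts[jj]
    angles = np.mod(np.arctan2(vecs[:, 1], vecs[:, 0]), np.pi)
    u = vecs[np.argmin(angles)]
    u = u / np.linalg.norm(u)
    L0 = float(np.sqrt(dmax))
    perp = np.array([-u[1], u[0]])
    proj = pts @ perp
    l0 = float(proj.max() - proj.min())
    seg = np.roll(pts, -1, axis=0) - pts
    P0 = float(np.sqrt((seg**2).sum(axis=1)).sum())
    return OtolithMeasures(L0=L0, l0=l0, P0=P0, A0=abs(area))


def shape_indices(m: OtolithMeasures) -> dict[str, float]:
    """The five dimensionless shape indices from the four size measures.

    ellipticity (L0-l0)/(L0+l0); circularity P0^2/A0; rectangularity
    A0/(L0*l0); roundness 4*A0/(pi*L0^2); form coefficient 4*pi*A0/P0^2.
    Circularity x form coefficient = 4*pi identically.
    """
    L0, l0, P0, A0 = m.L0, m.l0, m.P0, m.A0
    return {
        "ellipticity": (L0 - l0) / (L0 + l0),
        "circularity": P0**2 / A0,
        "rectangularity": A0 / (L0 * l0),
        "roundness": 4.0 * A0 / (np.pi * L0**2),
        "form_coefficient": 4.0 * np.pi * A0 / P0**2,
    }


def shape_index_table(contours: list[Contour]) -> pd.DataFrame:
    """Measure every contour and tabulate indices, indexed by otolith id.

    Also carries the raw size measures as extra columns (L0, l0, P0, A0).
    """
    rows = []
    for c in contours:
        m = measure_otolith(c)
        row = {"otolith_id": c.otolith_id, "fish_id": c.fish_id, "side": c.side}
        row.update(L0=m.L0, l0=m.l0, P0=m.P0, A0=m.A0)
        row.update(shape_indices(m))
        rows.append(row)
    return pd.DataFrame(rows).set_index("otolith_id")


def redundancy_screen(
    table: pd.DataFrame, r_threshold: float = 0.8
) -> tuple[list[str], pd.DataFrame]:
    """Pairwise-correlation redundancy screen over the five shape indices.

    An index is dropped only if its absolute Pearson correlation exceeds
    ``r_threshold`` with at least two other indices; with a single strong
    partner both members are kept. Returns (retained names, correlation
    matrix). Raises on constant columns (undefined correlation).
    """
    cols = [c for c in SHAPE_INDEX_NAMES if c in table.columns]
    if len(table) < 3:
        raise ValueError("need at least 3 otoliths for a correlation screen")
    sub = table[cols].astype(float)
    stds = sub.std(ddof=1)
    constant = stds[stds == 0.0].index.tolist()
    if constant:
        raise ValueError(f"constant shape index, correlation undefined: {constant}")
    corr = sub.corr(method="pearson")
    strong = (corr.abs() > r_threshold) & ~np.eye(len(cols), dtype=bool)
    dropped: list[str] = []
    # drop greedily, most-connected first, re-checking after each removal
    while True:
        active = [c for c in cols if c not in dropped]
        counts = strong.loc[active, active].sum(axis=1)
        worst = counts.idxmax()
        if counts[worst] >= 2:
            dropped.append(worst)
        else:
            break
    retained = [c for c in cols if c not in dropped]
    return retained, corr
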