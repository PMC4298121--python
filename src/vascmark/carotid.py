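"""Carotid vessel-wall morphometry: wall area and normalized wall index.

NWI = vessel wall area / total vessel area, with wall area the difference
between outer and inner (lumen) contour areas.  Stacks hold eight contiguous
2 mm slices; slice 8 is adjacent to the flow divider and only slices 2-5
enter the analysis.  Areas are averaged over the analyzed slices first and
the index is the ratio of those means, not the mean of per-slice ratios.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from shapely.geometry import Point, Polygon

from .errors import GeometryError

ANALYZED_SLICES = (2, 3, 4, 5)
N_SLICES = 8
SLICE_THICKNESS_MM = 2.0


@dataclass(frozen=True)
class CarotidSlice:
    """Inner/outer wall polygons (mm) of one cross-sectional slice."""

    slice_index: int  # 1 = most caudal, 8 = at the flow divider
    inner: np.ndarray  # (n, 2) closed polygon, mm
    outer: np.ndarray  # (m, 2) closed polygon, mm
    thickness: float = SLICE_THICKNESS_MM

    def __post_init__(self) -> None:
        object.__setattr__(self, "inner", np.asarray(self.inner, dtype=float))
        object.__setattr__(self, "outer", np.asarray(self.outer, dtype=float))


@dataclass(frozen=True)
class ContourStack:
    """Eight-slice stack of carotid wall contours, ordered caudal to divider."""

    slices: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "slices", tuple(self.slices))
        if len(self.slices) != N_SLICES:
            raise GeometryError(f"stack must hold exactly {N_SLICES} slices")

    def slice(self, index: int) -> CarotidSlice:
        for s in self.slices:
            if s.slice_index == index:
                return s
        raise GeometryError(f"slice {index} missing from stack")


@dataclass(frozen=True)
class NwiResult:
    mean_vwa: float  # mm^2
    mean_total_area: float  # mm^2
    nwi: float
    slices_used: tuple = ANALYZED_SLICES


def contour_area(polygon: np.ndarray) -> float:
    """Absolute shoelace area of a simple closed polygon (mm^2).

    Orientation-independent; the closing edge from the last vertex back to
    the first is implicit, so a repeated final vertex is harmless.
    """
    pts = np.asarray(polygon, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise GeometryError("polygon must be an (n, 2) array")
    if np.unique(pts, axis=0).shape[0] < 3:
        raise GeometryError("degenerate polygon: fewer than 3 distinct points")
    x, y = pts[:, 0], pts[:, 1]
    return float(0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))


def _check_simple(polygon: np.ndarray, name: str) -> None:
    if not Polygon(polygon).is_simple:
        raise GeometryError(f"{name} contour is self-intersecting")


def slice_wall_measures(inner: np.ndarray, outer: np.ndarray) -> tuple:
    """(vessel wall area, total vessel area) in mm^2 for one slice.

    Containment of the inner contour is checked cheaply via area ordering
    plus inner-centroid-in-outer-polygon, adequate for near-circular contours.
    """
    a_in = contour_area(inner)
    a_out = contour_area(outer)
    if a_out <= a_in:
        raise GeometryError(
            f"outer area ({a_out:.3f} mm^2) must exceed inner area ({a_in:.3f} mm^2)"
        )
    _check_simple(inner, "inner")
    _check_simple(outer, "outer")
    centroid = np.asarray(inner, dtype=float).mean(axis=0)
    if not Polygon(outer).contains(Point(centroid)):
        raise GeometryError("inner contour centroid lies outside the outer contour")
    return a_out - a_in, a_out


def carotid_nwi(stack: ContourStack, slices_used: tuple = ANALYZED_SLICES) -> NwiResult:
    """Normalized wall index over the analyzed slices (default 2-5).

    Mean VWA and mean total area are taken over the analyzed slices only and
    NWI is the ratio of those means.  Slices outside the analyzed set are
    ignored entirely and may be invalid.
    """
    vwas, totals = [], []
    for idx in slices_used:
        s = stack.slice(idx)
        vwa, total = slice_wall_measures(s.inner, s.outer)
        vwas.append(vwa)
        totals.append(total)
    mean_vwa = float(np.mean(vwas))
    mean_total = float(np.mean(totals))
    nwi = mean_vwa / mean_total
    if not (0.0 < nwi < 1.0):
        raise GeometryError(f"NWI {nwi:.4f} outside the open interval (0, 1)")
    return NwiResult(mean_vwa=mean_vwa, mean_total_area=mean_total, nwi=nwi,
                     slices_used=tuple(slices_used))
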