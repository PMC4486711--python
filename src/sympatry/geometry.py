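"""Range-overlap geometry and summary indices.

Sister-species range overlap is measured as the area of sympatry divided
by the area of the smaller of the two ranges, giving an index on [0, 1].
An index below 0.05 is treated as complete allopatry and one above 0.95
as complete sympatry, absorbing sampling incompleteness and small mapping
inaccuracies at the extremes.  A set of pairwise indices is summarised by
the counts of completely sympatric (z) and completely allopatric (c)
pairs and by a bimodality score (z*c)/(a*b), where a = b = n/2 are the
counts that an even split between the two extreme states would produce.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "RangePolygon",
    "PairOverlap",
    "OverlapSummary",
    "InvalidGeometryError",
    "ALLOPATRY_THRESHOLD",
    "SYMPATRY_THRESHOLD",
    "polygon_area",
    "polygon_intersection_area",
    "overlap_index",
    "classify_overlap",
    "bimodality",
    "summarize_overlaps",
]

#: Overlap index below which a pair counts as completely allopatric.
ALLOPATRY_THRESHOLD = 0.05
#: Overlap index above which a pair counts as completely sympatric.
SYMPATRY_THRESHOLD = 0.95


class InvalidGeometryError(ValueError):
    """Raised for rings that are not simple polygons with positive area."""


@dataclass(frozen=True)
class RangePolygon:
    """A species range as a single simple ring in planar equal-area units.

    Coordinates are assumed to be already projected; the package performs
    no CRS handling.  Holes and multi-part ranges are out of scope.
    """

    vertices: tuple[tuple[float, float], ...]
    species_id: str = ""

    def __post_init__(self) -> None:
        verts = tuple((float(x), float(y)) for x, y in self.vertices)
        object.__setattr__(self, "vertices", verts)
        if len(verts) < 3:
            raise InvalidGeometryError(
                f"polygon for {self.species_id!r} has {len(verts)} vertices; "
                "at least 3 required"
            )
        poly = _ShapelyPolygon(verts)
        if not poly.is_valid:
            raise InvalidGeometryError(
                f"polygon for {self.species_id!r} is not a simple ring"
            )
        if poly.area <= 0:
            raise InvalidGeometryError(
                f"polygon for {self.species_id!r} has zero area"
            )

    def to_shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)


@dataclass(frozen=True)
class PairOverlap:
    """Areas and overlap index for one sister pair."""

    area_a: float
    area_b: float
    area_intersection: float
    index: float = field(init=False)
    category: str = field(init=False)

    def __post_init__(self) -> None:
        idx = overlap_index(self.area_a, self.area_b, self.area_intersection)
        object.__setattr__(self, "index", idx)
        object.__setattr__(self, "category", classify_overlap(idx))


@dataclass(frozen=True)
class OverlapSummary:
    """Counts of extreme-overlap pairs and the bimodality score."""

    n: int
    z: int  # completely sympatric (index > 0.95)
    c: int  # completely allopatric (index < 0.05)
    bimodality: float

    def __post_init__(self) -> None:
        if self.z + self.c > self.n:
            raise ValueError(f"z + c = {self.z + self.c} exceeds n = {self.n}")


def polygon_area(poly: RangePolygon) -> float:
    """Planar area of a simple ring, independent of vertex orientation."""
    return poly.to_shapely().area


def polygon_intersection_area(a: RangePolygon, b: RangePolygon) -> float:
    """Area of the geometric intersection of two ranges; 0 when disjoint."""
    return a.to_shapely().intersection(b.to_shapely()).area


def overlap_index(area_a: float, area_b: float, area_intersection: float) -> float:
    """Area of sympatry divided by the area of the smaller range.

    Parameters are plain areas in any consistent (equal-area) units.
    Raises ``ValueError`` for non-positive range areas or an intersection
    exceeding the smaller range (inconsistent inputs, allowing for
    floating-point slack).
    """
    if area_a <= 0 or area_b <= 0:
        raise ValueError("range areas must be positive")
    smaller = min(area_a, area_b)
    if area_intersection < 0 or area_intersection > smaller * (1 + 1e-9):
        raise ValueError(
            f"intersection area {area_intersection} inconsistent with "
            f"smaller range area {smaller}"
        )
    return min(area_intersection / smaller, 1.0)


def classify_overlap(index: float) -> str:
    """Classify an overlap index as allopatric, partial or sympatric.

    Thresholds are strict: exactly 0.05 or 0.95 is 'partial'.
    """
    if not 0.0 <= index <= 1.0:
        raise ValueError(f"overlap index {index} outside [0, 1]")
    if index < ALLOPATRY_THRESHOLD:
        return "allopatric"
    if index > SYMPATRY_THRESHOLD:
        return "sympatric"
    return "partial"


def bimodality(z: int, c: int, n: int) -> float:
    """Bimodality of an overlap distribution, (z*c)/((n/2)*(n/2)).

    z and c count completely sympatric and completely allopatric pairs;
    the denominator is the product of the counts under an even split
    between the two extreme states, with n/2 real-valued so that odd n
    is well defined.  The score lies in [0, 1], reaching 1 only when
    z = c = n/2.
    """
    if n < 1:
        raise ValueError("n must be at least 1")
    if z < 0 or c < 0 or z + c > n:
        raise ValueError(f"invalid counts z={z}, c={c} for n={n}")
    half = n / 2.0
    return (z * c) / (half * half)


def summarize_overlaps(indices: Sequence[float] | Iterable[float]) -> OverlapSummary:
    """Summarise a collection of overlap indices into counts and bimodality."""
    values = np.asarray(list(indices), dtype=float)
    if values.size == 0:
        raise ValueError("cannot summarise an empty list of overlap indices")
    if np.any((values < 0) | (values > 1)):
        raise ValueError("overlap indices must lie in [0, 1]")
    n = int(values.size)
    z = int(np.sum(values > SYMPATRY_THRESHOLD))
    c = int(np.sum(values < ALLOPATRY_THRESHOLD))
    return OverlapSummary(n=n, z=z, c=c, bimodality=bimodality(z, c, n))
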