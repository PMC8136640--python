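"""Species ranges, the spatial congruence index, and the congruence network.

The spatial congruence index between two species ranges *a* and *b* is

    C_S = (O / A_a) * (O / A_b)

where ``O`` is the area of overlap of the two ranges and ``A_a``, ``A_b``
their areas.  The index is the product of the overlap fraction of each
range, varies from 0 (disjoint ranges) to 1 (identical ranges), and is
symmetric.  It is a vector (polygon) analogue of the Jaccard index: for
nested ranges it reduces to the ratio of the two areas.

All computation is planar: areas are taken in squared map units, so input
geometries must already be in an equal-area projection (see
:mod:`chorotypes.io` for the guard against raw longitude/latitude input).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from shapely import STRtree, union_all
from shapely.geometry.base import BaseGeometry

__all__ = [
    "OVERLAP_REL_TOL",
    "GeometryError",
    "SpeciesRange",
    "CongruenceEdge",
    "CongruenceNetwork",
    "overlap_area",
    "spatial_congruence",
    "build_network",
    "common_and_total_area",
]

# Overlap areas below this fraction of the smaller range are treated as
# zero, so boundary-touching ranges never count as overlapping.
OVERLAP_REL_TOL = 1e-12


class GeometryError(ValueError):
    """Raised for invalid or degenerate range geometries."""


@dataclass
class SpeciesRange:
    """One species' range: identifier plus a (multi)polygon in planar coordinates.

    Invalid geometries are repaired once by zero-width buffering; if the
    repair fails, or the area is not strictly positive, ``GeometryError``
    is raised naming the species.  Multipolygon parts are one range: a
    species with a disjunct distribution is still a single vertex of the
    congruence network.
    """

    species_id: str
    geometry: BaseGeometry
    area: float = field(default=0.0)

    def __post_init__(self) -> None:
        if not isinstance(self.geometry, BaseGeometry):
            raise GeometryError(
                f"species {self.species_id!r}: geometry must be a shapely geometry"
            )
        if not self.geometry.is_valid:
            repaired = self.geometry.buffer(0)
            if not repaired.is_valid:
                raise GeometryError(
                    f"species {self.species_id!r}: geometry invalid after repair"
                )
            self.geometry = repaired
        self.area = self.geometry.area
        if not self.area > 0.0:
            raise GeometryError(
                f"species {self.species_id!r}: range area must be > 0 "
                f"(got {self.area!r})"
            )

    def __repr__(self) -> str:  # geometry WKT can be huge
        return f"SpeciesRange({self.species_id!r}, area={self.area:.6g})"


@dataclass(frozen=True)
class CongruenceEdge:
    """An unordered species pair with its overlap area and congruence index."""

    species_a: str
    species_b: str
    overlap_area: float
    cs: float


def overlap_area(a: SpeciesRange, b: SpeciesRange) -> float:
    """Area of overlap of two ranges; 0 for merely touching boundaries."""
    o = a.geometry.intersection(b.geometry).area
    if o < OVERLAP_REL_TOL * min(a.area, b.area):
        return 0.0
    return o


def spatial_congruence(a: SpeciesRange, b: SpeciesRange) -> float:
    """Spatial congruence index C_S = (O/A_a) * (O/A_b) in [0, 1].

    Returns 0 for disjoint ranges and 1 for ranges identical up to a set
    of measure zero.  When one range is nested in the other this equals
    the ratio of the smaller to the larger area.
    """
    o = overlap_area(a, b)
    if o == 0.0:
        return 0.0
    cs = (o / a.area) * (o / b.area)
    # float noise can push identical ranges a hair over 1
    return min(cs, 1.0)


class CongruenceNetwork:
    """Sparse symmetric store of pairwise C_S values over a species pool.

    Species are vertices; pairs with ``cs >= store_floor`` are edges.
    Looking up an absent pair (including self-pairs) returns 0.  Positive
    pairwise overlap is recorded for *all* pairs, independent of the
    floor, because the spatial overlap criterion needs it even where the
    congruence itself is negligible.
    """

    def __init__(self, species: Iterable[str], store_floor: float = 0.1):
        self.species: list[str] = list(species)
        if len(set(self.species)) != len(self.species):
            raise ValueError("duplicate species_id in network")
        if not 0.0 <= store_floor < 1.0:
            raise ValueError("store_floor must be in [0, 1)")
        self.store_floor = float(store_floor)
        self._adj: dict[str, dict[str, float]] = {s: {} for s in self.species}
        self._overlap: dict[frozenset[str], float] = {}

    def _record_overlap(self, a: str, b: str, o: float) -> None:
        if o > 0.0:
            self._overlap[frozenset((a, b))] = o

    def add_edge(self, a: str, b: str, overlap: float, cs: float) -> None:
        if a == b:
            raise ValueError(f"self-edge on {a!r}")
        if not 0.0 < cs <= 1.0:
            raise ValueError(f"edge cs must be in (0, 1], got {cs!r}")
        self._record_overlap(a, b, overlap)
        if cs >= self.store_floor:
            self._adj[a][b] = cs
            self._adj[b][a] = cs

    def cs(self, a: str, b: str) -> float:
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, s: str) -> Mapping[str, float]:
        return self._adj[s]

    def overlaps(self, a: str, b: str) -> bool:
        """Whether the two ranges share positive overlap area."""
        return frozenset((a, b)) in self._overlap

    def pair_overlap_area(self, a: str, b: str) -> float:
        return self._overlap.get(frozenset((a, b)), 0.0)

    def edges(self) -> list[CongruenceEdge]:
        """All stored edges (cs >= store_floor), sorted by species pair."""
        out = []
        for a, nbrs in self._adj.items():
            for b, cs in nbrs.items():
                if a < b:
                    out.append(
                        CongruenceEdge(a, b, self.pair_overlap_area(a, b), cs)
                    )
        return sorted(out, key=lambda e: (e.species_a, e.species_b))

    def __contains__(self, s: str) -> bool:
        return s in self._adj

    def __len__(self) -> int:
        return len(self.species)


def build_network(
    ranges: Iterable[SpeciesRange], store_floor: float = 0.1
) -> CongruenceNetwork:
    """Compute all pairwise congruences and assemble the network.

    Every species is compared with every other (an STRtree prunes
    non-intersecting pairs), so a subset of references can later be
    scanned against the full pool.  ``store_floor`` defaults to the
    scan's default minimum congruence threshold: edges below it can
    never activate during a default sweep.
    """
    ranges = list(ranges)
    if len(ranges) < 2:
        raise ValueError("need at least 2 species to build a network")
    ids = [r.species_id for r in ranges]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValueError(f"duplicate species_id: {dupes}")

    net = CongruenceNetwork(ids, store_floor=store_floor)
    geoms = [r.geometry for r in ranges]
    tree = STRtree(geoms)
    left, right = tree.query(geoms, predicate="intersects")
    seen = set()
    for i, j in zip(left.tolist(), right.tolist()):
        if i >= j or (i, j) in seen:
            continue
        seen.add((i, j))
        a, b = ranges[i], ranges[j]
        o = overlap_area(a, b)
        if o == 0.0:
            continue
        cs = min((o / a.area) * (o / b.area), 1.0)
        net.add_edge(a.species_id, b.species_id, o, cs)
    return net


def common_and_total_area(ranges: Iterable[SpeciesRange]) -> tuple[float, float]:
    """(common, total) area of a species group.

    The common area is the area of the intersection of all member ranges
    (0 when empty); the total area is the area of their union.  Their
    ratio measures the trade-off between spatial cohesion and
    comprehensiveness of the group.
    """
    ranges = list(ranges)
    if not ranges:
        raise ValueError("need at least 1 range")
    inter = ranges[0].geometry
    for r in ranges[1:]:
        inter = inter.intersection(r.geometry)
        if inter.is_empty:
            break
    common = 0.0 if inter.is_empty else inter.area
    if common < OVERLAP_REL_TOL * min(r.area for r in ranges):
        common = 0.0
    total = union_all([r.geometry for r in ranges]).area
    return common, total
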