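"""The SCAN algorithm: threshold sweep with breadth-first group expansion.

For one reference species and one congruence threshold C_T, a group is
grown level by level: every species with C_S >= C_T to the reference is
directly congruent (depth 1); each further pass adds species congruent
to any already-grouped species (indirect congruence, depth 2, 3, ...).
The group "closes" when a pass adds nothing.  The sweep starts at the
highest threshold and descends in fixed decimal steps, recording every
closed group of two or more species as a partial chorotype, until the
expansion fails -- the depth cap is hit while more species would still
join, or the spatial overlap criterion is violated -- or the minimum
threshold is passed.  The set of all partial chorotypes of one reference
is its chorotype.

The optional spatial overlap criterion (on by default) admits a
candidate only if its range shares positive overlap area with every
previously grouped species; if, even so, the joint common area of the
group becomes empty at the end of a level, the whole threshold round is
dropped and the reference's sweep terminates.
"""

from __future__ import annotations

import enum
import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from .congruence import (
    CongruenceNetwork,
    SpeciesRange,
    common_and_total_area,
    overlap_area,
)

__all__ = [
    "ScanParams",
    "Termination",
    "ExpansionFailure",
    "Member",
    "GroupExpansion",
    "PartialChorotype",
    "Chorotype",
    "ScanResult",
    "expand_at_threshold",
    "scan_reference",
    "scan_all",
]


class ExpansionFailure(str, enum.Enum):
    MAX_DEPTH_REACHED = "max_depth_reached"
    OVERLAP_VIOLATED = "overlap_violated"


class Termination(str, enum.Enum):
    MIN_CT_REACHED = "min_ct_reached"
    MAX_DEPTH_REACHED = "max_depth_reached"
    OVERLAP_VIOLATED = "overlap_violated"
    NO_CLOSURE = "no_closure"


@dataclass(frozen=True)
class ScanParams:
    """Control parameters of a scan.

    max_depth
        Maximum number of breadth-first passes allowed before a group
        must close (default 7).
    ct_max, ct_min
        Highest and lowest congruence thresholds of the sweep
        (defaults 1.0 and 0.1).
    ct_step
        Threshold resolution: the decrement between successive rounds
        (default 0.01, i.e. 1% increments).
    overlap_criterion
        Whether a congruent range must share some overlap area with all
        previously grouped species (default on).
    cs_epsilon
        Float tolerance for the inclusive comparison ``cs >= ct``.
    """

    max_depth: int = 7
    ct_max: float = 1.0
    ct_min: float = 0.1
    ct_step: float = 0.01
    overlap_criterion: bool = True
    cs_epsilon: float = 1e-9

    def __post_init__(self) -> None:
        if self.max_depth < 1:
            raise ValueError("max_depth must be >= 1")
        if not (0.0 < self.ct_min <= self.ct_max <= 1.0):
            raise ValueError("need 0 < ct_min <= ct_max <= 1")
        if self.ct_step <= 0:
            raise ValueError("ct_step must be > 0")

    def ct_grid(self) -> list[float]:
        """Thresholds visited, descending from ct_max in exact decimal steps.

        The grid is built from integer multiples of ct_step so that ~90
        iterations accumulate no float drift.
        """
        k_max = math.floor(self.ct_max / self.ct_step + 1e-9)
        k_min = math.ceil(self.ct_min / self.ct_step - 1e-9)
        grid = []
        for k in range(k_max, k_min - 1, -1):
            ct = round(k * self.ct_step, 12)
            if ct <= self.ct_max + 1e-12:
                grid.append(ct)
        return grid


@dataclass(frozen=True)
class Member:
    """Membership record of one species in one expansion."""

    depth: int
    via: str | None  # linking species one level up (None for the reference)
    cs_to_reference: float


@dataclass
class GroupExpansion:
    """State of one breadth-first expansion at one threshold."""

    reference: str
    ct: float
    members: dict[str, Member]
    closed: bool
    closure_depth: int
    failure: ExpansionFailure | None = None

    @property
    def species(self) -> frozenset[str]:
        return frozenset(self.members)


@dataclass(frozen=True)
class PartialChorotype:
    """A closed species group valid over a contiguous threshold interval.

    ``ct_max`` is the highest and ``ct_min`` the lowest threshold at
    which exactly this composition closed; ``depth`` is the closure
    depth at ``ct_max``.  ``per_species`` maps each member to its
    congruence with the reference and its minimum depth over the
    interval.  ``common_area``/``total_area`` are the intersection and
    union areas of the member ranges.
    """

    reference: str
    species: frozenset[str]
    ct_max: float
    ct_min: float
    depth: int
    per_species: Mapping[str, tuple[float, int]]
    common_area: float
    total_area: float

    @property
    def ratio(self) -> float:
        return self.common_area / self.total_area if self.total_area else 0.0

    @property
    def richness(self) -> int:
        return len(self.species)


@dataclass
class Chorotype:
    """All partial chorotypes derived from one reference species."""

    reference: str
    partials: list[PartialChorotype]  # ordered by descending ct_max
    informative: bool
    termination: Termination
    thresholds_visited: list[float] = field(default_factory=list)

    @property
    def final_species(self) -> frozenset[str] | None:
        """Species set of the last (lowest-threshold, most inclusive) partial."""
        return self.partials[-1].species if self.partials else None


@dataclass
class ScanResult:
    """Chorotypes of all scanned references, keyed by reference id."""

    chorotypes: dict[str, Chorotype]
    params: ScanParams

    def __getitem__(self, reference: str) -> Chorotype:
        return self.chorotypes[reference]

    def __iter__(self):
        return iter(self.chorotypes.values())

    def __len__(self) -> int:
        return len(self.chorotypes)

    @property
    def references(self) -> list[str]:
        return list(self.chorotypes)

    def all_partials(self) -> list[PartialChorotype]:
        return [p for ch in self for p in ch.partials]


def _cs_to_reference(
    sid: str,
    reference: str,
    network: CongruenceNetwork,
    ranges: Mapping[str, SpeciesRange] | None,
) -> float:
    cs = network.cs(sid, reference)
    if cs == 0.0 and ranges is not None and network.overlaps(sid, reference):
        # present overlap but edge below the store floor: report the exact value
        a, b = ranges[sid], ranges[reference]
        o = overlap_area(a, b)
        cs = (o / a.area) * (o / b.area)
    return cs


def expand_at_threshold(
    reference: str,
    ct: float,
    network: CongruenceNetwork,
    ranges: Mapping[str, SpeciesRange],
    params: ScanParams,
) -> GroupExpansion:
    """Grow the group of ``reference`` at threshold ``ct`` until it closes or fails.

    Within a level, candidates are evaluated in descending congruence to
    their linking member (ties broken by species id) so results are
    deterministic.  With the overlap criterion on, a candidate is
    admitted only if its range positively overlaps every current
    member's range; a level after which the joint common area of all
    members is empty fails the round (``overlap_violated``).  If members
    were admitted at level ``max_depth`` and a further pass would admit
    more, the round fails with ``max_depth_reached``.
    """
    if reference not in network:
        raise KeyError(f"unknown reference species {reference!r}")
    thr = ct - params.cs_epsilon
    members: dict[str, Member] = {reference: Member(0, None, 1.0)}
    rejected: set[str] = set()
    common = ranges[reference].geometry if params.overlap_criterion else None
    frontier = [reference]
    depth = 0

    def candidates(front: Sequence[str]) -> list[tuple[str, float, str]]:
        best: dict[str, tuple[float, str]] = {}
        for m in front:
            for nb, cs in network.neighbors(m).items():
                if nb in members or nb in rejected or cs < thr:
                    continue
                cur = best.get(nb)
                if cur is None or cs > cur[0] or (cs == cur[0] and m < cur[1]):
                    best[nb] = (cs, m)
        return sorted(
            ((sid, cs, via) for sid, (cs, via) in best.items()),
            key=lambda t: (-t[1], t[0]),
        )

    def admissible(sid: str) -> bool:
        if not params.overlap_criterion:
            return True
        return all(network.overlaps(sid, m) for m in members)

    while True:
        admitted = []
        for sid, cs, via in candidates(frontier):
            if not admissible(sid):
                rejected.add(sid)
                continue
            members[sid] = Member(
                depth + 1, via, _cs_to_reference(sid, reference, network, ranges)
            )
            admitted.append(sid)
        if not admitted:
            return GroupExpansion(reference, ct, members, True, depth)
        depth += 1
        if params.overlap_criterion:
            for sid in admitted:
                common = common.intersection(ranges[sid].geometry)
            if common.is_empty or common.area <= 0.0:
                return GroupExpansion(
                    reference, ct, members, False, depth,
                    failure=ExpansionFailure.OVERLAP_VIOLATED,
                )
        if depth == params.max_depth:
            would_add = any(admissible(sid) for sid, _, _ in candidates(admitted))
            if would_add:
                return GroupExpansion(
                    reference, ct, members, False, depth,
                    failure=ExpansionFailure.MAX_DEPTH_REACHED,
                )
            return GroupExpansion(reference, ct, members, True, depth)
        frontier = admitted


def scan_reference(
    reference: str,
    network: CongruenceNetwork,
    ranges: Mapping[str, SpeciesRange],
    params: ScanParams = ScanParams(),
) -> Chorotype:
    """Sweep thresholds from ct_max down to ct_min for one reference.

    Singleton closures are skipped silently (the sweep continues);
    consecutive rounds closing on the identical species set are merged
    into one partial chorotype spanning their threshold interval.  The
    sweep terminates at the first failing threshold, or after ct_min.
    """
    partials: list[PartialChorotype] = []
    visited: list[float] = []
    termination: Termination | None = None

    cur_species: frozenset[str] | None = None
    cur_ct_max = cur_ct_min = 0.0
    cur_depth = 0
    cur_min_depths: dict[str, int] = {}
    cur_cs: dict[str, float] = {}

    def flush() -> None:
        nonlocal cur_species
        if cur_species is None:
            return
        members = [ranges[s] for s in sorted(cur_species)]
        common, total = common_and_total_area(members)
        partials.append(
            PartialChorotype(
                reference=reference,
                species=cur_species,
                ct_max=cur_ct_max,
                ct_min=cur_ct_min,
                depth=cur_depth,
                per_species={
                    s: (cur_cs[s], cur_min_depths[s]) for s in sorted(cur_species)
                },
                common_area=common,
                total_area=total,
            )
        )
        cur_species = None

    for ct in params.ct_grid():
        visited.append(ct)
        exp = expand_at_threshold(reference, ct, network, ranges, params)
        if exp.failure is not None:
            termination = Termination(exp.failure.value)
            break
        if len(exp.members) < 2:  # singleton closure: skip, keep sweeping
            flush()
            continue
        if exp.species == cur_species:
            cur_ct_min = ct
            for s, m in exp.members.items():
                if m.depth < cur_min_depths[s]:
                    cur_min_depths[s] = m.depth
        else:
            flush()
            cur_species = exp.species
            cur_ct_max = cur_ct_min = ct
            cur_depth = exp.closure_depth
            cur_min_depths = {s: m.depth for s, m in exp.members.items()}
            cur_cs = {s: m.cs_to_reference for s, m in exp.members.items()}
    flush()
    if termination is None:
        termination = Termination.MIN_CT_REACHED if partials else Termination.NO_CLOSURE
    return Chorotype(
        reference=reference,
        partials=partials,
        informative=bool(partials),
        termination=termination,
        thresholds_visited=visited,
    )


def scan_all(
    references: Iterable[str],
    network: CongruenceNetwork,
    ranges: Mapping[str, SpeciesRange] | Iterable[SpeciesRange],
    params: ScanParams = ScanParams(),
) -> ScanResult:
    """Run the sweep for every reference, one by one.

    References must be members of the network's species pool; the pool
    itself may be larger (non-reference species still act as links and
    members).  Results are independent per reference, so the outcome
    does not depend on reference order.
    """
    if not isinstance(ranges, Mapping):
        ranges = {r.species_id: r for r in ranges}
    references = list(references)
    unknown = [r for r in references if r not in network]
    if unknown:
        raise KeyError(f"reference species not in pool: {unknown}")
    if len(set(references)) != len(references):
        raise ValueError("duplicate reference species")
    return ScanResult(
        chorotypes={
            ref: scan_reference(ref, network, ranges, params) for ref in references
        },
        params=params,
    )
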