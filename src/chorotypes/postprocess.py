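"""Cross-reference analysis of scan results.

Scans run per reference species, so different references frequently
rediscover the same species group.  This module deduplicates partial
chorotypes, groups references that converge on the same final set into
synonymous chorotype families (named after the reference with the
highest mean congruence to the grouped species), finds nesting
relations and species-disjoint "zones", detects independent chorotypes
that overlap spatially without sharing species, and summarizes
informative status.
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

from shapely import union_all

from .congruence import OVERLAP_REL_TOL, SpeciesRange
from .core import Chorotype, PartialChorotype, ScanResult

__all__ = [
    "UniquePartial",
    "ChorotypeFamily",
    "unique_partial_chorotypes",
    "find_synonyms",
    "find_nested",
    "disjoint_zones",
    "find_independent_overlaps",
    "informative_species",
    "informative_summary",
]


@dataclass(frozen=True)
class UniquePartial:
    """One distinct species set with its widest observed threshold interval."""

    species: frozenset[str]
    ct_max: float
    ct_min: float
    references: tuple[str, ...]  # references that recorded this set
    depth_min: int
    common_area: float
    total_area: float

    @property
    def richness(self) -> int:
        return len(self.species)

    @property
    def ratio(self) -> float:
        return self.common_area / self.total_area if self.total_area else 0.0


@dataclass(frozen=True)
class ChorotypeFamily:
    """References converging on the same canonical species set.

    The family is named after the reference whose mean congruence with
    all other members of the canonical set is highest (ties broken
    lexicographically).
    """

    name: str
    canonical_set: frozenset[str]
    synonyms: tuple[str, ...]
    members_by_reference: Mapping[str, frozenset[str]] = field(default_factory=dict)


def _as_results(result: ScanResult | Iterable[ScanResult]) -> list[ScanResult]:
    if isinstance(result, ScanResult):
        return [result]
    return list(result)


def unique_partial_chorotypes(
    result: ScanResult | Iterable[ScanResult],
) -> list[UniquePartial]:
    """Deduplicate recorded partial chorotypes by exact species-set equality.

    Accepts one scan result or several (e.g. scans at different depth
    caps) and pools them.  Per distinct set, the widest threshold
    interval observed is kept, along with every generating reference and
    the minimum closure depth.
    """
    pools: dict[frozenset[str], list[PartialChorotype]] = {}
    for res in _as_results(result):
        for p in res.all_partials():
            pools.setdefault(p.species, []).append(p)
    out = []
    for species, parts in pools.items():
        refs = tuple(sorted({p.reference for p in parts}))
        out.append(
            UniquePartial(
                species=species,
                ct_max=max(p.ct_max for p in parts),
                ct_min=min(p.ct_min for p in parts),
                references=refs,
                depth_min=min(p.depth for p in parts),
                common_area=parts[0].common_area,
                total_area=parts[0].total_area,
            )
        )
    # deterministic order: by descending ct_max, then richness, then members
    out.sort(key=lambda u: (-u.ct_max, u.richness, tuple(sorted(u.species))))
    return out


def _mean_cs_to_others(ref: str, chorotype: Chorotype) -> float:
    """Mean congruence of ``ref`` with the other members of its final set."""
    final = chorotype.partials[-1]
    others = [s for s in final.species if s != ref]
    if not others:
        return 0.0
    return sum(final.per_species[s][0] for s in others) / len(others)


def find_synonyms(
    result: ScanResult, strict: bool = False
) -> list[ChorotypeFamily]:
    """Group informative references into synonymous chorotype families.

    By default two chorotypes are synonymous when their final (lowest
    threshold, most inclusive) partials have equal species sets.  With
    ``strict=True`` the whole sequence of partial compositions must
    match.
    """
    groups: dict[tuple, list[str]] = {}
    for ch in result:
        if not ch.informative:
            continue
        if strict:
            key = tuple(p.species for p in ch.partials)
        else:
            key = (ch.final_species,)
        groups.setdefault(key, []).append(ch.reference)

    families = []
    for key, refs in groups.items():
        canonical = key[-1]
        scored = sorted(
            refs, key=lambda r: (-_mean_cs_to_others(r, result[r]), r)
        )
        families.append(
            ChorotypeFamily(
                name=scored[0],
                canonical_set=canonical,
                synonyms=tuple(sorted(refs)),
                members_by_reference={
                    r: result[r].final_species for r in sorted(refs)
                },
            )
        )
    families.sort(key=lambda f: f.name)
    return families


def find_nested(
    uniques: Sequence[UniquePartial | frozenset],
) -> list[tuple[frozenset[str], frozenset[str]]]:
    """All strict-subset pairs (subset, superset) among unique species sets."""
    sets = sorted(
        {u.species if isinstance(u, UniquePartial) else frozenset(u) for u in uniques},
        key=lambda s: (len(s), tuple(sorted(s))),
    )
    pairs = []
    for i, a in enumerate(sets):
        for b in sets[i + 1 :]:
            if len(a) < len(b) and a < b:
                pairs.append((a, b))
    return pairs


def disjoint_zones(
    uniques: Sequence[UniquePartial | frozenset],
) -> list[frozenset[str]]:
    """A maximum-cardinality collection of mutually species-disjoint sets.

    Picks, among the unique partial chorotypes, as many groups as
    possible such that no species belongs to two of them -- the
    non-overlapping "zones" into which the recovered patterns classify
    the pool.  Exact search (branch and bound); ties are resolved
    deterministically in favour of lexicographically earlier sets.
    """
    sets = sorted(
        {u.species if isinstance(u, UniquePartial) else frozenset(u) for u in uniques},
        key=lambda s: (len(s), tuple(sorted(s))),
    )
    best: list[frozenset[str]] = []

    def extend(i: int, chosen: list[frozenset[str]], used: frozenset[str]) -> None:
        nonlocal best
        if len(chosen) + (len(sets) - i) <= len(best):
            return
        if i == len(sets):
            if len(chosen) > len(best):
                best = list(chosen)
            return
        s = sets[i]
        if not (s & used):
            chosen.append(s)
            extend(i + 1, chosen, used | s)
            chosen.pop()
        extend(i + 1, chosen, used)

    extend(0, [], frozenset())
    return best


def find_independent_overlaps(
    families: Sequence[ChorotypeFamily],
    ranges: Mapping[str, SpeciesRange],
) -> list[tuple[ChorotypeFamily, ChorotypeFamily]]:
    """Pairs of families with no species in common but positive shared area.

    These are independent chorotypes centered on overlapping regions --
    patterns a species-disjoint classification would conflate.
    """
    unions = {
        f.name: union_all([ranges[s].geometry for s in f.canonical_set])
        for f in families
    }
    out = []
    for i, fa in enumerate(families):
        for fb in families[i + 1 :]:
            if fa.canonical_set & fb.canonical_set:
                continue
            inter = unions[fa.name].intersection(unions[fb.name])
            min_area = min(unions[fa.name].area, unions[fb.name].area)
            if not inter.is_empty and inter.area > OVERLAP_REL_TOL * min_area:
                out.append((fa, fb))
    return out


def informative_species(result: ScanResult | Iterable[ScanResult]) -> frozenset[str]:
    """Species giving rise to or composing at least one partial chorotype.

    Membership alone confers informative status: a pool species never
    used as a reference is informative if it appears in any recorded
    group.
    """
    species: set[str] = set()
    for res in _as_results(result):
        for p in res.all_partials():
            species |= p.species
            species.add(p.reference)
    return frozenset(species)


def informative_summary(result: ScanResult) -> dict:
    """Counts of informative/non-informative references, families, richness."""
    info = informative_species(result)
    refs = result.references
    informative_refs = [r for r in refs if r in info]
    uniques = unique_partial_chorotypes(result)
    richness: dict[int, int] = {}
    for u in uniques:
        richness[u.richness] = richness.get(u.richness, 0) + 1
    return {
        "n_references": len(refs),
        "n_informative_references": len(informative_refs),
        "n_noninformative_references": len(refs) - len(informative_refs),
        "n_informative_species": len(info),
        "n_unique_partial_chorotypes": len(uniques),
        "n_families": len(find_synonyms(result)),
        "richness_distribution": {k: richness[k] for k in sorted(richness)},
    }
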