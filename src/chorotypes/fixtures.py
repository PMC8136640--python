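"""Synthetic range communities with known congruence structure.

Two generators are provided.  ``kreft_jetz_gradient`` builds the
classic two-center test problem: thirty latitudinal range bars in a
southern (S1-S15) and a northern (N16-N30) group, each a succession of
ranges every one slightly longer than the last, so that the widest
ranges of the two groups overlap across a transition zone.  A sound
chorotype method must separate the two groups and must not report the
transition zone as a unit of its own.  ``random_syndrome_community``
plants seeded communities realizing the classic range "syndromes"
(nuclear congruence, habitat tracking, expansion gradients, linear
gradients, disjunct ranges) with ground-truth membership, for property
testing.

All bars are realized as thin rectangles so the full two-dimensional
polygon code path is exercised; lengths are in arbitrary planar map
units.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import box
from shapely import union_all

from .congruence import SpeciesRange

__all__ = [
    "GradientSpec",
    "SyndromeSpec",
    "kreft_jetz_gradient",
    "random_syndrome_community",
]

# Deviations from the uniformly graded range increments ("small arrows"
# of the original scheme), as additive length deltas in map units.
# Because congruence is a ratio of lengths, grading happens in ratio
# space: these deltas spread the consecutive length ratios of each group
# over distinct 1% threshold cells and place zones of range
# discontinuity inside each group.  Together with the reduced increments
# among N28-N30 they make up the documented reference parametrization;
# the calibration is explained in docs/methods.md.
DEFAULT_EXCEPTIONS: dict[str, float] = {
    "S1": -11.3, "S2": -9.2, "S3": -4.8, "S4": 2.8, "S5": 6.6,
    "S6": 10.0, "S7": 10.0, "S8": 10.0, "S9": 10.0, "S10": 10.0,
    "S11": 24.0, "S12": 26.2, "S13": 29.3, "S14": 31.2, "S15": 32.4,
    "N16": 32.4, "N17": 31.2, "N18": 29.3, "N19": 26.2, "N20": 24.0,
    "N21": 10.0, "N22": 10.0, "N23": 10.0, "N24": 10.0, "N25": 7.0,
    "N26": 3.6, "N27": 0.3,
}


@dataclass(frozen=True)
class GradientSpec:
    """Parametrization of the thirty-species two-center gradient.

    South bar k (k = 1..15) spans ``base_length + (k-1) * increment``
    map units northward from the southern origin; north bars mirror
    them southward from the northern edge, except that the three
    smallest northern ranges (N28-N30) are spaced by
    ``reduced_increment`` < ``increment``, which widens the range
    discontinuity between N27 and N28.  The widest bars of the two
    groups (S15, N16) overlap by ``overlap_span``.  ``exceptions`` adds
    per-species length deltas reproducing the small deviations of the
    original scheme.  All bars share an identical longitudinal extent
    (``bar_width``), so every pair of bars with overlapping latitudinal
    spans overlaps spatially.
    """

    n_south: int = 15
    n_north: int = 15
    base_length: float = 30.0
    increment: float = 5.0
    overlap_span: float = 47.7
    reduced_increment: float = 2.0
    bar_width: float = 10.0
    origin: tuple[float, float] = (0.0, 0.0)
    exceptions: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EXCEPTIONS)
    )

    def south_lengths(self) -> dict[str, float]:
        out = {}
        for k in range(1, self.n_south + 1):
            sid = f"S{k}"
            out[sid] = (
                self.base_length
                + (k - 1) * self.increment
                + self.exceptions.get(sid, 0.0)
            )
        return out

    def north_lengths(self) -> dict[str, float]:
        """Mirrored lengths; the three smallest northern ranges are compressed."""
        n = self.n_north
        out = {}
        for i in range(n):  # N16 largest ... N(15+n) smallest
            sid = f"N{16 + i}"
            rank = n - i  # 1 = smallest
            if rank <= 3:
                length = self.base_length + (rank - 1) * self.reduced_increment
            else:
                length = self.base_length + (rank - 1) * self.increment
            out[sid] = length + self.exceptions.get(sid, 0.0)
        return out

    def domain_height(self) -> float:
        south = self.south_lengths()
        north = self.north_lengths()
        return max(south.values()) + max(north.values()) - self.overlap_span

    def validate(self) -> None:
        south, north = self.south_lengths(), self.north_lengths()
        height = self.domain_height()
        for sid, length in {**south, **north}.items():
            if length <= 0:
                raise ValueError(f"non-positive bar length for {sid}")
            if length > height:
                raise ValueError(f"bar {sid} exceeds the latitudinal domain")
        if not 0 < self.overlap_span < min(max(south.values()), max(north.values())):
            raise ValueError("overlap_span must be positive and smaller than the widest bars")
        if not 0 < self.reduced_increment <= self.increment:
            raise ValueError("need 0 < reduced_increment <= increment")


def kreft_jetz_gradient(spec: GradientSpec = GradientSpec()) -> list[SpeciesRange]:
    """Build the thirty-bar gradient community (deterministic).

    Returns the ranges in order S1..S15, N16..N30.  South bars are
    anchored at the southern origin and grow northward with k; north
    bars are anchored at the northern edge and grow southward.  Within
    each group consecutive ranges are nested, so their congruence is
    exactly the ratio of their lengths.
    """
    spec.validate()
    x0, y0 = spec.origin
    x1 = x0 + spec.bar_width
    height = spec.domain_height()
    ranges = []
    for sid, length in spec.south_lengths().items():
        ranges.append(SpeciesRange(sid, box(x0, y0, x1, y0 + length)))
    for sid, length in spec.north_lengths().items():
        ranges.append(SpeciesRange(sid, box(x0, y0 + height - length, x1, y0 + height)))
    return ranges


@dataclass(frozen=True)
class SyndromeSpec:
    """One planted syndrome of congruent ranges.

    kind
        'nuclear' (a common core range with positional jitter),
        'habitat-tracking' (an elongated band followed with jitter),
        'expansion-gradient' (concentric ranges growing from a core),
        'linear-gradient' (equal ranges shifted stepwise along an axis),
        'disjunct' (two far-apart patches shared by all species).
    n_species, seed
        Community size and RNG seed (reproducible for a given seed).
    center, scale
        Location and linear size of the core range, map units.
    jitter
        Positional noise as a fraction of ``scale``.
    step
        Per-species growth (expansion) or shift (linear) fraction.
    prefix
        Species id prefix, e.g. 'nuc' -> 'nuc1', 'nuc2', ...
    """

    kind: str = "nuclear"
    n_species: int = 5
    seed: int = 0
    center: tuple[float, float] = (0.0, 0.0)
    scale: float = 10.0
    jitter: float = 0.1
    step: float = 0.25
    prefix: str = ""

    KINDS = (
        "nuclear",
        "habitat-tracking",
        "expansion-gradient",
        "linear-gradient",
        "disjunct",
    )

    def __post_init__(self) -> None:
        if self.kind not in self.KINDS:
            raise ValueError(f"unknown syndrome kind {self.kind!r}")
        if self.n_species < 1:
            raise ValueError("n_species must be >= 1")


def random_syndrome_community(
    spec: SyndromeSpec,
) -> tuple[list[SpeciesRange], frozenset[str]]:
    """Generate one syndrome community and its ground-truth membership.

    Returns ``(ranges, members)`` where ``members`` is the id set of the
    species planted as a single congruent group (all of them).
    """
    rng = np.random.default_rng(spec.seed)
    cx, cy = spec.center
    s = spec.scale
    prefix = spec.prefix or spec.kind.split("-")[0]
    ranges = []
    for i in range(spec.n_species):
        sid = f"{prefix}{i + 1}"
        dx, dy = rng.uniform(-spec.jitter * s, spec.jitter * s, size=2)
        if spec.kind == "nuclear":
            geom = box(cx - s / 2 + dx, cy - s / 2 + dy, cx + s / 2 + dx, cy + s / 2 + dy)
        elif spec.kind == "habitat-tracking":
            # elongated band (aspect 6:1) tracked with jitter along its axis
            geom = box(
                cx - 3 * s + 6 * dx, cy - s / 2 + dy, cx + 3 * s + 6 * dx, cy + s / 2 + dy
            )
        elif spec.kind == "expansion-gradient":
            half = s / 2 * (1.0 + spec.step * i)
            geom = box(cx - half + dx, cy - half + dy, cx + half + dx, cy + half + dy)
        elif spec.kind == "linear-gradient":
            shift = spec.step * s * i
            geom = box(
                cx - s / 2 + shift + dx, cy - s / 2 + dy,
                cx + s / 2 + shift + dx, cy + s / 2 + dy,
            )
        else:  # disjunct: two far-apart patches, both part of every range
            gap = 10 * s
            geom = union_all(
                [
                    box(cx - s / 2 + dx, cy - s / 2 + dy, cx + s / 2 + dx, cy + s / 2 + dy),
                    box(
                        cx + gap - s / 2 + dx, cy - s / 2 + dy,
                        cx + gap + s / 2 + dx, cy + s / 2 + dy,
                    ),
                ]
            )
        ranges.append(SpeciesRange(sid, geom))
    return ranges, frozenset(r.species_id for r in ranges)
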