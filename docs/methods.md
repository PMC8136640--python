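# Methods

## Model

Spatial Congruence Analysis treats the species pool as a one-layer network:
species are vertices, and each pair of ranges is connected by its spatial
congruence

    C_S(a, b) = (O / A_a) · (O / A_b),

the product of the fraction of each range covered by the mutual overlap
area *O*. The index is symmetric, bounded in [0, 1], equals the area ratio
for nested ranges, and is invariant to rigid motions of the pair. It
compares whole vector ranges, so there is no grid-cell scale parameter; the
price is that all areas must be computed in an equal-area planar projection
(see *Coordinates* below).

Chorotypes are recovered per **reference species** by a breadth-first
closure at an explicit **congruence threshold** C_T: level 1 admits every
species with C_S ≥ C_T to the reference, level *k* admits every remaining
species with C_S ≥ C_T to any level-(*k*−1) member, and the group *closes*
when a level admits nothing. The number of levels that admitted members is
the group's **depth**. With the threshold explicit, the whole sweep
C_T = ct_max, ct_max − step, … ≥ ct_min is informative: each closed
composition, recorded with the contiguous threshold interval over which it
is stable, is a **partial chorotype**; the full set per reference is its
**chorotype**. Closure is what makes the result non-trivial — a group
closes only if its members are collectively discontinuous from the rest of
the pool at that congruence level.

Two assumptions are inherited from all range-based biogeography: that
ranges and their direct/indirect spatial relationships are meaningful
units, and that the input polygons represent distributions adequately at
the scale of interest.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_depth` | 7 | maximum breadth-first passes before a group must close |
| `ct_max`, `ct_min` | 1.0, 0.1 | threshold sweep limits (dimensionless congruence) |
| `ct_step` | 0.01 | threshold resolution (1% increments) |
| `overlap_criterion` | on | admitted ranges must overlap all current members |
| `cs_epsilon` | 1e-9 | tolerance of the inclusive comparison C_S ≥ C_T |
| `store_floor` | = ct_min | network edges below it are not stored (cannot activate) |

`max_depth` and `ct_min` are limiting parameters: the first threshold round
at which the expansion fails — members were admitted at the depth cap while
a further pass would admit more, or the group's joint common area became
empty — terminates that reference's sweep entirely. Singleton closures are
skipped silently (otherwise every sweep would end at C_T = 1).

The **spatial overlap criterion** is evaluated per candidate against every
current member pairwise: a candidate admitted on congruence must share
positive overlap area with *all* previously grouped species, otherwise it
is skipped (the round continues without it). Pairwise overlap does not
guarantee a joint overlap for polygons, so if the common intersection of
all members is empty at the end of a level, the round is dropped and the
sweep stops (`overlap_violated`). Within a level, candidates are evaluated
in descending congruence to their linking member, ties broken by species
id; the fixed order makes results reproducible because members admitted
earlier in a level participate in the overlap checks of later candidates.

## Numerical conventions

- The threshold grid is generated from integer multiples of `ct_step`, so
  ~90 sweep iterations accumulate no float drift, and grid values are exact
  two-decimal numbers.
- Overlap areas below 1e-12 of the smaller range count as zero: ranges that
  merely touch along a boundary do not overlap.
- Invalid polygons are repaired once by zero-width buffering; a geometry
  still invalid afterwards, or with non-positive area, is an input error
  naming the species.
- Multipolygon parts are one species range: disjunct distributions are a
  single vertex of the network.
- Congruences reported for members linked indirectly (below the network's
  store floor) are recomputed exactly from the geometries.

### Coordinates

Because C_S is a ratio of planar areas, inputs that look like raw
longitude/latitude are refused. Callers can assert planarity
(`projection="planar"`) or request the built-in spherical Lambert
cylindrical equal-area transform (`projection="cea"`, output in km), which
preserves the area ratios the index uses up to the spherical approximation
of the figure of the Earth.

## Post-processing

Partial chorotypes are deduplicated across references by exact species-set
equality, keeping the widest threshold interval observed. References whose
*final* (lowest-threshold, most inclusive) partials coincide are synonymous
and form a family named after the reference with the highest mean C_S to
the other members of the canonical set (ties: lexicographic; a stricter
mode compares whole partial sequences). A species is **informative** if it
gives rise to *or* composes at least one partial chorotype — membership
alone suffices, so pool species never scanned as references can be
informative. Zones are computed as a maximum-cardinality collection of
mutually species-disjoint unique partials (exact branch-and-bound;
deterministic tie-break toward lexicographically earlier sets). Families
with no species in common but positive intersection of their union
geometries are reported as independent overlapping chorotypes.

## The gradient fixture

`kreft_jetz_gradient` builds the classic two-center test community:
thirty bars of identical longitudinal extent, S1–S15 anchored at the
southern edge and growing northward, N16–N30 mirrored from the northern
edge, with the widest bars of the two groups overlapping across a
transition zone (overlap 47.7 units; cross-group congruence 0.13, so the
two groups connect only at very relaxed thresholds). Within each group
consecutive bars are nested, so their congruence is exactly the ratio of
their lengths, and the whole closure dynamic is governed by the sequence of
consecutive length ratios relative to the 1% threshold grid.

The source scheme is published only as a drawing, so the exact lengths are
documented constants of this package, chosen to realize its qualitative
structure in ratio space: uniformly graded cores (increment 5 on base 30),
a handful of deviations ("exceptions") that place zones of range
discontinuity inside each group and spread the within-group ratios over
distinct 1% cells, and reduced increments (2) among N28–N30 that widen the
discontinuity at the northern extreme and make the three smallest northern
ranges mutually congruent. Under the default sweep this parametrization
yields small, highly congruent groups next to the discontinuities at high
thresholds, whole-group closure at low thresholds, 23 unique partial
chorotypes pooled over depth caps 3–10 (11 southern, 12 northern), 27 of 30
references informative at depth 3, five species-disjoint zones at that
depth, and never a mixed or transition-zone group — the inventory the
acceptance script recomputes. The three smallest southern ranges are the
depth-3 casualties: each first connects into an already-large group that no
surviving reference can close within three passes.

## Synthetic syndromes

`random_syndrome_community` plants seeded communities of the classic range
syndromes — nuclear congruence, habitat tracking, expansion gradients,
linear gradients, disjunct ranges — as jittered rectangles with known
membership. They emulate the *topology* of real range relationships
(nesting, chained overlap, disjunction) but not the irregular outlines,
holes, or heavy-tailed size distributions of real range maps; passing tests
on them demonstrates the algorithmic contracts (closure = thresholded
connectivity, determinism, criterion semantics), not cartographic realism.

## Scope and limitations

- Only polygon ranges are supported; grid-cell or probabilistic
  (model-surface) congruence variants would need a different index backend.
- Results at continental scale depend on the projection chosen; the
  built-in cylindrical equal-area transform is spherical, not ellipsoidal.
- The admission-order convention inside a level is a tie-break of this
  implementation; compositions can in principle differ from
  implementations that evaluate candidates in another order when the
  overlap criterion rejects some of them.
- Whole-pool analyses are quadratic in the number of species at the
  network-construction step; the thirty-species reference community scans
  in seconds, and a few thousand species are practical because the sweep
  itself touches only stored edges.
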