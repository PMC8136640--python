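"""Planted range syndromes and what the scan recovers from them.

Generates seeded communities realizing classic syndromes of shared
distributions -- a nuclear region of congruence and an expansion
gradient -- plus an isolated outlier, then scans the combined pool.
The planted groups are recovered as separate chorotypes and the
outlier stays non-informative.
"""

from shapely.geometry import box

from chorotypes import (
    ScanParams,
    SpeciesRange,
    SyndromeSpec,
    build_network,
    find_synonyms,
    informative_species,
    random_syndrome_community,
    scan_all,
)

nuclear, nuclear_truth = random_syndrome_community(
    SyndromeSpec(kind="nuclear", n_species=4, jitter=0.05, seed=7, prefix="nuc")
)
gradient, gradient_truth = random_syndrome_community(
    SyndromeSpec(kind="expansion-gradient", n_species=5, step=0.15, jitter=0.02,
                 seed=8, center=(200.0, 0.0), prefix="exp")
)
outlier = SpeciesRange("lone1", box(800, 800, 810, 810))

pool = nuclear + gradient + [outlier]
rmap = {r.species_id: r for r in pool}
network = build_network(pool, store_floor=0.1)
result = scan_all(list(rmap), network, rmap, ScanParams())

print("planted groups:")
print(f"  nuclear syndrome: {sorted(nuclear_truth)}")
print(f"  expansion gradient: {sorted(gradient_truth)}")

print("\nrecovered chorotype families:")
for fam in find_synonyms(result):
    print(f"  {fam.name}: {sorted(fam.canonical_set)}")

info = informative_species(result)
print(f"\ninformative species: {len(info)} of {len(pool)}; "
      f"'lone1' informative: {'lone1' in info}")
print("Both planted syndromes are recovered exactly and never merge;")
print("the isolated range composes no group, hence is non-informative.")
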