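import numpy as np
import networkx as nx
import pytest
from shapely import union_all
from shapely.geometry import box

from conftest import random_box_community
from chorotypes import (
    ScanParams,
    SpeciesRange,
    Termination,
    build_network,
    expand_at_threshold,
    scan_all,
    scan_reference,
)
from chorotypes.core import ExpansionFailure


class TestScanParams:
    def test_defaults_match_standard_settings(self):
        p = ScanParams()
        assert (p.max_depth, p.ct_max, p.ct_min, p.ct_step) == (7, 1.0, 0.1, 0.01)
        assert p.overlap_criterion

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_depth": 0},
            {"ct_min": 0.0},
            {"ct_min": 0.5, "ct_max": 0.4},
            {"ct_max": 1.2},
            {"ct_step": 0.0},
        ],
    )
    def test_invalid_parameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            ScanParams(**kwargs)

    def test_ct_grid_exact_decimals(self):
        grid = ScanParams().ct_grid()
        assert len(grid) == 91
        assert grid[0] == 1.0 and grid[-1] == 0.1
        # exact decimal steps, no float drift over the sweep
        assert all(ct == round(ct, 2) for ct in grid)
        assert 0.93 in grid and 0.57 in grid  # cells prone to float drift
        assert grid == sorted(grid, reverse=True)


class TestExpansion:
    def test_direct_only(self, bars_net, bars_map):
        exp = expand_at_threshold("A", 0.80, bars_net, bars_map, ScanParams())
        assert exp.species == {"A", "B"} and exp.closed
        assert exp.closure_depth == 1
        assert exp.members["B"].via == "A"

    def test_indirect_link(self, bars_net, bars_map):
        exp = expand_at_threshold("A", 0.60, bars_net, bars_map, ScanParams())
        assert exp.species == {"A", "B", "C"} and exp.closed
        assert exp.closure_depth == 2
        assert exp.members["C"].via == "B"  # C joins through B

    def test_singleton_closure(self, bars_net, bars_map):
        exp = expand_at_threshold("A", 0.90, bars_net, bars_map, ScanParams())
        assert exp.species == {"A"} and exp.closed and exp.closure_depth == 0

    def test_depth_cap_failure(self, bars_net, bars_map):
        exp = expand_at_threshold("A", 0.60, bars_net, bars_map, ScanParams(max_depth=1))
        assert not exp.closed
        assert exp.failure == ExpansionFailure.MAX_DEPTH_REACHED

    def test_unknown_reference(self, bars_net, bars_map):
        with pytest.raises(KeyError, match="Z"):
            expand_at_threshold("Z", 0.5, bars_net, bars_map, ScanParams())

    def test_candidate_without_full_overlap_is_skipped(self):
        """A congruent range that misses one member is left out; the group
        still closes (the spatial overlap criterion rejects candidates,
        not whole rounds, while the common area stays positive)."""
        ranges = [
            SpeciesRange("a", box(0, 0, 10, 1)),
            SpeciesRange("b", box(0, 0, 11, 1)),
            SpeciesRange("c", box(9.5, 0, 20, 1)),  # overlaps b, barely a... not a
        ]
        # c overlaps b on [9.5, 11] and a on [9.5, 10]: shrink a so c misses it
        ranges[0] = SpeciesRange("a", box(0, 0, 9, 1))
        net = build_network(ranges, store_floor=0.01)
        rmap = {r.species_id: r for r in ranges}
        params = ScanParams(ct_min=0.01)
        exp = expand_at_threshold("a", 0.02, net, rmap, params)
        assert exp.closed and "c" not in exp.species

    def test_empty_common_area_drops_the_round(self):
        """Pairwise-overlapping ranges whose joint intersection is empty
        violate the criterion and fail the threshold round."""
        a = SpeciesRange("a", box(0, 0, 6, 2))
        b = SpeciesRange("b", box(4, 0, 10, 2))
        # c overlaps a on the left and b on the right, but avoids [4,6]
        c = SpeciesRange(
            "c", union_all([box(0, 0, 3, 2), box(7, 0, 10, 2)])
        )
        net = build_network([a, b, c], store_floor=0.01)
        rmap = {"a": a, "b": b, "c": c}
        params = ScanParams(ct_min=0.01)
        exp = expand_at_threshold("a", 0.05, net, rmap, params)
        assert not exp.closed
        assert exp.failure == ExpansionFailure.OVERLAP_VIOLATED


class TestScanReference:
    def test_bars_sweep(self, bars_net, bars_map):
        ch = scan_reference("A", bars_net, bars_map, ScanParams())
        assert ch.informative
        assert [tuple(sorted(p.species)) for p in ch.partials] == [
            ("A", "B"),
            ("A", "B", "C"),
        ]
        p1, p2 = ch.partials
        assert (p1.ct_max, p1.ct_min) == (0.83, 0.70)
        assert (p2.ct_max, p2.ct_min) == (0.69, 0.10)
        assert ch.termination == Termination.MIN_CT_REACHED
        assert p2.common_area == pytest.approx(8.0)
        assert p2.total_area == pytest.approx(14.0)
        assert p2.ratio == pytest.approx(8 / 14)

    def test_depth_capped_sweep_terminates_early(self, bars_net, bars_map):
        ch = scan_reference("A", bars_net, bars_map, ScanParams(max_depth=1))
        assert [tuple(sorted(p.species)) for p in ch.partials] == [("A", "B")]
        assert ch.partials[0].ct_min == 0.70
        assert ch.termination == Termination.MAX_DEPTH_REACHED

    def test_isolated_reference_is_uninformative(self, bars):
        far = SpeciesRange("D", box(100, 100, 101, 101))
        ranges = bars + [far]
        net = build_network(ranges, store_floor=0.1)
        ch = scan_reference("D", net, {r.species_id: r for r in ranges}, ScanParams())
        assert not ch.informative and ch.partials == []
        assert ch.termination == Termination.NO_CLOSURE

    def test_threshold_intervals_descend_without_overlap(self, bars_net, bars_map):
        ch = scan_reference("A", bars_net, bars_map, ScanParams())
        for earlier, later in zip(ch.partials, ch.partials[1:]):
            assert earlier.ct_min > later.ct_max


class TestScanAll:
    def test_bars_all_references_converge(self, bars_net, bars_map):
        res = scan_all(["A", "B", "C"], bars_net, bars_map, ScanParams())
        assert all(ch.informative for ch in res)
        assert {ch.final_species for ch in res} == {frozenset("ABC")}

    def test_empty_reference_list(self, bars_net, bars_map):
        assert len(scan_all([], bars_net, bars_map, ScanParams())) == 0

    def test_unknown_reference_fails_before_computation(self, bars_net, bars_map):
        with pytest.raises(KeyError, match="nope"):
            scan_all(["A", "nope"], bars_net, bars_map, ScanParams())

    def test_reference_subset_uses_full_pool(self, bars_net, bars_map):
        res = scan_all(["A"], bars_net, bars_map, ScanParams())
        assert res.references == ["A"]
        assert res["A"].final_species == frozenset("ABC")  # B, C joined as members


# --------------------------------------------------------------------------
# properties against a brute-force oracle


def _component_at(net, ranges, reference, ct):
    """Brute-force oracle: connected component of the thresholded graph."""
    g = nx.Graph()
    g.add_nodes_from(r.species_id for r in ranges)
    for e in net.edges():
        if e.cs >= ct - 1e-9:
            g.add_edge(e.species_a, e.species_b)
    return frozenset(nx.node_connected_component(g, reference))


def _scan_setup(rng, n):
    ranges = random_box_community(rng, n)
    net = build_network(ranges, store_floor=0.01)
    return ranges, net, {r.species_id: r for r in ranges}


def test_closure_equals_connected_component(seed=20260925):
    """With the overlap criterion off and no depth cap, a closed group is
    exactly the reference's connected component at that threshold."""
    rng = np.random.default_rng(seed)
    params = ScanParams(
        max_depth=15, ct_min=0.05, overlap_criterion=False
    )
    for _ in range(60):
        n = int(rng.integers(3, 13))
        ranges, net, rmap = _scan_setup(rng, n)
        for ct in rng.uniform(0.05, 0.95, size=3):
            ref = ranges[int(rng.integers(n))].species_id
            exp = expand_at_threshold(ref, float(ct), net, rmap, params)
            assert exp.closed
            assert exp.species == _component_at(net, ranges, ref, float(ct))


def test_threshold_monotonicity_without_criterion(seed=7):
    """Lowering the threshold never shrinks the closed member set."""
    rng = np.random.default_rng(seed)
    params = ScanParams(max_depth=15, ct_min=0.05, overlap_criterion=False)
    for _ in range(25):
        ranges, net, rmap = _scan_setup(rng, int(rng.integers(4, 13)))
        ref = ranges[0].species_id
        prev = None
        for ct in (0.9, 0.7, 0.5, 0.3, 0.1):
            exp = expand_at_threshold(ref, ct, net, rmap, params)
            if prev is not None:
                assert prev <= exp.species
            prev = exp.species


def test_closure_symmetry_without_criterion(seed=11):
    """Expansion from any member of a closed group yields the same group."""
    rng = np.random.default_rng(seed)
    params = ScanParams(max_depth=15, ct_min=0.05, overlap_criterion=False)
    for _ in range(25):
        ranges, net, rmap = _scan_setup(rng, int(rng.integers(4, 13)))
        ref = ranges[0].species_id
        ct = float(rng.uniform(0.1, 0.8))
        group = expand_at_threshold(ref, ct, net, rmap, params).species
        for member in group:
            assert expand_at_threshold(member, ct, net, rmap, params).species == group


def test_depth_bound_and_no_singleton_partials(seed=3):
    rng = np.random.default_rng(seed)
    for _ in range(15):
        ranges, net, rmap = _scan_setup(rng, int(rng.integers(4, 11)))
        params = ScanParams(max_depth=int(rng.integers(1, 6)), ct_min=0.05)
        res = scan_all([r.species_id for r in ranges], net, rmap, params)
        for ch in res:
            for p in ch.partials:
                assert p.depth <= params.max_depth
                assert len(p.species) >= 2
                assert p.reference in p.species
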