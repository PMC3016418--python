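import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pooldeconv.deconvolution import (
    SCORE_DECIMALS,
    candidate_clones,
    contains,
    count_FN,
    deconvolute_marker,
    find_C2,
    overlaps,
    plate_intersections,
    score,
    spans,
)
from pooldeconv.design import (
    CloneAddress,
    LibrarySpec,
    build_design,
    format_clone_name,
)
from pooldeconv.fpc_io import SINGLETON_CTG, ContigClone, ContigMap, MarkerHits


def brute_force_candidates(design, rsp_hits, csp_hits, rp_hits, cp_hits):
    """Independent oracle: enumerate every well of every plate and keep the
    clones whose own five pools are all among the positive ones."""
    out = set()
    for clone in design.clones():
        pools = {p.kind: p.index for p in design.true_pool_hits(clone)}
        if (
            pools["RSP"] in rsp_hits
            and pools["CSP"] in csp_hits
            and pools["RP"] in rp_hits
            and pools["CP"] in cp_hits
        ):
            out.add(clone)
    return out


@pytest.fixture
def design_16_plates():
    """16 one-library plates on a full 4x4 matrix, one sub-pool."""
    return build_design([LibrarySpec("SA", 16)], (4, 4))


@pytest.fixture
def design_16_plates_4_subs():
    return build_design([LibrarySpec("SA", 16)], (4, 4), sub_pool_plan={"SA": 4})


class TestPlateIntersections:
    def test_5x6_hits_give_30_plates(self, five_lib_design):
        plates = plate_intersections(range(1, 6), range(1, 7), five_lib_design.matrix)
        assert len(plates) == 30

    def test_1x1(self, design_16_plates):
        assert plate_intersections([2], [3], design_16_plates.matrix) == {("SA", 7)}

    def test_empty_cell_excluded(self):
        # 3 plates on a 2x2 matrix: cell (2,2) is empty
        d = build_design([LibrarySpec("SA", 3)], (2, 2))
        plates = plate_intersections([1, 2], [1, 2], d.matrix)
        # enumeration oracle: all four cells minus the empty one
        expected = {d.matrix.cells[rc] for rc in [(1, 1), (1, 2), (2, 1)]}
        assert plates == expected
        assert len(plates) == 3

    def test_empty_input(self, design_16_plates):
        assert plate_intersections([], [1, 2], design_16_plates.matrix) == set()


class TestCandidateClones:
    def test_256_candidates_without_sub_pooling(self, design_16_plates):
        d = design_16_plates
        plates = plate_intersections([1, 2, 3, 4], [1, 2, 3, 4], d.matrix)
        assert len(plates) == 16
        cand = candidate_clones(
            plates,
            {("SA", r) for r in "ABCD"},
            {("SA", c) for c in (1, 2, 3, 4)},
            d,
        )
        assert len(cand.clones) == 256

    def test_64_candidates_with_4_sub_pools(self, design_16_plates_4_subs):
        d = design_16_plates_4_subs
        plates = plate_intersections([1, 2, 3, 4], [1, 2, 3, 4], d.matrix)
        rp = {(f"SA.{k}", row) for k, row in zip((1, 2, 3, 4), "ABCD")}
        cp = {(f"SA.{k}", k) for k in (1, 2, 3, 4)}
        cand = candidate_clones(plates, rp, cp, d, library_filter=False)
        assert len(cand.clones) == 64
        assert cand.per_sub_pool == {f"SA.{k}": 16 for k in (1, 2, 3, 4)}

    def test_no_rp_hits_gives_empty_set(self, design_16_plates):
        plates = plate_intersections([1], [1], design_16_plates.matrix)
        cand = candidate_clones(plates, set(), {("SA", 1)}, design_16_plates)
        assert cand.clones == set()

    def test_library_filter_restricts_to_own_sub_pool(self, design_16_plates_4_subs):
        d = design_16_plates_4_subs
        plates = set(d.plates)  # all 16
        cand = candidate_clones(plates, {("SA.1", "A")}, {("SA.1", 1)}, d)
        # SA.1 holds plates 1-4 only
        assert {c.plate for c in cand.clones} == {1, 2, 3, 4}

    def test_matches_brute_force_on_small_designs(self):
        rng = random.Random(99)
        designs = [
            build_design([LibrarySpec("SA", 2), LibrarySpec("SB", 2)], (2, 2)),
            build_design([LibrarySpec("SA", 4)], (2, 2), sub_pool_plan={"SA": 2}),
            build_design([LibrarySpec("SA", 3)], (2, 2)),
        ]
        for d in designs:
            subs = list(d.sub_pools)
            for _ in range(30):
                rsp = {r for r in range(1, d.matrix.n_rows + 1) if rng.random() < 0.5}
                csp = {c for c in range(1, d.matrix.n_cols + 1) if rng.random() < 0.5}
                rp = {(s, r) for s in subs for r in "ABCDEFGHIJKLMNOP" if rng.random() < 0.15}
                cp = {(s, c) for s in subs for c in range(1, 25) if rng.random() < 0.15}
                plates = plate_intersections(rsp, csp, d.matrix)
                cand = candidate_clones(plates, rp, cp, d)
                assert cand.clones == brute_force_candidates(d, rsp, csp, rp, cp)


class TestFingerprintRelations:
    def test_contains_example(self):
        assert contains(frozenset({1, 2}), frozenset({1, 2, 3}))
        assert not contains(frozenset({1, 2, 3}), frozenset({1, 2}))

    def test_spans_example(self):
        a, b, c = frozenset({1, 2, 3}), frozenset({3, 4, 5}), frozenset({2, 3, 4})
        assert spans(a, b, c)
        assert not spans(a, b, frozenset({6}))

    def test_overlaps_example(self):
        assert not overlaps(frozenset({1, 2}), frozenset({9, 10}), min_shared=1)
        assert overlaps(frozenset({1, 2, 3}), frozenset({3, 4}), min_shared=1)
        assert not overlaps(frozenset({1, 2, 3}), frozenset({3, 4}), min_shared=2)

    def test_empty_fingerprints_never_relate(self):
        assert not contains(frozenset(), frozenset({1}))
        assert not overlaps(frozenset({1}), frozenset())

    def test_tolerance_greedy_matching(self):
        # 100 matches 101, 200 matches 201 under tolerance 1
        assert contains(frozenset({100, 200}), frozenset({101, 201}), tolerance=1)
        assert not contains(frozenset({100, 200}), frozenset({103, 201}), tolerance=1)
        # one-to-one: both bands of a cannot consume the single band of b
        assert not contains(frozenset({100, 101}), frozenset({100}), tolerance=1)

    @given(
        a=st.frozensets(st.integers(1, 30), min_size=1, max_size=8),
        b=st.frozensets(st.integers(1, 30), min_size=1, max_size=8),
    )
    def test_exact_contains_is_subset(self, a, b):
        assert contains(a, b) == (a <= b)


def _contig(members):
    return [ContigClone(name, "ctgX", left, right) for name, left, right in members]


class TestFindC2:
    def test_chain_of_five_gives_one_set(self):
        members = _contig(
            [("C1", 0, 10), ("C2", 5, 15), ("C3", 12, 22), ("C4", 20, 30), ("C5", 28, 38)]
        )
        fps = {
            "C1": frozenset({1, 2}),
            "C2": frozenset({2, 3}),
            "C3": frozenset({3, 4}),
            "C4": frozenset({4, 5}),
            "C5": frozenset({5, 6}),
        }
        c2 = find_C2(members, {m.name for m in members}, fps)
        assert c2 == [frozenset({"C1", "C2", "C3", "C4", "C5"})]

    def test_disjoint_pair_gives_no_set(self):
        members = _contig([("C1", 0, 5), ("C2", 50, 60)])
        fps = {"C1": frozenset({1}), "C2": frozenset({9})}
        assert find_C2(members, {"C1", "C2"}, fps) == []

    def test_two_separated_pairs_give_two_sets(self):
        # oracle: relation graph has exactly two components {a,b} and {c,d}
        fps = {
            "A1": frozenset({1, 2}),
            "A2": frozenset({2, 3}),
            "B1": frozenset({10, 11}),
            "B2": frozenset({11, 12}),
        }
        members = _contig([("A1", 0, 5), ("A2", 3, 8), ("B1", 40, 45), ("B2", 43, 48)])
        c2 = find_C2(members, set(fps), fps)
        assert sorted(c2, key=min) == [frozenset({"A1", "A2"}), frozenset({"B1", "B2"})]

    def test_single_candidate_gives_nothing(self):
        members = _contig([("C1", 0, 5)])
        assert find_C2(members, {"C1"}, {"C1": frozenset({1})}) == []

    def test_inclusion_relation_connects(self):
        fps = {"BIG": frozenset({1, 2, 3, 4}), "IN": frozenset({2, 3})}
        members = _contig([("BIG", 0, 10), ("IN", 2, 6)])
        assert find_C2(members, {"BIG", "IN"}, fps) == [frozenset({"BIG", "IN"})]

    def test_spanning_triple_connects_under_min_shared_2(self):
        # C shares only one band with each of A and B, so pairwise overlap
        # fails at min_shared=2, but A and B together span C
        fps = {"A": frozenset({1, 2, 3}), "B": frozenset({5, 6, 7}), "C": frozenset({3, 5})}
        members = _contig([("A", 0, 10), ("B", 8, 20), ("C", 5, 14)])
        c2 = find_C2(members, {"A", "B", "C"}, fps, min_shared=2)
        assert c2 == [frozenset({"A", "B", "C"})]
        # without C's bridging bands there is no relation at all
        fps["C"] = frozenset({40, 50})
        assert find_C2(members, {"A", "B", "C"}, fps, min_shared=2) == []


class TestCountFN:
    def test_all_interior_clones_missing(self):
        members = _contig(
            [("C1", 0, 10), ("C2", 10, 20), ("C3", 20, 30), ("C4", 30, 40), ("C5", 40, 50)]
        )
        assert count_FN({"C1", "C5"}, members, {"C1", "C5"}) == 3

    def test_no_interior_clones(self):
        members = _contig([("C1", 0, 10), ("C2", 5, 15)])
        assert count_FN({"C1", "C2"}, members, {"C1", "C2"}) == 0

    def test_interior_clone_in_C_not_counted(self):
        members = _contig([("C1", 0, 10), ("C2", 10, 20), ("C3", 20, 30)])
        assert count_FN({"C1", "C3"}, members, {"C1", "C3", "C2"}) == 0

    def test_midpoint_rule(self):
        # C4 pokes out beyond the span: midpoint 32.5 > right end 30 -> not FN
        members = _contig([("C1", 0, 10), ("C4", 25, 40), ("C3", 20, 30)])
        assert count_FN({"C1", "C3"}, members, {"C1", "C3"}) == 0


class TestScore:
    def test_maximum_is_one(self):
        assert score(5, 5, 0) == pytest.approx(1.0)

    def test_direct_evaluation(self):
        assert score(2, 4, 1) == pytest.approx(0.5)

    def test_negative_score_triggers_no_solution_rule(self):
        assert score(2, 2, 12) == pytest.approx(-0.2)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            score(2, 0, 0)
        with pytest.raises(ValueError):
            score(0, 2, 0)
        with pytest.raises(ValueError):
            score(2, 2, -1)

    @given(
        nc=st.integers(2, 10),
        extra=st.integers(0, 5),
        fn=st.integers(0, 30),
    )
    def test_score_bounded_above_by_one(self, nc, extra, fn):
        assert score(nc, nc + extra, fn) <= 1.0 + 1e-12


def _map_for(design, placements, fps):
    """placements: contig_id -> [(clone_addr, left, right)]"""
    contigs = {}
    for cid, rows in placements.items():
        contigs[cid] = [
            ContigClone(format_clone_name(a), cid, left, right) for a, left, right in rows
        ]
    return ContigMap(contigs=contigs, fingerprints=fps)


class TestDeconvoluteMarker:
    def test_empty_hits_is_screening_failure(self, design_16_plates):
        res = deconvolute_marker(MarkerHits("M1"), design_16_plates, ContigMap())
        assert res.status == "no_solution"
        assert res.diagnostics.get("screening_failure")

    def test_no_c2_anywhere_is_no_solution(self, design_16_plates):
        d = design_16_plates
        mh = MarkerHits("M1", {1}, {1}, {("SA", "A")}, {("SA", 1)})
        # single candidate SA001A1; alone it cannot form a C2 set
        a = CloneAddress("SA", 1, "A", 1)
        cmap = _map_for(d, {"ctg1": [(a, 0, 10)]}, {format_clone_name(a): frozenset({1})})
        res = deconvolute_marker(mh, d, cmap)
        assert res.status == "no_solution"
        assert res.diagnostics["n_candidates"] == 1

    def test_unique_solution_found(self, design_16_plates):
        d = design_16_plates
        mh = MarkerHits("M1", {1}, {1, 2}, {("SA", "A")}, {("SA", 1)})
        # candidates: SA001A1 and SA002A1 (plates 1 and 2 in matrix row 1)
        a1, a2 = CloneAddress("SA", 1, "A", 1), CloneAddress("SA", 2, "A", 1)
        fps = {format_clone_name(a1): frozenset({1, 2}), format_clone_name(a2): frozenset({2, 3})}
        cmap = _map_for(d, {"ctg1": [(a1, 0, 10), (a2, 5, 15)]}, fps)
        res = deconvolute_marker(mh, d, cmap)
        assert res.status == "unique"
        assert res.solutions[0].clones == frozenset({"SA001A1", "SA002A1"})
        assert res.solutions[0].score == pytest.approx(1.0)

    def test_identical_scores_are_non_unique(self, design_16_plates):
        d = design_16_plates
        mh = MarkerHits("M1", {1}, {1, 2, 3, 4}, {("SA", "A")}, {("SA", 1)})
        # two pairs in two contigs, both perfect: tie
        addrs = [CloneAddress("SA", p, "A", 1) for p in (1, 2, 3, 4)]
        names = [format_clone_name(a) for a in addrs]
        fps = {
            names[0]: frozenset({1, 2}),
            names[1]: frozenset({2, 3}),
            names[2]: frozenset({10, 11}),
            names[3]: frozenset({11, 12}),
        }
        cmap = _map_for(
            d,
            {
                "ctg1": [(addrs[0], 0, 10), (addrs[1], 5, 15)],
                "ctg2": [(addrs[2], 0, 10), (addrs[3], 5, 15)],
            },
            fps,
        )
        res = deconvolute_marker(mh, d, cmap)
        assert res.status == "non_unique"
        top = round(res.solutions[0].score, SCORE_DECIMALS)
        assert round(res.solutions[1].score, SCORE_DECIMALS) == top
        assert res.returned_clones() == set(names)

    def test_negative_best_score_is_no_solution(self, design_16_plates):
        d = design_16_plates
        mh = MarkerHits("M1", {1}, {1, 2}, {("SA", "A")}, {("SA", 1)})
        a1, a2 = CloneAddress("SA", 1, "A", 1), CloneAddress("SA", 2, "A", 1)
        names = [format_clone_name(a1), format_clone_name(a2)]
        fps = {names[0]: frozenset({1, 2}), names[1]: frozenset({2, 3})}
        # 12 interior fillers not in C drive FN up: score 0.8 + 0.2*(1-12/2) < 0
        fillers = [
            (CloneAddress("SA", 9, "B", c), 20 + c, 30 + c) for c in range(1, 13)
        ]
        placements = {"ctg1": [(a1, 0, 100), (a2, 50, 150)] + fillers}
        for f, _, _ in fillers:
            fps[format_clone_name(f)] = frozenset({99})
        cmap = _map_for(d, placements, fps)
        res = deconvolute_marker(mh, d, cmap)
        assert res.status == "no_solution"
        assert res.solutions and res.solutions[0].score <= 0

    def test_singletons_never_in_solutions(self, design_16_plates):
        d = design_16_plates
        mh = MarkerHits("M1", {1}, {1, 2}, {("SA", "A")}, {("SA", 1)})
        a1, a2 = CloneAddress("SA", 1, "A", 1), CloneAddress("SA", 2, "A", 1)
        n1, n2 = format_clone_name(a1), format_clone_name(a2)
        cmap = ContigMap(
            contigs={},
            fingerprints={n1: frozenset({1, 2}), n2: frozenset({2, 3})},
            singletons=[
                ContigClone(n1, SINGLETON_CTG, 0, 10),
                ContigClone(n2, SINGLETON_CTG, 5, 15),
            ],
        )
        res = deconvolute_marker(mh, d, cmap)
        assert res.status == "no_solution"
        assert res.diagnostics["candidates_singletons"] == 2

    def test_mc_taken_across_contigs(self, design_16_plates):
        d = design_16_plates
        mh = MarkerHits("M1", {1, 2}, {1, 2, 3, 4}, {("SA", "A")}, {("SA", 1)})
        # contig1 holds a chained triple, contig2 a pair; MC = 3 for both
        addrs = [CloneAddress("SA", p, "A", 1) for p in (1, 2, 3, 5, 6)]
        names = [format_clone_name(a) for a in addrs]
        fps = {
            names[0]: frozenset({1, 2}),
            names[1]: frozenset({2, 3}),
            names[2]: frozenset({3, 4}),
            names[3]: frozenset({10, 11}),
            names[4]: frozenset({11, 12}),
        }
        cmap = _map_for(
            d,
            {
                "ctg1": [(addrs[0], 0, 10), (addrs[1], 5, 15), (addrs[2], 12, 22)],
                "ctg2": [(addrs[3], 0, 10), (addrs[4], 5, 15)],
            },
            fps,
        )
        res = deconvolute_marker(mh, d, cmap)
        assert res.status == "unique"
        assert res.solutions[0].mc == 3
        pair = next(s for s in res.solutions if s.nc == 2)
        assert pair.score == pytest.approx(0.8 * 2 / 3 + 0.2)
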