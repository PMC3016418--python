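"""Clone deconvolution: from positive pool hits to true-positive clone calls.

For each marker the algorithm

1. intersects positive row/column super-pools on the plate matrix to get
   candidate plates, then intersects those with positive clone row/column
   pools per sub-pool to get the candidate clone set ``C``;
2. restricts ``C`` to each contig of the map (subset ``C1``);
3. inside each contig groups ``C1`` into sets ``C2`` of clones chained by
   containment / spanning / overlap of their fingerprints;
4. counts false-negative clones ``FN`` lying between the extremes of ``C2``
   but absent from ``C``;
5. scores every ``C2`` as ``0.8*NC/MC + 0.2*(1 - FN/NC)`` where ``NC`` is the
   size of ``C2`` and ``MC`` the largest ``NC`` over all sets of the marker;
6. ranks the sets: the top score wins, a tie is reported as non-unique, and a
   best score <= 0 (or no set at all) means no solution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import networkx as nx

from .design import (
    CloneAddress,
    PlateRef,
    PoolingDesign,
    SuperPoolMatrix,
    format_clone_name,
)
from .fpc_io import SINGLETON_CTG, ContigClone, ContigMap, MarkerHits

__all__ = [
    "CandidateSet",
    "ScoredSolution",
    "DeconvolutionResult",
    "plate_intersections",
    "candidate_clones",
    "contains",
    "spans",
    "overlaps",
    "find_C2",
    "count_FN",
    "score",
    "deconvolute_marker",
    "deconvolute_all",
]

SCORE_DECIMALS = 6  # ties decided on score rounded to this many decimals


@dataclass
class CandidateSet:
    """The candidate clone set C for one marker, with per-sub-pool counts."""

    marker: str
    clones: set[CloneAddress]
    per_sub_pool: dict[str, int]

    def names(self) -> set[str]:
        return {format_clone_name(c) for c in self.clones}


@dataclass
class ScoredSolution:
    """One scored clone set C2 inside one contig."""

    contig_id: str
    clones: frozenset[str]
    nc: int
    mc: int
    fn: int
    score: float


@dataclass
class DeconvolutionResult:
    marker: str
    status: str  # unique | non_unique | no_solution
    solutions: list[ScoredSolution] = field(default_factory=list)
    diagnostics: dict = field(default_factory=dict)

    def returned_clones(self) -> set[str]:
        """The clone set the caller would act on: the unique winner, or the
        union of tied top sets for a non-unique call; empty for no solution."""
        if self.status == "no_solution" or not self.solutions:
            return set()
        top = round(self.solutions[0].score, SCORE_DECIMALS)
        out: set[str] = set()
        for sol in self.solutions:
            if round(sol.score, SCORE_DECIMALS) != top:
                break
            out |= sol.clones
        return out


# ---------------------------------------------------------------------------
# steps (1): pool intersections
# ---------------------------------------------------------------------------


def plate_intersections(
    rsp_hits: Iterable[int], csp_hits: Iterable[int], matrix: SuperPoolMatrix
) -> set[PlateRef]:
    """Occupied matrix cells at the cross of positive RSP rows and CSP columns."""
    out: set[PlateRef] = set()
    for r in rsp_hits:
        for c in csp_hits:
            plate = matrix.cells.get((r, c))
            if plate is not None:
                out.add(plate)
    return out


def candidate_clones(
    plates: Iterable[PlateRef],
    rp_hits: Iterable[tuple[str, str]],
    cp_hits: Iterable[tuple[str, int]],
    design: PoolingDesign,
    marker: str = "",
    library_filter: bool = True,
) -> CandidateSet:
    """Candidate clones at intersections of candidate plates with positive
    RP/CP pools, taken per sub-pool.

    With *library_filter* on (default), a sub-pool's RP/CP hits combine only
    with candidate plates that actually belong to that sub-pool.  Switched
    off, every candidate plate combines with every sub-pool's hits, which
    reproduces the idealized ``(plates x rows x cols) x sub-pools``
    intersection arithmetic.
    """
    plates = set(plates)
    rows_by_sub: dict[str, set[str]] = {}
    for sub, row in rp_hits:
        rows_by_sub.setdefault(sub, set()).add(row)
    cols_by_sub: dict[str, set[int]] = {}
    for sub, col in cp_hits:
        cols_by_sub.setdefault(sub, set()).add(col)

    clones: set[CloneAddress] = set()
    per_sub_pool: dict[str, int] = {}
    for sub in design.sub_pools:
        rows = rows_by_sub.get(sub, set())
        cols = cols_by_sub.get(sub, set())
        if not rows or not cols:
            continue
        if library_filter:
            sub_plates = plates & set(design.sub_pools[sub])
        else:
            sub_plates = plates
        found = {
            CloneAddress(lib, plate, row, col)
            for (lib, plate) in sub_plates
            for row in rows
            for col in cols
        }
        per_sub_pool[sub] = len(found)
        clones |= found
    return CandidateSet(marker=marker, clones=clones, per_sub_pool=per_sub_pool)


# ---------------------------------------------------------------------------
# fingerprint relations
# ---------------------------------------------------------------------------


def _match_count(a: frozenset[int], b: frozenset[int], tolerance: int) -> int:
    """Number of bands of *a* matched one-to-one into *b* within *tolerance*.

    Greedy two-pointer matching over sorted band values; with tolerance 0
    this is exactly the intersection size.
    """
    if tolerance == 0:
        return len(a & b)
    sa, sb = sorted(a), sorted(b)
    i = j = matched = 0
    while i < len(sa) and j < len(sb):
        d = sa[i] - sb[j]
        if abs(d) <= tolerance:
            matched += 1
            i += 1
            j += 1
        elif d > 0:
            j += 1
        else:
            i += 1
    return matched


def contains(a: frozenset[int], b: frozenset[int], tolerance: int = 0) -> bool:
    """True if fingerprint *a* is contained in fingerprint *b*."""
    if not a or not b:
        return False
    return _match_count(a, b, tolerance) == len(a)


def spans(
    a: frozenset[int], b: frozenset[int], c: frozenset[int], tolerance: int = 0
) -> bool:
    """True if clones *a* and *b* span clone *c*: f(c) lies in f(a) u f(b)."""
    if not c:
        return False
    return contains(c, a | b, tolerance)


def overlaps(
    a: frozenset[int], b: frozenset[int], min_shared: int = 1, tolerance: int = 0
) -> bool:
    """True if the fingerprints share at least *min_shared* matched bands."""
    if not a or not b:
        return False
    return _match_count(a, b, tolerance) >= min_shared


# ---------------------------------------------------------------------------
# steps (3)-(5): C2 construction, FN counting, scoring
# ---------------------------------------------------------------------------


def find_C2(
    contig_members: Sequence[ContigClone],
    c1_names: set[str],
    fingerprints: dict[str, frozenset[int]],
    min_shared: int = 1,
    tolerance: int = 0,
) -> list[frozenset[str]]:
    """Group C1 into candidate solution sets C2.

    A C2 set is a connected component (size >= 2) of the relation graph on C1
    whose edges are fingerprint containment, pairwise overlap, or a spanning
    triple; clones need not be pairwise related, chains suffice.
    """
    nodes = sorted(n for n in c1_names if fingerprints.get(n))
    if len(nodes) < 2:
        return []
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for i, u in enumerate(nodes):
        fu = fingerprints[u]
        for v in nodes[i + 1 :]:
            fv = fingerprints[v]
            if (
                overlaps(fu, fv, min_shared, tolerance)
                or contains(fu, fv, tolerance)
                or contains(fv, fu, tolerance)
            ):
                g.add_edge(u, v)
    # spanning triples: c bridged to a pair (a, b) whose union covers it
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            if g.has_edge(u, v):
                continue
            fu, fv = fingerprints[u], fingerprints[v]
            for w in nodes:
                if w in (u, v):
                    continue
                if spans(fu, fingerprints[w], fv, tolerance) or spans(
                    fv, fingerprints[w], fu, tolerance
                ):
                    g.add_edge(u, w)
                    g.add_edge(v, w)
                    break
    comps = [frozenset(comp) for comp in nx.connected_components(g) if len(comp) >= 2]
    comps.sort(key=lambda s: (-len(s), min(s)))
    return comps


def count_FN(
    c2: Iterable[str], contig_members: Sequence[ContigClone], candidate_names: set[str]
) -> int:
    """Contig members whose midpoint falls inside the closed span of C2 but
    that are not candidate clones."""
    c2 = set(c2)
    spanned = [m for m in contig_members if m.name in c2]
    if not spanned:
        return 0
    left = min(m.left for m in spanned)
    right = max(m.right for m in spanned)
    fn = 0
    for m in contig_members:
        if m.name in candidate_names:
            continue
        if left <= m.midpoint <= right:
            fn += 1
    return fn


def score(nc: int, mc: int, fn: int) -> float:
    """Discrimination score ``0.8*NC/MC + 0.2*(1 - FN/NC)``."""
    if mc <= 0:
        raise ValueError("MC must be positive")
    if nc < 1:
        raise ValueError("NC must be >= 1")
    if fn < 0:
        raise ValueError("FN must be >= 0")
    return 0.8 * nc / mc + 0.2 * (1.0 - fn / nc)


# ---------------------------------------------------------------------------
# step (6): full per-marker deconvolution
# ---------------------------------------------------------------------------


def deconvolute_marker(
    hits: MarkerHits,
    design: PoolingDesign,
    contig_map: ContigMap,
    min_shared: int = 1,
    tolerance: int = 0,
    library_filter: bool = True,
) -> DeconvolutionResult:
    """Run the full deconvolution for one marker."""
    if hits.is_empty:
        return DeconvolutionResult(
            marker=hits.marker,
            status="no_solution",
            diagnostics={"screening_failure": True, "n_candidates": 0},
        )

    plates = plate_intersections(hits.rsp_hits, hits.csp_hits, design.matrix)
    cand = candidate_clones(
        plates, hits.rp_hits, hits.cp_hits, design, marker=hits.marker, library_filter=library_filter
    )
    cand_names = cand.names()

    n_in_contigs = n_singletons = n_unplaced = 0
    c1_by_contig: dict[str, set[str]] = {}
    for name in cand_names:
        loc = contig_map.location(name)
        if loc is None:
            n_unplaced += 1
        elif loc == SINGLETON_CTG:
            n_singletons += 1
        else:
            n_in_contigs += 1
            c1_by_contig.setdefault(loc, set()).add(name)

    diagnostics = {
        "n_candidate_plates": len(plates),
        "n_candidates": len(cand_names),
        "per_sub_pool": cand.per_sub_pool,
        "candidates_in_contigs": n_in_contigs,
        "candidates_singletons": n_singletons,
        "candidates_unplaced": n_unplaced,
    }

    raw: list[tuple[str, frozenset[str]]] = []
    for cid in sorted(c1_by_contig):
        c1 = c1_by_contig[cid]
        if len(c1) < 2:
            continue
        for c2 in find_C2(contig_map.contigs[cid], c1, contig_map.fingerprints, min_shared, tolerance):
            raw.append((cid, c2))

    if not raw:
        return DeconvolutionResult(hits.marker, "no_solution", [], diagnostics)

    mc = max(len(c2) for _, c2 in raw)
    solutions = []
    for cid, c2 in raw:
        nc = len(c2)
        fn = count_FN(c2, contig_map.contigs[cid], cand_names)
        solutions.append(
            ScoredSolution(contig_id=cid, clones=c2, nc=nc, mc=mc, fn=fn, score=score(nc, mc, fn))
        )
    solutions.sort(key=lambda s: (-round(s.score, SCORE_DECIMALS), -s.nc, s.contig_id, min(s.clones)))

    best = round(solutions[0].score, SCORE_DECIMALS)
    if best <= 0:
        return DeconvolutionResult(hits.marker, "no_solution", solutions, diagnostics)
    n_tied = sum(1 for s in solutions if round(s.score, SCORE_DECIMALS) == best)
    status = "unique" if n_tied == 1 else "non_unique"
    return DeconvolutionResult(hits.marker, status, solutions, diagnostics)


def deconvolute_all(
    hits_list: Iterable[MarkerHits],
    design: PoolingDesign,
    contig_map: ContigMap,
    **kwargs,
) -> list[DeconvolutionResult]:
    return [deconvolute_marker(h, design, contig_map, **kwargs) for h in hits_list]
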