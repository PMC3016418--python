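"""Seeded synthetic data: an abstract genome tiled by interval clones in
multi-library plate collections, band-site fingerprints, perfect contigs,
point markers, and pool hits with injectable per-pool-kind error rates.

Everything is driven by one integer seed; identical configs give identical
outputs.  Error injection draws one uniform per (marker, pool) from a
dedicated stream, so runs that differ only in the error rates share the same
underlying draws (dropped/spurious hit sets are nested across rates).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Union

import numpy as np

from .design import (
    CloneAddress,
    LibrarySpec,
    PlateLayout,
    PoolingDesign,
    build_design,
    format_clone_name,
    parse_clone_name,
)
from .fpc_io import SINGLETON_CTG, ContigClone, ContigMap, MarkerHits

__all__ = ["SimLibrary", "SimConfig", "SimTruth", "simulate", "degrade_contigs"]

SCREENED = ("RSP", "CSP", "RP", "CP")


@dataclass(frozen=True)
class SimLibrary:
    """One simulated library: full plates of clones with a given insert size."""

    code: str
    n_plates: int
    insert_mean: float = 100.0
    insert_sd: float = 10.0


def _as_rate_map(value: Union[float, dict]) -> dict[str, float]:
    if isinstance(value, dict):
        rates = {k: float(value.get(k, 0.0)) for k in SCREENED}
    else:
        rates = {k: float(value) for k in SCREENED}
    for k, p in rates.items():
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"error rate for {k} must be in [0, 1], got {p}")
    return rates


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulation run; ``seed`` is mandatory."""

    genome_length: float
    libraries: tuple[SimLibrary, ...]
    n_markers: int
    seed: int
    band_site_density: float = 1.0  # band sites per genome unit
    p_fp: Union[float, dict] = 0.0  # per-pool-kind false-positive rate
    p_fn: Union[float, dict] = 0.0  # per-pool-kind false-negative rate
    matrix_shape: Optional[tuple[int, int]] = None
    sub_pool_plan: Optional[dict[str, int]] = None
    min_tp_per_marker: int = 0  # resample markers until this many planted clones

    def __post_init__(self) -> None:
        if self.genome_length <= 0:
            raise ValueError("genome_length must be positive")
        if self.n_markers <= 0:
            raise ValueError("n_markers must be positive")
        if self.band_site_density <= 0:
            raise ValueError("band_site_density must be positive")
        if not self.libraries:
            raise ValueError("at least one library required")
        for lib in self.libraries:
            if lib.insert_mean <= 0:
                raise ValueError(f"library {lib.code!r}: zero-coverage library (insert_mean <= 0)")
        _as_rate_map(self.p_fp)
        _as_rate_map(self.p_fn)

    @property
    def total_clones(self) -> int:
        return sum(lib.n_plates for lib in self.libraries) * PlateLayout().wells_per_plate

    def coverage(self, lib: SimLibrary) -> float:
        n = lib.n_plates * PlateLayout().wells_per_plate
        return n * lib.insert_mean / self.genome_length


@dataclass
class SimTruth:
    """Ground truth of one simulation run."""

    clone_intervals: dict[str, tuple[float, float]]
    marker_positions: dict[str, float]
    tp_clones: dict[str, set[str]]
    true_hits: dict[str, MarkerHits]


def _default_matrix_shape(n_plates: int) -> tuple[int, int]:
    rows = max(1, int(math.isqrt(n_plates)))
    cols = math.ceil(n_plates / rows)
    return rows, cols


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    lo = max(1.0, mean - 3.0 * sd)
    hi = mean + 3.0 * sd
    return np.clip(rng.normal(mean, sd, size=n), lo, hi)


def _fingerprint(start: float, end: float, offset: float, spacing: float) -> frozenset[int]:
    """Band-site ids (1-based lattice indices) inside [start, end]."""
    first = math.ceil((start - offset) / spacing)
    last = math.floor((end - offset) / spacing)
    if last < first:
        return frozenset()
    return frozenset(range(first + 1, last + 2))


def _build_contigs(
    names: list[str],
    starts: np.ndarray,
    ends: np.ndarray,
    fingerprints: dict[str, frozenset[int]],
) -> ContigMap:
    """Perfect contigs: connected components of the interval-overlap graph.

    Clones with empty fingerprints are unassembled; size-1 components are
    singletons.  Sweep over intervals sorted by start; map coordinates are
    integerized interval endpoints.
    """
    assembled = [i for i, n in enumerate(names) if fingerprints.get(n)]
    order = sorted(assembled, key=lambda i: (starts[i], ends[i]))
    components: list[list[int]] = []
    cur: list[int] = []
    cur_max_end = -math.inf
    for i in order:
        if cur and starts[i] > cur_max_end:
            components.append(cur)
            cur = []
            cur_max_end = -math.inf
        cur.append(i)
        cur_max_end = max(cur_max_end, ends[i])
    if cur:
        components.append(cur)

    contigs: dict[str, list[ContigClone]] = {}
    singletons: list[ContigClone] = []
    k = 0
    for comp in components:
        if len(comp) == 1:
            i = comp[0]
            singletons.append(
                ContigClone(names[i], SINGLETON_CTG, int(math.floor(starts[i])), int(math.ceil(ends[i])))
            )
            continue
        k += 1
        cid = f"ctg{k}"
        contigs[cid] = [
            ContigClone(names[i], cid, int(math.floor(starts[i])), int(math.ceil(ends[i])))
            for i in comp
        ]
    unassembled = [n for n in names if not fingerprints.get(n)]
    return ContigMap(
        contigs=contigs,
        fingerprints={n: f for n, f in fingerprints.items() if f},
        singletons=singletons,
        unassembled=unassembled,
    )


def simulate(config: SimConfig) -> tuple[PoolingDesign, ContigMap, list[MarkerHits], SimTruth]:
    """Generate a full fixture bundle: design, contig map, observed hits, truth."""
    layout = PlateLayout()
    genome_rng = np.random.default_rng([config.seed, 0])
    error_rng = np.random.default_rng([config.seed, 1])
    L = float(config.genome_length)

    lib_specs = [
        LibrarySpec(lib.code, lib.n_plates, genome_coverage=config.coverage(lib))
        for lib in config.libraries
    ]
    shape = config.matrix_shape or _default_matrix_shape(sum(l.n_plates for l in lib_specs))
    design = build_design(lib_specs, shape, sub_pool_plan=config.sub_pool_plan, layout=layout)

    # interval clones: uniform starts, truncated-normal insert lengths
    names: list[str] = []
    starts_parts: list[np.ndarray] = []
    lens_parts: list[np.ndarray] = []
    spacing = 1.0 / config.band_site_density
    site_offset = genome_rng.uniform(0.0, spacing)
    for lib in config.libraries:
        slots = [
            CloneAddress(lib.code, p, row, col)
            for p in range(1, lib.n_plates + 1)
            for row in layout.row_labels
            for col in range(1, layout.n_well_cols + 1)
        ]
        genome_rng.shuffle(slots)  # random plate/well placement
        n = len(slots)
        names.extend(format_clone_name(a) for a in slots)
        starts_parts.append(genome_rng.uniform(0.0, L, size=n))
        lens_parts.append(_truncated_normal(genome_rng, lib.insert_mean, lib.insert_sd, n))
    starts = np.concatenate(starts_parts)
    ends = starts + np.concatenate(lens_parts)

    fingerprints = {
        name: _fingerprint(starts[i], ends[i], site_offset, spacing) for i, name in enumerate(names)
    }
    contig_map = _build_contigs(names, starts, ends, fingerprints)

    # markers: uniform positions, optionally resampled until enough planted clones
    marker_positions: dict[str, float] = {}
    tp_clones: dict[str, set[str]] = {}
    attempts = 0
    max_attempts = 1000 * config.n_markers
    while len(marker_positions) < config.n_markers:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"could not place {config.n_markers} markers with >= "
                f"{config.min_tp_per_marker} planted clones each; raise coverage"
            )
        pos = float(genome_rng.uniform(0.0, L))
        mask = (starts <= pos) & (ends >= pos)
        if int(mask.sum()) < config.min_tp_per_marker:
            continue
        marker = f"M{len(marker_positions) + 1:04d}"
        marker_positions[marker] = pos
        tp_clones[marker] = {names[i] for i in np.flatnonzero(mask)}

    # true pool hits, reverse-read from planted clone addresses
    true_hits: dict[str, MarkerHits] = {}
    for marker, clones in tp_clones.items():
        mh = MarkerHits(marker=marker)
        for name in clones:
            for pool in design.true_pool_hits(parse_clone_name(name)):
                if pool.kind == "RSP":
                    mh.rsp_hits.add(pool.index)
                elif pool.kind == "CSP":
                    mh.csp_hits.add(pool.index)
                elif pool.kind == "RP":
                    mh.rp_hits.add(pool.index)
                elif pool.kind == "CP":
                    mh.cp_hits.add(pool.index)
        true_hits[marker] = mh

    # error injection: one uniform per (marker, pool), fixed enumeration order
    p_fp = _as_rate_map(config.p_fp)
    p_fn = _as_rate_map(config.p_fn)
    pools_by_kind = {kind: [p.index for p in design.pools(kind)] for kind in SCREENED}
    observed: list[MarkerHits] = []
    for marker in sorted(marker_positions):
        th = true_hits[marker]
        true_sets = {"RSP": th.rsp_hits, "CSP": th.csp_hits, "RP": th.rp_hits, "CP": th.cp_hits}
        obs = MarkerHits(marker=marker)
        obs_sets = {"RSP": obs.rsp_hits, "CSP": obs.csp_hits, "RP": obs.rp_hits, "CP": obs.cp_hits}
        for kind in SCREENED:
            u = error_rng.random(len(pools_by_kind[kind]))
            for idx, ui in zip(pools_by_kind[kind], u):
                if idx in true_sets[kind]:
                    if ui >= p_fn[kind]:
                        obs_sets[kind].add(idx)
                else:
                    if ui < p_fp[kind]:
                        obs_sets[kind].add(idx)
        observed.append(obs)

    truth = SimTruth(
        clone_intervals={name: (float(starts[i]), float(ends[i])) for i, name in enumerate(names)},
        marker_positions=marker_positions,
        tp_clones=tp_clones,
        true_hits=true_hits,
    )
    return design, contig_map, observed, truth


def degrade_contigs(contig_map: ContigMap, split_rate: float, seed: int) -> ContigMap:
    """Randomly split contigs at internal joins, mimicking over-stringent
    assembly.  ``split_rate=0`` is the identity; ``split_rate=1`` shatters
    every contig into size-1 contigs.  Clone coordinates are preserved."""
    if not 0.0 <= split_rate <= 1.0:
        raise ValueError(f"split_rate must be in [0, 1], got {split_rate}")
    if split_rate == 0.0:
        return contig_map
    rng = np.random.default_rng([seed, 2])
    new_contigs: dict[str, list[ContigClone]] = {}
    for cid in sorted(contig_map.contigs):
        members = contig_map.contigs[cid]
        pieces: list[list[ContigClone]] = [[members[0]]]
        for m in members[1:]:
            if rng.random() < split_rate:
                pieces.append([m])
            else:
                pieces[-1].append(m)
        if len(pieces) == 1:
            new_contigs[cid] = list(members)
        else:
            for j, piece in enumerate(pieces, start=1):
                new_contigs[f"{cid}.{j}"] = [replace(c, contig_id=f"{cid}.{j}") for c in piece]
    return ContigMap(
        contigs=new_contigs,
        fingerprints=dict(contig_map.fingerprints),
        singletons=list(contig_map.singletons),
        unassembled=list(contig_map.unassembled),
    )
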