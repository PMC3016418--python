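"""File formats: a minimal textual FPC dialect, sidecar band files, pool-hit
tables, matrix design tables, and the three result writers.

All tabular formats are UTF-8 TSV with one header line; lines starting with
``#`` are comments.  The FPC dialect supports clone stanzas of the form::

    BAC : "BB092N18"
    Map "ctg4985" Ends Left 12 Right 34
    Bands: 101 102 107

``Bands:`` is an inline extension; band sets may instead come from a sidecar
``.bands`` TSV (clone <TAB> space-separated integers).  A clone stanza without
a ``Map`` record is recorded as unassembled; the contig id ``ctg0`` holds
singletons (FPC convention).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, TextIO, Union

import yaml

from .design import LibrarySpec, PlateRef, PoolingDesign, build_design

__all__ = [
    "FileFormatError",
    "ContigClone",
    "ContigMap",
    "MarkerHits",
    "read_fpc",
    "write_fpc",
    "read_bands",
    "write_bands",
    "read_pool_hits",
    "write_pool_hits",
    "read_matrix_design",
    "write_matrix_design",
    "write_outputs",
    "read_summary",
    "write_truth",
    "read_truth",
    "write_design_config",
    "read_design_config",
]

SINGLETON_CTG = "ctg0"


class FileFormatError(ValueError):
    """An input file violates the expected format."""


@dataclass(frozen=True)
class ContigClone:
    """One clone placed (or not) on the contig map."""

    name: str
    contig_id: Optional[str]  # None = unassembled; SINGLETON_CTG = singleton
    left: Optional[int] = None
    right: Optional[int] = None

    def __post_init__(self) -> None:
        if self.contig_id is not None:
            if self.left is None or self.right is None:
                raise FileFormatError(f"clone {self.name!r}: placed clone needs coordinates")
            if self.left > self.right:
                raise FileFormatError(f"clone {self.name!r}: left > right")

    @property
    def midpoint(self) -> float:
        return (self.left + self.right) / 2.0


@dataclass
class ContigMap:
    """Contigs with ordered member clones plus fingerprint band sets."""

    contigs: dict[str, list[ContigClone]] = field(default_factory=dict)
    fingerprints: dict[str, frozenset[int]] = field(default_factory=dict)
    singletons: list[ContigClone] = field(default_factory=list)
    unassembled: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        for cid, members in self.contigs.items():
            members.sort(key=lambda c: (c.left, c.right, c.name))
        self._index: dict[str, ContigClone] = {}
        for members in self.contigs.values():
            for c in members:
                if c.name in self._index:
                    raise FileFormatError(f"clone {c.name!r} appears in more than one contig")
                self._index[c.name] = c
        for c in self.singletons:
            if c.name in self._index:
                raise FileFormatError(f"clone {c.name!r} both singleton and contig member")
            self._index[c.name] = c

    @property
    def n_clones(self) -> int:
        return len(self._index) + len(self.unassembled)

    def location(self, clone_name: str) -> Optional[str]:
        """Contig id, ``ctg0`` for singletons, ``None`` if unassembled/unknown."""
        c = self._index.get(clone_name)
        return c.contig_id if c is not None else None

    def clone(self, clone_name: str) -> Optional[ContigClone]:
        return self._index.get(clone_name)


@dataclass
class MarkerHits:
    """Positive pool identifiers observed for one marker.

    RSP/CSP hits are matrix indices; RP hits are ``(sub_pool, well_row)``
    pairs and CP hits are ``(sub_pool, well_col)`` pairs.
    """

    marker: str
    rsp_hits: set[int] = field(default_factory=set)
    csp_hits: set[int] = field(default_factory=set)
    rp_hits: set[tuple[str, str]] = field(default_factory=set)
    cp_hits: set[tuple[str, int]] = field(default_factory=set)

    @property
    def is_empty(self) -> bool:
        return not (self.rsp_hits or self.csp_hits or self.rp_hits or self.cp_hits)


# ---------------------------------------------------------------------------
# FPC dialect
# ---------------------------------------------------------------------------

_BAC_RE = re.compile(r'^BAC\s*:\s*"([^"]+)"\s*$')
_MAP_RE = re.compile(r'^Map\s+"([^"]+)"\s+Ends\s+Left\s+(-?\d+)\s+Right\s+(-?\d+)\s*$')
_BANDS_RE = re.compile(r"^Bands:\s*(.*)$")


def read_fpc(path: Union[str, Path]) -> ContigMap:
    """Parse the minimal FPC dialect into a :class:`ContigMap`."""
    contigs: dict[str, list[ContigClone]] = {}
    fingerprints: dict[str, frozenset[int]] = {}
    singletons: list[ContigClone] = []
    unassembled: list[str] = []
    seen: set[str] = set()

    cur_name: Optional[str] = None
    cur_map: Optional[tuple[str, int, int]] = None

    def flush(lineno: int) -> None:
        nonlocal cur_name, cur_map
        if cur_name is None:
            return
        if cur_map is None:
            unassembled.append(cur_name)
        else:
            cid, left, right = cur_map
            clone = ContigClone(cur_name, cid, left, right)
            if cid == SINGLETON_CTG:
                singletons.append(clone)
            else:
                contigs.setdefault(cid, []).append(clone)
        cur_name, cur_map = None, None

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith(("#", "//")):
                continue
            m = _BAC_RE.match(line)
            if m:
                flush(lineno)
                name = m.group(1)
                if name in seen:
                    raise FileFormatError(f"{path}:{lineno}: duplicate clone {name!r}")
                seen.add(name)
                cur_name = name
                continue
            m = _MAP_RE.match(line)
            if m:
                if cur_name is None:
                    raise FileFormatError(f"{path}:{lineno}: Map record outside a clone stanza")
                cur_map = (m.group(1), int(m.group(2)), int(m.group(3)))
                continue
            m = _BANDS_RE.match(line)
            if m:
                if cur_name is None:
                    raise FileFormatError(f"{path}:{lineno}: Bands record outside a clone stanza")
                try:
                    bands = frozenset(int(tok) for tok in m.group(1).split())
                except ValueError as exc:
                    raise FileFormatError(f"{path}:{lineno}: bad band value ({exc})") from exc
                fingerprints[cur_name] = bands
                continue
            raise FileFormatError(f"{path}:{lineno}: unknown record {line!r}")
    flush(-1)
    return ContigMap(
        contigs=contigs, fingerprints=fingerprints, singletons=singletons, unassembled=unassembled
    )


def write_fpc(contig_map: ContigMap, path: Union[str, Path], inline_bands: bool = True) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("// pooldeconv fpc dialect v1\n")

        def stanza(clone: ContigClone) -> None:
            fh.write(f'BAC : "{clone.name}"\n')
            fh.write(f'Map "{clone.contig_id}" Ends Left {clone.left} Right {clone.right}\n')
            if inline_bands and clone.name in contig_map.fingerprints:
                bands = " ".join(str(b) for b in sorted(contig_map.fingerprints[clone.name]))
                fh.write(f"Bands: {bands}\n")
            fh.write("\n")

        for cid in sorted(contig_map.contigs):
            for clone in contig_map.contigs[cid]:
                stanza(clone)
        for clone in sorted(contig_map.singletons, key=lambda c: c.name):
            stanza(clone)
        for name in sorted(contig_map.unassembled):
            fh.write(f'BAC : "{name}"\n')
            if inline_bands and name in contig_map.fingerprints:
                bands = " ".join(str(b) for b in sorted(contig_map.fingerprints[name]))
                fh.write(f"Bands: {bands}\n")
            fh.write("\n")


def read_bands(path: Union[str, Path]) -> dict[str, frozenset[int]]:
    """Sidecar band file: clone <TAB> space-separated integer band values."""
    out: dict[str, frozenset[int]] = {}
    with open(path, encoding="utf-8") as fh:
        header = _read_header(fh, path)
        if header[:1] != ["clone"]:
            raise FileFormatError(f"{path}: expected 'clone' header, got {header!r}")
        for lineno, row in _iter_rows(fh):
            if len(row) != 2:
                raise FileFormatError(f"{path}:{lineno}: expected 2 columns")
            name, bands_s = row
            if name in out:
                raise FileFormatError(f"{path}:{lineno}: duplicate clone {name!r}")
            try:
                out[name] = frozenset(int(tok) for tok in bands_s.split())
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: bad band value ({exc})") from exc
    return out


def write_bands(fingerprints: dict[str, frozenset[int]], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("clone\tbands\n")
        for name in sorted(fingerprints):
            fh.write(f"{name}\t{' '.join(str(b) for b in sorted(fingerprints[name]))}\n")


# ---------------------------------------------------------------------------
# pool hit file
# ---------------------------------------------------------------------------


def _read_header(fh: TextIO, path: object) -> list[str]:
    for raw in fh:
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        return line.split("\t")
    raise FileFormatError(f"{path}: empty file (no header)")


def _iter_rows(fh: TextIO) -> Iterable[tuple[int, list[str]]]:
    for lineno, raw in enumerate(fh, start=2):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        yield lineno, line.split("\t")


def _split_list(cell: str) -> list[str]:
    cell = cell.strip()
    if not cell or cell == "-":
        return []
    return [tok.strip() for tok in cell.split(",") if tok.strip()]


POOL_HIT_COLUMNS = ["marker", "rsp", "csp", "rp", "cp"]


def read_pool_hits(
    path: Union[str, Path], design: Optional[PoolingDesign] = None
) -> list[MarkerHits]:
    """Read a pool-hit TSV (marker, rsp, csp, rp, cp; comma-separated ids)."""
    hits: list[MarkerHits] = []
    seen: set[str] = set()
    with open(path, encoding="utf-8") as fh:
        header = _read_header(fh, path)
        if header != POOL_HIT_COLUMNS:
            raise FileFormatError(f"{path}: expected header {POOL_HIT_COLUMNS}, got {header}")
        for lineno, row in _iter_rows(fh):
            if len(row) != 5:
                raise FileFormatError(f"{path}:{lineno}: expected 5 columns, got {len(row)}")
            marker = row[0]
            if not marker:
                raise FileFormatError(f"{path}:{lineno}: empty marker name")
            if marker in seen:
                raise FileFormatError(f"{path}:{lineno}: duplicate marker {marker!r}")
            seen.add(marker)
            try:
                rsp = {int(t) for t in _split_list(row[1])}
                csp = {int(t) for t in _split_list(row[2])}
                rp = {_parse_rp(t) for t in _split_list(row[3])}
                cp = {_parse_cp(t) for t in _split_list(row[4])}
            except (ValueError, FileFormatError) as exc:
                raise FileFormatError(f"{path}:{lineno}: marker {marker!r}: {exc}") from exc
            mh = MarkerHits(marker=marker, rsp_hits=rsp, csp_hits=csp, rp_hits=rp, cp_hits=cp)
            if design is not None:
                _validate_hits(mh, design, path, lineno)
            hits.append(mh)
    return hits


def _parse_rp(token: str) -> tuple[str, str]:
    sub, sep, row = token.rpartition(":")
    if not sep or not sub or len(row) != 1 or not row.isalpha():
        raise FileFormatError(f"bad RP id {token!r} (expected SUB:ROWLETTER)")
    return (sub, row.upper())


def _parse_cp(token: str) -> tuple[str, int]:
    sub, sep, col = token.rpartition(":")
    if not sep or not sub or not col.isdigit():
        raise FileFormatError(f"bad CP id {token!r} (expected SUB:COLNUMBER)")
    return (sub, int(col))


def _validate_hits(mh: MarkerHits, design: PoolingDesign, path: object, lineno: int) -> None:
    for r in mh.rsp_hits:
        if not (1 <= r <= design.matrix.n_rows):
            raise FileFormatError(f"{path}:{lineno}: marker {mh.marker!r}: RSP {r} outside matrix")
    for c in mh.csp_hits:
        if not (1 <= c <= design.matrix.n_cols):
            raise FileFormatError(f"{path}:{lineno}: marker {mh.marker!r}: CSP {c} outside matrix")
    for sub, row in mh.rp_hits:
        if sub not in design.sub_pools or not design.layout.valid_row(row):
            raise FileFormatError(f"{path}:{lineno}: marker {mh.marker!r}: unknown RP {sub}:{row}")
    for sub, col in mh.cp_hits:
        if sub not in design.sub_pools or not design.layout.valid_col(col):
            raise FileFormatError(f"{path}:{lineno}: marker {mh.marker!r}: unknown CP {sub}:{col}")


def write_pool_hits(hits: Iterable[MarkerHits], path: Union[str, Path]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(POOL_HIT_COLUMNS) + "\n")
        for mh in hits:
            fh.write(
                "\t".join(
                    [
                        mh.marker,
                        ",".join(str(r) for r in sorted(mh.rsp_hits)),
                        ",".join(str(c) for c in sorted(mh.csp_hits)),
                        ",".join(f"{s}:{r}" for s, r in sorted(mh.rp_hits)),
                        ",".join(f"{s}:{c}" for s, c in sorted(mh.cp_hits)),
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# matrix design file
# ---------------------------------------------------------------------------

_PLATE_RE = re.compile(r"^([A-Za-z]+?)(\d+)$")


def _parse_plate_id(token: str) -> PlateRef:
    m = _PLATE_RE.match(token)
    if m is None:
        raise FileFormatError(f"bad plate identifier {token!r}")
    return (m.group(1), int(m.group(2)))


def format_plate_id(plate: PlateRef, plate_digits: int = 3) -> str:
    return f"{plate[0]}{plate[1]:0{plate_digits}d}"


def read_matrix_design(path: Union[str, Path]) -> tuple[int, int, dict[tuple[int, int], PlateRef]]:
    """Read a matrix design TSV: header = CSP indices, first column = RSP index,
    cells = plate identifiers (e.g. ``HB086``) or empty."""
    with open(path, encoding="utf-8") as fh:
        header = _read_header(fh, path)
        if header[:1] != ["rsp"]:
            raise FileFormatError(f"{path}: first header column must be 'rsp'")
        try:
            cols = [int(c) for c in header[1:]]
        except ValueError as exc:
            raise FileFormatError(f"{path}: non-integer CSP index in header ({exc})") from exc
        if cols != list(range(1, len(cols) + 1)):
            raise FileFormatError(f"{path}: CSP indices must be 1..{len(cols)}")
        cells: dict[tuple[int, int], PlateRef] = {}
        n_rows = 0
        for lineno, row in _iter_rows(fh):
            try:
                r = int(row[0])
            except ValueError as exc:
                raise FileFormatError(f"{path}:{lineno}: bad RSP index {row[0]!r}") from exc
            n_rows = max(n_rows, r)
            for c, cell in enumerate(row[1:], start=1):
                cell = cell.strip()
                if not cell:
                    continue
                try:
                    cells[(r, c)] = _parse_plate_id(cell)
                except FileFormatError as exc:
                    raise FileFormatError(f"{path}:{lineno}: {exc}") from exc
    return n_rows, len(cols), cells


def write_matrix_design(
    matrix_rows: int,
    matrix_cols: int,
    cells: dict[tuple[int, int], PlateRef],
    path: Union[str, Path],
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("rsp\t" + "\t".join(str(c) for c in range(1, matrix_cols + 1)) + "\n")
        for r in range(1, matrix_rows + 1):
            row = [str(r)]
            for c in range(1, matrix_cols + 1):
                plate = cells.get((r, c))
                row.append(format_plate_id(plate) if plate is not None else "")
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

ACE_HEADER = "# pooldeconv ACE-style marker merge v1 (marker<TAB>clone<TAB>contig)"


def write_outputs(
    results: Iterable,
    summary_path: Union[str, Path],
    anchored_path: Union[str, Path],
    ace_path: Union[str, Path],
) -> None:
    """Write summary, anchored-marker and ACE-style files for deconvolution
    results (duck-typed: marker, status, solutions with contig_id/clones/score)."""
    results = list(results)
    with open(summary_path, "w", encoding="utf-8") as fh:
        fh.write("marker\tstatus\tcontig\tn_clones\tscore\tclones\n")
        for res in results:
            if res.status == "no_solution" or not res.solutions:
                fh.write(f"{res.marker}\t{res.status}\t\t0\t\t\n")
                continue
            top = res.solutions[0]
            # for a non-unique call report the union of the tied top sets
            returned = res.returned_clones() if hasattr(res, "returned_clones") else set(top.clones)
            if res.status == "non_unique":
                tied = sorted(
                    {s.contig_id for s in res.solutions if round(s.score, 6) == round(top.score, 6)}
                )
                contig = ";".join(tied)
            else:
                contig = top.contig_id
            fh.write(
                f"{res.marker}\t{res.status}\t{contig}\t{len(returned)}"
                f"\t{top.score:.6f}\t{','.join(sorted(returned))}\n"
            )
    with open(anchored_path, "w", encoding="utf-8") as fh:
        fh.write("marker\tcontig\tclones\n")
        for res in results:
            if res.status == "unique":
                top = res.solutions[0]
                fh.write(f"{res.marker}\t{top.contig_id}\t{','.join(sorted(top.clones))}\n")
    with open(ace_path, "w", encoding="utf-8") as fh:
        fh.write(ACE_HEADER + "\n")
        fh.write("marker\tclone\tcontig\n")
        for res in results:
            if res.status == "unique":
                top = res.solutions[0]
                for clone in sorted(top.clones):
                    fh.write(f"{res.marker}\t{clone}\t{top.contig_id}\n")


def read_summary(path: Union[str, Path]) -> list[dict]:
    """Read back a summary TSV into a list of plain dicts."""
    rows: list[dict] = []
    with open(path, encoding="utf-8") as fh:
        header = _read_header(fh, path)
        expected = ["marker", "status", "contig", "n_clones", "score", "clones"]
        if header != expected:
            raise FileFormatError(f"{path}: expected header {expected}, got {header}")
        for lineno, row in _iter_rows(fh):
            if len(row) != 6:
                raise FileFormatError(f"{path}:{lineno}: expected 6 columns")
            rows.append(
                {
                    "marker": row[0],
                    "status": row[1],
                    "contig": row[2] or None,
                    "n_clones": int(row[3]),
                    "score": float(row[4]) if row[4] else None,
                    "clones": set(_split_list(row[5])),
                }
            )
    return rows


# ---------------------------------------------------------------------------
# design config (YAML)
# ---------------------------------------------------------------------------


def write_design_config(design: PoolingDesign, path: Union[str, Path]) -> None:
    """Serialize the construction parameters of a design as YAML.

    The matrix cell placement itself lives in the matrix design TSV; the
    config records libraries, matrix shape and the sub-pool plan.
    """
    plan: dict[str, int] = {}
    for sub in design.sub_pools:
        code = design.library_of_sub_pool[sub]
        plan[code] = plan.get(code, 0) + 1
    doc = {
        "matrix_shape": [design.matrix.n_rows, design.matrix.n_cols],
        "libraries": [
            {"code": lib.code, "n_plates": lib.n_plates, "genome_coverage": lib.genome_coverage}
            for lib in design.libraries
        ],
        "sub_pool_plan": plan,
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def read_design_config(
    path: Union[str, Path],
    matrix_cells: Optional[dict[tuple[int, int], PlateRef]] = None,
) -> PoolingDesign:
    """Rebuild a :class:`PoolingDesign` from a YAML config, optionally with
    an explicit matrix cell placement from a matrix design file."""
    with open(path, encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    try:
        libraries = [
            LibrarySpec(
                code=str(lib["code"]),
                n_plates=int(lib["n_plates"]),
                genome_coverage=float(lib.get("genome_coverage", 0.0)),
            )
            for lib in doc["libraries"]
        ]
        shape = tuple(int(x) for x in doc["matrix_shape"])
        plan = {str(k): int(v) for k, v in (doc.get("sub_pool_plan") or {}).items()}
    except (KeyError, TypeError, ValueError) as exc:
        raise FileFormatError(f"{path}: bad design config ({exc})") from exc
    return build_design(libraries, shape, sub_pool_plan=plan, matrix_cells=matrix_cells)


# ---------------------------------------------------------------------------
# simulation truth
# ---------------------------------------------------------------------------


def write_truth(truth, path: Union[str, Path]) -> None:
    """Serialize simulation truth (marker position, planted clones, true hits)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("marker\tposition\ttp_clones\trsp\tcsp\trp\tcp\n")
        for marker in sorted(truth.marker_positions):
            th = truth.true_hits[marker]
            fh.write(
                "\t".join(
                    [
                        marker,
                        f"{truth.marker_positions[marker]:.3f}",
                        ",".join(sorted(truth.tp_clones[marker])),
                        ",".join(str(r) for r in sorted(th.rsp_hits)),
                        ",".join(str(c) for c in sorted(th.csp_hits)),
                        ",".join(f"{s}:{r}" for s, r in sorted(th.rp_hits)),
                        ",".join(f"{s}:{c}" for s, c in sorted(th.cp_hits)),
                    ]
                )
                + "\n"
            )


def read_truth(path: Union[str, Path]) -> tuple[dict[str, float], dict[str, set[str]], dict[str, MarkerHits]]:
    """Read back a truth TSV: positions, planted clone sets, true hits."""
    positions: dict[str, float] = {}
    tp_clones: dict[str, set[str]] = {}
    true_hits: dict[str, MarkerHits] = {}
    with open(path, encoding="utf-8") as fh:
        header = _read_header(fh, path)
        expected = ["marker", "position", "tp_clones", "rsp", "csp", "rp", "cp"]
        if header != expected:
            raise FileFormatError(f"{path}: expected header {expected}, got {header}")
        for lineno, row in _iter_rows(fh):
            if len(row) != 7:
                raise FileFormatError(f"{path}:{lineno}: expected 7 columns")
            marker = row[0]
            positions[marker] = float(row[1])
            tp_clones[marker] = set(_split_list(row[2]))
            true_hits[marker] = MarkerHits(
                marker=marker,
                rsp_hits={int(t) for t in _split_list(row[3])},
                csp_hits={int(t) for t in _split_list(row[4])},
                rp_hits={_parse_rp(t) for t in _split_list(row[5])},
                cp_hits={_parse_cp(t) for t in _split_list(row[6])},
            )
    return positions, tp_clones, true_hits
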