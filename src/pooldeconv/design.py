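"""Multi-library 384-well plate collections and the five pool dimensions.

A clone library collection is stacked as 384-well plates. Five kinds of DNA
pools are built on top of it:

* ``PP``  — plate pool, all 384 clones of one plate;
* ``RSP`` — row super-pool, all plate pools in one row of a 2-D plate matrix;
* ``CSP`` — column super-pool, all plate pools in one matrix column;
* ``RP``  — clone row pool, all clones sharing a well row across the plates of
  one sub-pool (a per-library split of the plate stack);
* ``CP``  — clone column pool, same for well columns.

The deconvolution machinery in :mod:`pooldeconv.deconvolution` consumes the
:class:`PoolingDesign` built here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional, Sequence

__all__ = [
    "PlateLayout",
    "LibrarySpec",
    "CloneAddress",
    "SuperPoolMatrix",
    "PoolingDesign",
    "PoolId",
    "PlateRef",
    "CloneNameError",
    "DesignError",
    "parse_clone_name",
    "format_clone_name",
    "build_design",
    "pool_size",
    "true_pool_hits",
    "expected_intersections",
]

WELL_ROW_LABELS = "ABCDEFGHIJKLMNOP"

#: (library code, 1-based plate number) — global plate identity.
PlateRef = tuple[str, int]


class CloneNameError(ValueError):
    """A clone name does not follow the LIB + plate + row + column grammar."""


class DesignError(ValueError):
    """Inconsistent pooling-design construction parameters."""


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of one microtiter plate (16 lettered rows x 24 columns)."""

    n_well_rows: int = 16
    n_well_cols: int = 24

    def __post_init__(self) -> None:
        if self.n_well_rows < 1 or self.n_well_rows > len(WELL_ROW_LABELS):
            raise DesignError(f"unsupported well row count {self.n_well_rows}")
        if self.n_well_cols < 1:
            raise DesignError(f"unsupported well column count {self.n_well_cols}")

    @property
    def wells_per_plate(self) -> int:
        return self.n_well_rows * self.n_well_cols

    @property
    def row_labels(self) -> str:
        return WELL_ROW_LABELS[: self.n_well_rows]

    def valid_row(self, label: str) -> bool:
        return label in self.row_labels

    def valid_col(self, col: int) -> bool:
        return 1 <= col <= self.n_well_cols


@dataclass(frozen=True)
class LibrarySpec:
    """One BAC library: short code, plate count and genome coverage."""

    code: str
    n_plates: int
    genome_coverage: float = 0.0

    def __post_init__(self) -> None:
        if not self.code:
            raise DesignError("library code must be non-empty")
        if self.n_plates < 1:
            raise DesignError(f"library {self.code!r}: n_plates must be >= 1")


@dataclass(frozen=True, order=True)
class CloneAddress:
    """A single clone: library code, plate number, well row letter, well column."""

    library: str
    plate: int
    well_row: str
    well_col: int

    @property
    def plate_ref(self) -> PlateRef:
        return (self.library, self.plate)


_CLONE_NAME_RE = re.compile(r"^([A-Za-z]+?)(\d+)([A-Za-z])(\d+)$")


def parse_clone_name(
    name: str,
    known_libraries: Optional[Sequence[str]] = None,
    layout: PlateLayout = PlateLayout(),
) -> CloneAddress:
    """Decompose a clone name like ``BB092N18`` into a :class:`CloneAddress`.

    Grammar: library code (letters) + plate number (digits, leading zeros
    allowed) + well row letter + well column number.  When *known_libraries*
    is given the library code must be one of them.
    """
    m = _CLONE_NAME_RE.match(name)
    if m is None:
        raise CloneNameError(f"malformed clone name {name!r}")
    lib, plate_s, row, col_s = m.groups()
    row = row.upper()
    if not layout.valid_row(row):
        raise CloneNameError(f"clone name {name!r}: well row {row!r} out of range")
    col = int(col_s)
    if not layout.valid_col(col):
        raise CloneNameError(f"clone name {name!r}: well column {col} out of range")
    if known_libraries is not None and lib not in known_libraries:
        raise CloneNameError(f"clone name {name!r}: unknown library code {lib!r}")
    plate = int(plate_s)
    if plate < 1:
        raise CloneNameError(f"clone name {name!r}: plate number {plate} out of range")
    return CloneAddress(library=lib, plate=plate, well_row=row, well_col=col)


def format_clone_name(address: CloneAddress, plate_digits: int = 3) -> str:
    """Canonical clone name: library + zero-padded plate + row + column."""
    return (
        f"{address.library}{address.plate:0{plate_digits}d}"
        f"{address.well_row}{address.well_col}"
    )


@dataclass
class SuperPoolMatrix:
    """2-D arrangement of plate pools; rows are RSPs, columns are CSPs.

    ``cells`` maps 1-based ``(matrix_row, matrix_col)`` to a plate; cells that
    do not appear are empty.
    """

    n_rows: int
    n_cols: int
    cells: dict[tuple[int, int], PlateRef]
    plate_cell: dict[PlateRef, tuple[int, int]] = field(init=False)

    def __post_init__(self) -> None:
        self.plate_cell = {}
        for (r, c), plate in self.cells.items():
            if not (1 <= r <= self.n_rows and 1 <= c <= self.n_cols):
                raise DesignError(f"matrix cell ({r}, {c}) outside {self.n_rows}x{self.n_cols}")
            if plate in self.plate_cell:
                raise DesignError(f"plate {plate} assigned to more than one matrix cell")
            self.plate_cell[plate] = (r, c)

    def plates_in_row(self, row: int) -> list[PlateRef]:
        return [self.cells[(row, c)] for c in range(1, self.n_cols + 1) if (row, c) in self.cells]

    def plates_in_col(self, col: int) -> list[PlateRef]:
        return [self.cells[(r, col)] for r in range(1, self.n_rows + 1) if (r, col) in self.cells]

    @property
    def n_empty_cells(self) -> int:
        return self.n_rows * self.n_cols - len(self.cells)


@dataclass(frozen=True)
class PoolId:
    """Identifier of one pool.

    ``index`` depends on ``kind``: matrix row (int) for RSP, matrix column
    (int) for CSP, a :data:`PlateRef` for PP, ``(sub_pool, well_row)`` for RP
    and ``(sub_pool, well_col)`` for CP.
    """

    kind: str  # one of PP, RSP, CSP, RP, CP
    index: object

    def __post_init__(self) -> None:
        if self.kind not in ("PP", "RSP", "CSP", "RP", "CP"):
            raise DesignError(f"unknown pool kind {self.kind!r}")


POOL_KINDS = ("PP", "RSP", "CSP", "RP", "CP")
#: the four pool kinds actually screened by the assay (PP positives are inferred)
SCREENED_KINDS = ("RSP", "CSP", "RP", "CP")


@dataclass
class PoolingDesign:
    """A complete pooling design over a multi-library plate collection."""

    layout: PlateLayout
    libraries: list[LibrarySpec]
    matrix: SuperPoolMatrix
    #: sub-pool id -> ordered plates it contains
    sub_pools: dict[str, list[PlateRef]]
    #: plate -> its sub-pool id
    sub_pool_of_plate: dict[PlateRef, str] = field(init=False)
    #: sub-pool id -> library code
    library_of_sub_pool: dict[str, str] = field(init=False)

    def __post_init__(self) -> None:
        self.sub_pool_of_plate = {}
        self.library_of_sub_pool = {}
        for sub, plates in self.sub_pools.items():
            if not plates:
                raise DesignError(f"sub-pool {sub!r} is empty")
            libs = {p[0] for p in plates}
            if len(libs) != 1:
                raise DesignError(f"sub-pool {sub!r} mixes libraries {sorted(libs)}")
            self.library_of_sub_pool[sub] = plates[0][0]
            for p in plates:
                if p in self.sub_pool_of_plate:
                    raise DesignError(f"plate {p} in more than one sub-pool")
                self.sub_pool_of_plate[p] = sub

    # -- basic accessors ---------------------------------------------------

    @property
    def plates(self) -> list[PlateRef]:
        return [(lib.code, p) for lib in self.libraries for p in range(1, lib.n_plates + 1)]

    @property
    def n_plates(self) -> int:
        return sum(lib.n_plates for lib in self.libraries)

    @property
    def n_clones(self) -> int:
        return self.n_plates * self.layout.wells_per_plate

    @property
    def library_codes(self) -> list[str]:
        return [lib.code for lib in self.libraries]

    def library(self, code: str) -> LibrarySpec:
        for lib in self.libraries:
            if lib.code == code:
                return lib
        raise DesignError(f"unknown library code {code!r}")

    def clones(self) -> Iterator[CloneAddress]:
        """All clone addresses of the design, plate-major."""
        for lib, plate in self.plates:
            for row in self.layout.row_labels:
                for col in range(1, self.layout.n_well_cols + 1):
                    yield CloneAddress(lib, plate, row, col)

    # -- pool enumeration and sizing --------------------------------------

    def pools(self, kind: str) -> Iterator[PoolId]:
        if kind == "PP":
            for plate in self.plates:
                yield PoolId("PP", plate)
        elif kind == "RSP":
            for r in range(1, self.matrix.n_rows + 1):
                yield PoolId("RSP", r)
        elif kind == "CSP":
            for c in range(1, self.matrix.n_cols + 1):
                yield PoolId("CSP", c)
        elif kind == "RP":
            for sub in self.sub_pools:
                for row in self.layout.row_labels:
                    yield PoolId("RP", (sub, row))
        elif kind == "CP":
            for sub in self.sub_pools:
                for col in range(1, self.layout.n_well_cols + 1):
                    yield PoolId("CP", (sub, col))
        else:
            raise DesignError(f"unknown pool kind {kind!r}")

    def n_pools(self, kind: str) -> int:
        return sum(1 for _ in self.pools(kind))

    def pool_size(self, pool: PoolId) -> int:
        """Exact number of clones contained in *pool*."""
        wells = self.layout.wells_per_plate
        if pool.kind == "PP":
            if pool.index not in self.matrix.plate_cell:
                raise DesignError(f"unknown plate pool {pool.index}")
            return wells
        if pool.kind == "RSP":
            r = pool.index
            if not (1 <= r <= self.matrix.n_rows):
                raise DesignError(f"RSP index {r} out of range")
            return len(self.matrix.plates_in_row(r)) * wells
        if pool.kind == "CSP":
            c = pool.index
            if not (1 <= c <= self.matrix.n_cols):
                raise DesignError(f"CSP index {c} out of range")
            return len(self.matrix.plates_in_col(c)) * wells
        if pool.kind == "RP":
            sub, row = pool.index
            if sub not in self.sub_pools or not self.layout.valid_row(row):
                raise DesignError(f"unknown RP pool {pool.index}")
            return len(self.sub_pools[sub]) * self.layout.n_well_cols
        if pool.kind == "CP":
            sub, col = pool.index
            if sub not in self.sub_pools or not self.layout.valid_col(col):
                raise DesignError(f"unknown CP pool {pool.index}")
            return len(self.sub_pools[sub]) * self.layout.n_well_rows
        raise DesignError(f"unknown pool kind {pool.kind!r}")

    # -- reverse lookup ----------------------------------------------------

    def true_pool_hits(self, clone: CloneAddress) -> set[PoolId]:
        """The five pools (one of each kind) that contain *clone*."""
        plate = clone.plate_ref
        cell = self.matrix.plate_cell.get(plate)
        if cell is None:
            raise DesignError(f"clone {format_clone_name(clone)} not in design")
        if not (self.layout.valid_row(clone.well_row) and self.layout.valid_col(clone.well_col)):
            raise DesignError(f"clone {format_clone_name(clone)} well outside plate layout")
        sub = self.sub_pool_of_plate[plate]
        r, c = cell
        return {
            PoolId("PP", plate),
            PoolId("RSP", r),
            PoolId("CSP", c),
            PoolId("RP", (sub, clone.well_row)),
            PoolId("CP", (sub, clone.well_col)),
        }


def build_design(
    libraries: Sequence[LibrarySpec],
    matrix_shape: tuple[int, int],
    sub_pool_plan: Optional[Mapping[str, int]] = None,
    matrix_cells: Optional[Mapping[tuple[int, int], PlateRef]] = None,
    layout: PlateLayout = PlateLayout(),
) -> PoolingDesign:
    """Construct a :class:`PoolingDesign`.

    Plates fill the matrix row-major in library declaration order unless
    *matrix_cells* (e.g. from a matrix design file) overrides the placement.
    *sub_pool_plan* maps library code to the number of sub-pools the library
    is split into (default 1, i.e. one sub-pool per library); plates are split
    into contiguous near-equal blocks.
    """
    if not libraries:
        raise DesignError("at least one library required")
    codes = [lib.code for lib in libraries]
    if len(set(codes)) != len(codes):
        raise DesignError(f"duplicate library codes in {codes}")
    n_rows, n_cols = matrix_shape
    plates: list[PlateRef] = [
        (lib.code, p) for lib in libraries for p in range(1, lib.n_plates + 1)
    ]
    if len(plates) > n_rows * n_cols:
        raise DesignError(
            f"{len(plates)} plates exceed matrix capacity {n_rows}x{n_cols}={n_rows * n_cols}"
        )

    if matrix_cells is not None:
        cells = dict(matrix_cells)
        missing = set(plates) - set(cells.values())
        if missing:
            raise DesignError(f"matrix file misses {len(missing)} plates, e.g. {sorted(missing)[:3]}")
        extra = set(cells.values()) - set(plates)
        if extra:
            raise DesignError(f"matrix file has unknown plates, e.g. {sorted(extra)[:3]}")
    else:
        cells = {}
        for i, plate in enumerate(plates):
            cells[(i // n_cols + 1, i % n_cols + 1)] = plate

    matrix = SuperPoolMatrix(n_rows=n_rows, n_cols=n_cols, cells=cells)

    plan = dict(sub_pool_plan or {})
    unknown = set(plan) - set(codes)
    if unknown:
        raise DesignError(f"sub-pool plan names unknown libraries {sorted(unknown)}")
    sub_pools: dict[str, list[PlateRef]] = {}
    for lib in libraries:
        n_sub = int(plan.get(lib.code, 1))
        if n_sub < 1 or n_sub > lib.n_plates:
            raise DesignError(
                f"library {lib.code!r}: cannot split {lib.n_plates} plates into {n_sub} sub-pools"
            )
        lib_plates = [(lib.code, p) for p in range(1, lib.n_plates + 1)]
        if n_sub == 1:
            sub_pools[lib.code] = lib_plates
        else:
            # contiguous near-equal blocks
            base, rem = divmod(len(lib_plates), n_sub)
            start = 0
            for k in range(n_sub):
                size = base + (1 if k < rem else 0)
                sub_pools[f"{lib.code}.{k + 1}"] = lib_plates[start : start + size]
                start += size

    return PoolingDesign(layout=layout, libraries=list(libraries), matrix=matrix, sub_pools=sub_pools)


def pool_size(design: PoolingDesign, pool: PoolId) -> int:
    return design.pool_size(pool)


def true_pool_hits(clone: CloneAddress, design: PoolingDesign) -> set[PoolId]:
    return design.true_pool_hits(clone)


def expected_intersections(genome_equivalents: int) -> tuple[int, int]:
    """Idealized super-pool intersection arithmetic.

    Screening g genome equivalents with each positive plate in a distinct
    matrix row and column yields g*g row/column intersections, of which
    g*g - g are false positives.
    """
    g = genome_equivalents
    if g < 1:
        raise ValueError(f"genome equivalents must be >= 1, got {g}")
    return g * g, g * g - g
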