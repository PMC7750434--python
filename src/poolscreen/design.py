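"""3D pooling design for arrayed clone libraries.

A large-insert clone library arrayed in microtiter plates is screened by
sequencing *pools* of clones rather than individual wells.  Every clone is
placed in exactly three pools — one per dimension (plate, row, column) — so
that a sequence observed in one plate pool, one row pool and one column pool
can be triangulated back to a single well.

Two pooling strategies are modelled:

``direct384``
    Plates are pooled as-is.  For a set of *k* plates this yields *k* plate
    pools plus one row pool per row letter and one column pool per column
    number of the plate format (16 rows / 24 columns for 384-well plates,
    8 / 12 for 96-well plates).

``rearray96``
    Each 384-well plate is split into four quadrants which are re-arrayed
    into 96-well plates (interleaved-parity convention, see
    :func:`rearray_384_to_96`), giving 4·k plate pools, 8 row pools and 12
    column pools per set.  This reduces the number of clones per plate pool
    and therefore increases per-clone sequencing coverage.

Libraries are organised in *sets* (contiguous blocks of plates, default 10);
pools never span sets, and deconvolution is performed per set.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass
from typing import Iterator, Literal

ROWS_384 = "ABCDEFGHIJKLMNOP"
ROWS_96 = "ABCDEFGH"
FORMAT_ROWS: dict[int, str] = {384: ROWS_384, 96: ROWS_96}
FORMAT_COLS: dict[int, int] = {384: 24, 96: 12}

PLATE, ROW, COLUMN = "plate", "row", "column"
DIMENSIONS = (PLATE, ROW, COLUMN)

DIRECT384 = "direct384"
REARRAY96 = "rearray96"
STRATEGIES = (DIRECT384, REARRAY96)

Strategy = Literal["direct384", "rearray96"]


class PoolingError(ValueError):
    """Base class for pooling-design errors."""


class InvalidConfigurationError(PoolingError):
    pass


class CrossSetError(PoolingError):
    """Pool ids from different sets were combined."""


class NoSuchWellError(PoolingError):
    """A pool triple does not intersect in any well."""


@dataclass(frozen=True, order=True)
class WellAddress:
    """Physical location of a clone: 1-based plate, row letter, 1-based column.

    The canonical string form ``P{plate:02d}{row}{column:02d}`` (e.g.
    ``P29O18``) is the library-wide clone identifier.
    """

    plate: int
    row: str
    column: int

    def canonical(self) -> str:
        return f"P{self.plate:02d}{self.row}{self.column:02d}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.canonical()

    def validate(self, plate_format: int) -> None:
        rows = FORMAT_ROWS[plate_format]
        if self.row not in rows:
            raise InvalidConfigurationError(
                f"row {self.row!r} invalid for {plate_format}-well format"
            )
        if not 1 <= self.column <= FORMAT_COLS[plate_format]:
            raise InvalidConfigurationError(
                f"column {self.column} out of range for {plate_format}-well format"
            )
        if self.plate < 1:
            raise InvalidConfigurationError("plate index must be >= 1")

    _RE = re.compile(r"^P(\d+)([A-P])(\d+)$")

    @classmethod
    def parse(cls, text: str) -> "WellAddress":
        m = cls._RE.match(text)
        if not m:
            raise InvalidConfigurationError(f"unparseable well address {text!r}")
        return cls(int(m.group(1)), m.group(2), int(m.group(3)))


@dataclass(frozen=True, order=True)
class PoolId:
    """Identity of one pool: the set it belongs to, its dimension, and a label.

    Labels are strings: zero-padded plate index ("03"), row letter ("O"),
    zero-padded column number ("18"), or quadrant-plate label ("03Q2") for
    the re-array strategy.
    """

    set_index: int
    dimension: str
    label: str

    def tag(self) -> str:
        """Compact identifier used as the pool-of-origin prefix in contig ids."""
        return f"S{self.set_index}.{self.dimension}.{self.label}"

    _RE = re.compile(r"^S(\d+)\.(plate|row|column)\.([0-9A-PQ]+)$")

    @classmethod
    def from_tag(cls, tag: str) -> "PoolId":
        m = cls._RE.match(tag)
        if not m:
            raise InvalidConfigurationError(f"unparseable pool tag {tag!r}")
        return cls(int(m.group(1)), m.group(2), m.group(3))


@dataclass(frozen=True)
class QuadrantAddress:
    """A well in a 96-well quadrant plate derived from a 384-well source plate."""

    plate: int  # source 384-well plate index
    quadrant: int  # 1..4
    row: str  # A-H
    column: int  # 1..12

    def plate_label(self) -> str:
        return f"{self.plate:02d}Q{self.quadrant}"


@dataclass(frozen=True)
class LibraryLayout:
    """Arrayed library: ``n_plates`` plates of a given format, in sets."""

    n_plates: int
    plate_format: int
    set_size: int

    def __post_init__(self) -> None:
        if self.n_plates < 1 or self.set_size < 1:
            raise InvalidConfigurationError("n_plates and set_size must be >= 1")
        if self.plate_format not in FORMAT_ROWS:
            raise InvalidConfigurationError(
                f"plate_format must be one of {sorted(FORMAT_ROWS)}"
            )

    @property
    def n_sets(self) -> int:
        return -(-self.n_plates // self.set_size)

    @property
    def sets(self) -> list[list[int]]:
        """Ordered partition of 1-based plate indices into contiguous sets."""
        plates = list(range(1, self.n_plates + 1))
        return [
            plates[i : i + self.set_size] for i in range(0, self.n_plates, self.set_size)
        ]

    @property
    def total_wells(self) -> int:
        return self.n_plates * self.plate_format

    def wells_of_plate(self, plate: int) -> Iterator[WellAddress]:
        rows = FORMAT_ROWS[self.plate_format]
        for row in rows:
            for col in range(1, FORMAT_COLS[self.plate_format] + 1):
                yield WellAddress(plate, row, col)

    def wells(self) -> Iterator[WellAddress]:
        for plate in range(1, self.n_plates + 1):
            yield from self.wells_of_plate(plate)


def build_layout(n_plates: int, plate_format: int, set_size: int) -> LibraryLayout:
    """Validate arguments and construct a :class:`LibraryLayout`."""
    return LibraryLayout(n_plates=n_plates, plate_format=plate_format, set_size=set_size)


def rearray_384_to_96(well: WellAddress) -> QuadrantAddress:
    """Map a 384-well address to its quadrant plate and 96-well position.

    Interleaved-parity convention: 0-based row/column ``(r, c)`` goes to
    quadrant ``2*(r % 2) + (c % 2) + 1`` at 96-well position
    ``(r // 2, c // 2)``.  This is the standard robotic re-array and is a
    bijection over the 384 wells of a plate.
    """
    well.validate(384)
    r = ROWS_384.index(well.row)
    c = well.column - 1
    quadrant = 2 * (r % 2) + (c % 2) + 1
    return QuadrantAddress(well.plate, quadrant, ROWS_96[r // 2], c // 2 + 1)


def inverse_rearray(qwell: QuadrantAddress) -> WellAddress:
    """Inverse of :func:`rearray_384_to_96`."""
    if not 1 <= qwell.quadrant <= 4:
        raise InvalidConfigurationError(f"quadrant {qwell.quadrant} out of range")
    if qwell.row not in ROWS_96 or not 1 <= qwell.column <= 12:
        raise InvalidConfigurationError(f"invalid 96-well position {qwell}")
    q = qwell.quadrant - 1
    r = 2 * ROWS_96.index(qwell.row) + q // 2
    c = 2 * (qwell.column - 1) + q % 2 + 1
    return WellAddress(qwell.plate, ROWS_384[r], c)


@dataclass
class PoolAssignment:
    """Pool membership for one set of plates under one strategy.

    ``membership`` maps each :class:`PoolId` to its member wells (original
    plate-format coordinates); ``inverse`` gives, for every well, exactly one
    pool per dimension.
    """

    strategy: str
    set_index: int
    plate_format: int
    plates: tuple[int, ...]
    membership: dict[PoolId, frozenset[WellAddress]]
    inverse: dict[WellAddress, dict[str, PoolId]]

    def pools(self, dimension: str | None = None) -> list[PoolId]:
        ids = sorted(self.membership)
        if dimension is None:
            return ids
        return [p for p in ids if p.dimension == dimension]

    def pool_counts(self) -> dict[str, int]:
        return {d: len(self.pools(d)) for d in DIMENSIONS}

    @property
    def wells(self) -> list[WellAddress]:
        return sorted(self.inverse)


def _plate_label(plate: int) -> str:
    return f"{plate:02d}"


def _column_label(col: int) -> str:
    return f"{col:02d}"


def build_pooling_scheme(
    layout: LibraryLayout, set_index: int, strategy: str
) -> PoolAssignment:
    """Build the pool membership map for one set under a strategy.

    ``set_index`` is 1-based.  ``direct384`` pools plates as arrayed;
    ``rearray96`` (384-format sets only) pools the quadrant re-array.
    """
    if strategy not in STRATEGIES:
        raise InvalidConfigurationError(f"unknown strategy {strategy!r}")
    if not 1 <= set_index <= layout.n_sets:
        raise InvalidConfigurationError(
            f"set {set_index} out of range (layout has {layout.n_sets} sets)"
        )
    plates = layout.sets[set_index - 1]
    fmt = layout.plate_format

    membership: dict[PoolId, set[WellAddress]] = {}
    if strategy == DIRECT384:
        for plate in plates:
            pid = PoolId(set_index, PLATE, _plate_label(plate))
            membership[pid] = set(layout.wells_of_plate(plate))
        for row in FORMAT_ROWS[fmt]:
            pid = PoolId(set_index, ROW, row)
            membership[pid] = {
                w for p in plates for w in layout.wells_of_plate(p) if w.row == row
            }
        for col in range(1, FORMAT_COLS[fmt] + 1):
            pid = PoolId(set_index, COLUMN, _column_label(col))
            membership[pid] = {
                w for p in plates for w in layout.wells_of_plate(p) if w.column == col
            }
    else:  # rearray96
        if fmt != 384:
            raise InvalidConfigurationError(
                "rearray96 requires 384-format plates"
            )
        rearrayed = {
            w: rearray_384_to_96(w)
            for p in plates
            for w in layout.wells_of_plate(p)
        }
        for plate, quadrant in itertools.product(plates, range(1, 5)):
            label = QuadrantAddress(plate, quadrant, "A", 1).plate_label()
            pid = PoolId(set_index, PLATE, label)
            membership[pid] = {
                w for w, qw in rearrayed.items()
                if qw.plate == plate and qw.quadrant == quadrant
            }
        for row in ROWS_96:
            pid = PoolId(set_index, ROW, row)
            membership[pid] = {w for w, qw in rearrayed.items() if qw.row == row}
        for col in range(1, 13):
            pid = PoolId(set_index, COLUMN, _column_label(col))
            membership[pid] = {w for w, qw in rearrayed.items() if qw.column == col}

    inverse: dict[WellAddress, dict[str, PoolId]] = {}
    for pid, wells in membership.items():
        for w in wells:
            inverse.setdefault(w, {})[pid.dimension] = pid

    return PoolAssignment(
        strategy=strategy,
        set_index=set_index,
        plate_format=fmt,
        plates=tuple(plates),
        membership={pid: frozenset(ws) for pid, ws in membership.items()},
        inverse=inverse,
    )


def coordinates_from_pools(
    plate_pool: PoolId,
    row_pool: PoolId,
    col_pool: PoolId,
    assignment: PoolAssignment,
) -> WellAddress:
    """Resolve a (plate, row, column) pool triple to its unique well.

    The returned address is always in the original plate-format coordinates
    (for ``rearray96`` the unique 96-well intersection is mapped back through
    the quadrant re-array, which the membership sets already encode).
    """
    triple = (plate_pool, row_pool, col_pool)
    sets = {p.set_index for p in triple}
    if len(sets) != 1 or sets != {assignment.set_index}:
        raise CrossSetError(f"pool triple spans sets {sorted(sets)}")
    dims = tuple(p.dimension for p in triple)
    if dims != (PLATE, ROW, COLUMN):
        raise InvalidConfigurationError(f"pool triple has dimensions {dims}")
    try:
        candidates = (
            assignment.membership[plate_pool]
            & assignment.membership[row_pool]
            & assignment.membership[col_pool]
        )
    except KeyError as exc:
        raise InvalidConfigurationError(f"unknown pool {exc.args[0]}") from exc
    if not candidates:
        raise NoSuchWellError(
            f"pools {plate_pool.label}/{row_pool.label}/{col_pool.label} "
            "do not intersect"
        )
    if len(candidates) > 1:  # cannot happen for the built-in strategies
        raise PoolingError(f"ambiguous pool triple: {sorted(candidates)}")
    return next(iter(candidates))
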