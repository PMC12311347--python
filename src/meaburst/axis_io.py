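"""Reading and writing electrode burst lists in the AxIS Navigator CSV dialect.

AxIS Navigator (Axion BioSystems) exports one CSV row per detected
single-electrode burst: the electrode label, the burst start time in
seconds, the burst size in spikes, and the burst duration in seconds.
Exports may carry a metadata preamble of variable length before the
header row; this module skips it by scanning for the header.

Electrode naming follows the vendor convention for 24-well CytoView
plates with a 4x4 electrode grid per well: ``B6_24`` is the electrode in
column 2, row 4 of well B6 (plate row B, plate column 6).
"""

from __future__ import annotations

import csv
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence, TextIO

import pandas as pd

from .errors import ElectrodeIDError, FormatError, ValidationError

__all__ = [
    "ElectrodeID",
    "PlateLayout",
    "BurstRecord",
    "BurstTable",
    "DialectOptions",
    "parse_electrode_id",
    "read_electrode_burst_list",
    "write_electrode_burst_list",
]


@dataclass(frozen=True, order=True)
class ElectrodeID:
    """One electrode position: well label plus (column, row) within the well.

    The canonical token is ``"<well>_<col><row>"``; the first position
    digit is the column and the second the row of the 4x4 in-well grid.
    """

    well_label: str
    col: int
    row: int

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[A-Z][0-9]+", self.well_label):
            raise ElectrodeIDError(
                f"well label {self.well_label!r} is not a row letter plus column number"
            )
        for name, v in (("col", self.col), ("row", self.row)):
            if not isinstance(v, int) or not 1 <= v <= 4:
                raise ElectrodeIDError(
                    f"electrode {name} {v!r} outside the 4x4 in-well grid"
                )

    def __str__(self) -> str:
        return f"{self.well_label}_{self.col}{self.row}"

    @property
    def token(self) -> str:
        """Canonical string form, e.g. ``"B6_24"``."""
        return str(self)


_TOKEN_RE = re.compile(r"^([A-Za-z][0-9]+)_([0-9])([0-9])$")


def parse_electrode_id(token: str) -> ElectrodeID:
    """Parse an electrode token such as ``"B6_24"`` (column 2, row 4 of well B6).

    Raises
    ------
    ElectrodeIDError
        If the token has no underscore, non-digit positions, or a
        position digit outside 1-4.
    """
    if not token:
        raise ElectrodeIDError("empty electrode token")
    m = _TOKEN_RE.match(token.strip())
    if m is None:
        raise ElectrodeIDError(f"malformed electrode token {token!r}")
    well, col, row = m.group(1).upper(), int(m.group(2)), int(m.group(3))
    if not (1 <= col <= 4 and 1 <= row <= 4):
        raise ElectrodeIDError(
            f"electrode token {token!r}: position {col}{row} outside the 4x4 grid"
        )
    return ElectrodeID(well, col, row)


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a multi-well MEA plate.

    Defaults describe the 24-well CytoView plate: wells A1-D6, 16
    electrodes per well on a 4x4 grid, 50 um electrode diameter at a
    350 um pitch.
    """

    well_rows: int = 4
    well_cols: int = 6
    electrodes_per_well_side: int = 4
    electrode_diameter_um: float = 50.0
    electrode_pitch_um: float = 350.0

    def __post_init__(self) -> None:
        if self.well_rows < 1 or self.well_cols < 1:
            raise ValidationError("plate must have at least one well")
        if self.electrodes_per_well_side < 1:
            raise ValidationError("wells must have at least one electrode")

    @property
    def wells(self) -> tuple[str, ...]:
        """Well labels in row-major order (A1, A2, ..)."""
        return tuple(
            f"{chr(ord('A') + r)}{c + 1}"
            for r in range(self.well_rows)
            for c in range(self.well_cols)
        )

    def electrodes(self, well_label: str) -> tuple[ElectrodeID, ...]:
        """All electrode IDs of one well, column-major ('11','12',..,'44')."""
        if well_label not in self.wells:
            raise ValidationError(f"well {well_label!r} not in layout")
        side = self.electrodes_per_well_side
        return tuple(
            ElectrodeID(well_label, c, r)
            for c in range(1, side + 1)
            for r in range(1, side + 1)
        )

    @property
    def n_electrodes_per_well(self) -> int:
        return self.electrodes_per_well_side**2


@dataclass(frozen=True)
class BurstRecord:
    """One detected burst on one electrode."""

    electrode: ElectrodeID
    start_time_s: float
    size_spikes: int
    duration_s: float

    def __post_init__(self) -> None:
        if self.start_time_s < 0:
            raise ValidationError(f"negative burst start time {self.start_time_s}")
        if self.size_spikes < 1:
            raise ValidationError(f"burst size {self.size_spikes} < 1 spike")
        if self.duration_s < 0:
            raise ValidationError(f"negative burst duration {self.duration_s}")
        if self.duration_s == 0 and self.size_spikes > 1:
            raise ValidationError(
                "zero duration is only permitted for single-spike records"
            )


@dataclass(frozen=True)
class BurstTable:
    """An electrode burst list: records plus plate metadata.

    Records are stable-sorted by (electrode token, start time) at
    construction, and every electrode must belong to a well of the
    layout.
    """

    records: tuple[BurstRecord, ...]
    recording_id: str = ""
    layout: PlateLayout = field(default_factory=PlateLayout)
    recording_length_s: float | None = None

    def __post_init__(self) -> None:
        wells = set(self.layout.wells)
        for rec in self.records:
            if rec.electrode.well_label not in wells:
                raise ValidationError(
                    f"electrode {rec.electrode} belongs to no well of the layout"
                )
        ordered = tuple(
            sorted(self.records, key=lambda r: (r.electrode, r.start_time_s))
        )
        object.__setattr__(self, "records", ordered)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[BurstRecord]:
        return iter(self.records)

    def electrodes(self) -> tuple[ElectrodeID, ...]:
        """Distinct electrodes with at least one record, sorted."""
        return tuple(sorted({r.electrode for r in self.records}))

    def wells(self) -> tuple[str, ...]:
        return tuple(sorted({r.electrode.well_label for r in self.records}))

    def for_electrode(self, electrode: ElectrodeID) -> tuple[BurstRecord, ...]:
        return tuple(r for r in self.records if r.electrode == electrode)

    def to_frame(self) -> pd.DataFrame:
        """Tidy DataFrame view (one row per burst)."""
        return pd.DataFrame(
            {
                "electrode": [str(r.electrode) for r in self.records],
                "start_time_s": [r.start_time_s for r in self.records],
                "size_spikes": [r.size_spikes for r in self.records],
                "duration_s": [r.duration_s for r in self.records],
            }
        )


# --- CSV dialect ------------------------------------------------------------

#: canonical column keys
_CANON = ("electrode", "time", "size", "duration")

_DEFAULT_ALIASES: dict[str, str] = {
    "electrode": "electrode",
    "time": "time",
    "times": "time",
    "timestart": "time",
    "starttime": "time",
    "size": "size",
    "sizespikes": "size",
    "duration": "duration",
    "durations": "duration",
    "durationsec": "duration",
}


def _normalize_header(name: str) -> str:
    """Lower-case, strip parenthesized units, drop non-letters.

    ``"Time (s)" -> "time"``, ``"Size_spikes" -> "sizespikes"``.
    """
    name = re.sub(r"\(.*?\)", "", name.lower())
    return re.sub(r"[^a-z]", "", name)


@dataclass(frozen=True)
class DialectOptions:
    """Column-name aliases and preamble policy for burst-list CSVs.

    ``aliases`` maps normalized header strings to the canonical keys
    ``electrode``/``time``/``size``/``duration``; extra entries extend
    (never replace) the defaults. The preamble scan looks for the first
    line containing an electrode-column alias, capped at
    ``max_preamble_lines``.
    """

    aliases: dict[str, str] = field(default_factory=dict)
    max_preamble_lines: int = 200

    def alias_map(self) -> dict[str, str]:
        merged = dict(_DEFAULT_ALIASES)
        merged.update({_normalize_header(k): v for k, v in self.aliases.items()})
        return merged


def _open_text(source: str | Path | TextIO) -> tuple[TextIO, bool]:
    if isinstance(source, (str, Path)):
        return open(source, "r", encoding="utf-8", newline=""), True
    return source, False


def _locate_header(
    lines: Sequence[str], dialect: DialectOptions
) -> tuple[int, dict[str, int]]:
    """Find the header line and map canonical keys to column indices."""
    aliases = dialect.alias_map()
    for i, line in enumerate(lines[: dialect.max_preamble_lines]):
        cells = next(csv.reader([line]), [])
        normed = [_normalize_header(c) for c in cells]
        if any(aliases.get(c) == "electrode" for c in normed):
            colmap: dict[str, int] = {}
            for j, c in enumerate(normed):
                key = aliases.get(c)
                if key is not None and key not in colmap:
                    colmap[key] = j
            missing = [k for k in _CANON if k not in colmap]
            if missing:
                raise FormatError(
                    f"burst list header missing column(s) {missing}; found {cells}"
                )
            return i, colmap
    raise FormatError(
        "no burst-list header found "
        f"(scanned {min(len(lines), dialect.max_preamble_lines)} lines "
        "for an electrode column)"
    )


def read_electrode_burst_list(
    source: str | Path | TextIO,
    dialect: DialectOptions | None = None,
    *,
    recording_id: str = "",
    layout: PlateLayout | None = None,
    recording_length_s: float | None = None,
) -> BurstTable:
    """Read an AxIS-dialect electrode burst list CSV into a :class:`BurstTable`.

    Metadata preamble lines before the header are skipped. Rows with
    unparseable electrode tokens or numeric fields are rejected with
    their 1-based line numbers.
    """
    dialect = dialect or DialectOptions()
    layout = layout or PlateLayout()
    fh, should_close = _open_text(source)
    try:
        lines = fh.read().splitlines()
    finally:
        if should_close:
            fh.close()
    if not any(line.strip() for line in lines):
        raise FormatError("empty burst list file")
    header_idx, colmap = _locate_header(lines, dialect)

    records: list[BurstRecord] = []
    bad_rows: list[str] = []
    for lineno, line in enumerate(lines[header_idx + 1 :], start=header_idx + 2):
        if not line.strip():
            continue
        cells = next(csv.reader([line]), [])
        try:
            electrode = parse_electrode_id(cells[colmap["electrode"]])
            start = float(cells[colmap["time"]])
            size_raw = float(cells[colmap["size"]])
            if size_raw != int(size_raw):
                raise ValidationError(f"non-integer burst size {size_raw}")
            duration = float(cells[colmap["duration"]])
            records.append(BurstRecord(electrode, start, int(size_raw), duration))
        except (IndexError, ValueError) as exc:  # includes our error classes
            bad_rows.append(f"line {lineno}: {exc}")
    if bad_rows:
        raise FormatError(
            "unparseable burst-list rows:\n" + "\n".join(bad_rows[:20])
        )
    return BurstTable(
        tuple(records),
        recording_id=recording_id,
        layout=layout,
        recording_length_s=recording_length_s,
    )


def write_electrode_burst_list(table: BurstTable, sink: str | Path | TextIO) -> None:
    """Write a burst table as CSV in the default dialect.

    Numeric fields use ``repr`` so a read-back reproduces the table
    exactly (full float precision).
    """
    if isinstance(sink, (str, Path)):
        fh: TextIO = open(sink, "w", encoding="utf-8", newline="")
        should_close = True
    else:
        fh, should_close = sink, False
    try:
        writer = csv.writer(fh)
        writer.writerow(["Electrode", "Time (s)", "Size (spikes)", "Duration (s)"])
        for rec in table.records:
            writer.writerow(
                [
                    str(rec.electrode),
                    repr(rec.start_time_s),
                    rec.size_spikes,
                    repr(rec.duration_s),
                ]
            )
    finally:
        if should_close:
            fh.close()
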