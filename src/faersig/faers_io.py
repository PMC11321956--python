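"""Reader/writer for the FAERS quarterly ASCII dialect.

FAERS distributes each quarter as a set of "$"-delimited text tables
(DEMO, DRUG, REAC, OUTC, ...) with a single header line and one record
per line.  This module parses those files into plain field maps keyed by
upper-case column name, and writes the same dialect back out so that
synthetic corpora can be round-tripped through the exact on-disk format.

Only the modern primaryid/caseid schema is modelled; when a legacy
header is encountered the columns ``ISR`` and ``CASE`` are renamed to
``PRIMARYID`` and ``CASEID`` and everything else is passed through.
Files are decoded as Latin-1 with replacement (real FAERS archives
contain non-UTF-8 bytes; the analysis fields used here are ASCII).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

DELIMITER = "$"
TABLE_NAMES = ("DEMO", "DRUG", "REAC", "OUTC")

#: legacy (pre-2012) column names mapped onto the modern schema
LEGACY_COLUMNS = {"ISR": "PRIMARYID", "CASE": "CASEID"}

_QUARTER_RE = re.compile(r"^(\d{4})Q([1-4])$")

MIN_QUARTER = "2004Q1"
MAX_QUARTER = "2099Q4"


class FaersIOError(Exception):
    """Base class for dialect and quarter-range errors."""


class InvalidQuarterError(FaersIOError, ValueError):
    """A quarter label does not match ``YYYYQ[1-4]`` or is out of window."""


class InvalidRangeError(FaersIOError, ValueError):
    """Quarter range start is after its end."""


class TableAbsentError(FaersIOError):
    """An expected per-quarter table file is missing."""

    def __init__(self, table: str, filename: str) -> None:
        self.table = table
        self.filename = filename
        super().__init__(f"table {table} absent: expected file {filename}")


class MalformedHeaderError(FaersIOError):
    """A table header lacks the primaryid column."""


class DialectError(FaersIOError):
    """A field value cannot be represented in the '$'-delimited dialect."""


# ---------------------------------------------------------------------------
# quarter labels
# ---------------------------------------------------------------------------

def parse_quarter(label: str) -> tuple[int, int]:
    """Parse ``'2017Q3'`` into ``(2017, 3)``; raise on malformed labels."""
    m = _QUARTER_RE.match(str(label))
    if m is None:
        raise InvalidQuarterError(f"malformed quarter label: {label!r}")
    return int(m.group(1)), int(m.group(2))


def quarter_index(label: str) -> int:
    """Monotone integer index of a quarter label (consecutive quarters differ by 1)."""
    year, q = parse_quarter(label)
    return year * 4 + (q - 1)


def quarter_label(index: int) -> str:
    """Inverse of :func:`quarter_index`."""
    return f"{index // 4}Q{index % 4 + 1}"


@dataclass(frozen=True)
class QuarterRange:
    """Inclusive chronological range of calendar quarters."""

    start: str
    end: str

    def __post_init__(self) -> None:
        for label in (self.start, self.end):
            idx = quarter_index(label)
            if not quarter_index(MIN_QUARTER) <= idx <= quarter_index(MAX_QUARTER):
                raise InvalidQuarterError(
                    f"quarter {label} outside supported window "
                    f"{MIN_QUARTER}..{MAX_QUARTER}"
                )
        if quarter_index(self.start) > quarter_index(self.end):
            raise InvalidRangeError(f"range start {self.start} after end {self.end}")

    def __len__(self) -> int:
        return quarter_index(self.end) - quarter_index(self.start) + 1

    def __contains__(self, label: str) -> bool:
        return quarter_index(self.start) <= quarter_index(label) <= quarter_index(self.end)

    def labels(self) -> list[str]:
        return iterate_quarters(self)


def iterate_quarters(qrange: QuarterRange) -> list[str]:
    """All quarter labels in ``qrange``, chronological, inclusive of both ends."""
    lo = quarter_index(qrange.start)
    hi = quarter_index(qrange.end)
    return [quarter_label(i) for i in range(lo, hi + 1)]


# ---------------------------------------------------------------------------
# table sets
# ---------------------------------------------------------------------------

RawRow = dict[str, str]


@dataclass
class RawTableSet:
    """The four per-quarter tables as lists of raw field maps.

    Field maps are keyed by upper-case FAERS column name; empty strings
    mark missing values exactly as they appear on disk.
    """

    quarter: str
    demo_rows: list[RawRow] = field(default_factory=list)
    drug_rows: list[RawRow] = field(default_factory=list)
    reac_rows: list[RawRow] = field(default_factory=list)
    outc_rows: list[RawRow] = field(default_factory=list)

    def __post_init__(self) -> None:
        parse_quarter(self.quarter)

    def rows_for(self, table: str) -> list[RawRow]:
        return {
            "DEMO": self.demo_rows,
            "DRUG": self.drug_rows,
            "REAC": self.reac_rows,
            "OUTC": self.outc_rows,
        }[table]


def table_filename(table: str, quarter: str) -> str:
    """On-disk file name for one table of one quarter, e.g. ``DEMO17Q3.txt``."""
    year, q = parse_quarter(quarter)
    return f"{table}{year % 100:02d}Q{q}.txt"


def _normalize_header(fields: list[str]) -> list[str]:
    return [LEGACY_COLUMNS.get(f.strip().upper(), f.strip().upper()) for f in fields]


def _parse_table(path: Path, table: str) -> list[RawRow]:
    with open(path, encoding="latin-1", errors="replace") as fh:
        lines = fh.read().split("\n")
    if lines and lines[-1] == "":
        lines.pop()
    if not lines:
        raise MalformedHeaderError(f"{path}: empty file, no header")
    header = _normalize_header(lines[0].split(DELIMITER))
    if "PRIMARYID" not in header:
        raise MalformedHeaderError(f"{path}: header lacks primaryid column: {lines[0]!r}")
    rows: list[RawRow] = []
    width = len(header)
    for line in lines[1:]:
        values = line.split(DELIMITER)
        if len(values) < width:
            values += [""] * (width - len(values))
        rows.append(dict(zip(header, values)))
    return rows


def read_quarter(directory: str | Path, quarter: str) -> RawTableSet:
    """Read the four quarter tables from ``directory``.

    A missing file is an error (silent gaps would bias downstream time
    series), reported with the exact expected filename.
    """
    directory = Path(directory)
    parsed: dict[str, list[RawRow]] = {}
    for table in TABLE_NAMES:
        path = directory / table_filename(table, quarter)
        if not path.is_file():
            raise TableAbsentError(table, str(path))
        parsed[table] = _parse_table(path, table)
    return RawTableSet(
        quarter=quarter,
        demo_rows=parsed["DEMO"],
        drug_rows=parsed["DRUG"],
        reac_rows=parsed["REAC"],
        outc_rows=parsed["OUTC"],
    )


def _header_for(rows: list[RawRow]) -> list[str]:
    # union of keys in first-seen order; PRIMARYID always present and first
    columns: list[str] = ["PRIMARYID"]
    for row in rows:
        for key in row:
            if key not in columns:
                columns.append(key)
    return columns


def write_quarter(tables: RawTableSet, directory: str | Path) -> list[Path]:
    """Write ``tables`` in the dialect :func:`read_quarter` consumes.

    ``read_quarter(write_quarter(x))`` is the identity on field values;
    a literal "$" inside a field cannot be represented and is rejected.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for table in TABLE_NAMES:
        rows = tables.rows_for(table)
        columns = _header_for(rows)
        path = directory / table_filename(table, tables.quarter)
        with open(path, "w", encoding="latin-1", errors="replace") as fh:
            fh.write(DELIMITER.join(columns) + "\n")
            for row in rows:
                values = []
                for col in columns:
                    value = row.get(col, "")
                    if DELIMITER in value:
                        raise DialectError(
                            f"{table} {tables.quarter}: field {col} contains "
                            f"the '$' delimiter: {value!r}"
                        )
                    values.append(value)
                fh.write(DELIMITER.join(values) + "\n")
        written.append(path)
    return written
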