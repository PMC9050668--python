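"""Domain types for registry records and life tables, plus CSV readers/writers.

A mortality registry row is one deceased (or candidate-deceased) animal with
its demographics, dates and free-text clinical fields.  A life table is the
classical cohort tabulation: for each one-year age interval ``[x, x+1)`` it
holds the deaths ``d_x``, survivors ``l_x``, the death probability
``q_x = d_x / l_x``, the mean fraction of the last year lived ``a_x``, the
animal-years lived ``L_x = (l_x - d_x) + a_x * d_x``, the cumulative years
``T_x`` and the life expectancy ``e_x = T_x / l_x``.  The final interval is
open ("n and over"): everyone alive at ``n`` dies in it, its ``q`` is 1 and
its ``e`` equals its ``a`` (mean years lived past ``n``).

The package ships a transcription of a published UK companion-dog cohort
life table (death counts and mean-fraction-lived per interval) as a worked
fixture; :func:`load_reference_aggregates` returns it rebuilt from those two
columns alone.
"""

from __future__ import annotations

import csv
import enum
import logging
from dataclasses import dataclass, field
from datetime import date
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

from .errors import ConfigurationError, DataError

log = logging.getLogger(__name__)

#: canonical registry CSV header
CANONICAL_COLUMNS = (
    "animal_id",
    "breed",
    "sex",
    "neuter_status",
    "birth_date",
    "death_date",
    "death_mechanism",
    "clinical_note",
    "treatment_text",
    "insured",
)

MANDATORY_COLUMNS = (
    "animal_id",
    "breed",
    "sex",
    "neuter_status",
    "birth_date",
    "death_date",
)


class Sex(str, enum.Enum):
    FEMALE = "female"
    MALE = "male"
    UNKNOWN = "unknown"


class NeuterStatus(str, enum.Enum):
    NEUTERED = "neutered"
    ENTIRE = "entire"
    UNKNOWN = "unknown"


class DeathMechanism(str, enum.Enum):
    EUTHANASED = "euthanased"
    UNASSISTED = "unassisted"
    UNRECORDED = "unrecorded"


#: sentinel stratum label for animals that cannot be classified in a scheme
UNCLASSIFIED = "unclassified"


@dataclass
class DeathRecord:
    """One registry row: an animal with demographics, dates and free text."""

    animal_id: str
    breed: str = ""
    sex: Sex = Sex.UNKNOWN
    neuter_status: NeuterStatus = NeuterStatus.UNKNOWN
    birth_date: Optional[date] = None
    death_date: Optional[date] = None
    death_mechanism: DeathMechanism = DeathMechanism.UNRECORDED
    clinical_note: str = ""
    treatment_text: str = ""
    insured: Optional[bool] = None

    def __post_init__(self) -> None:
        if not self.animal_id:
            raise DataError("animal_id must be non-empty")


@dataclass
class CohortObservation:
    """A cleaned analysis unit: fractional lifespan in years plus stratum labels."""

    animal_id: str
    lifespan_years: float
    strata: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.lifespan_years < 0:
            raise DataError(
                f"lifespan must be non-negative, got {self.lifespan_years!r} "
                f"for {self.animal_id}"
            )


@dataclass
class LifeTableRow:
    """One age interval of a cohort life table.

    ``a_hat`` is ``None`` for a closed interval with no deaths (the mean
    fraction of the last year lived is then undefined).  For the open final
    row ``a_hat`` is the mean years lived past the interval start and may
    exceed 1.
    """

    x: int
    d: int
    l: int
    q_hat: float
    a_hat: Optional[float]
    L: float
    T: float
    e_hat: float
    e_lo: Optional[float] = None
    e_hi: Optional[float] = None


@dataclass
class LifeTable:
    """An ordered set of rows covering ages 0..n, the last row open."""

    stratum: dict[str, str]
    rows: list[LifeTableRow]
    final_open_start: int
    eligible: bool
    n_animals: int

    def row(self, x: int) -> LifeTableRow:
        return self.rows[x]

    def e(self, x: int) -> float:
        return self.rows[x].e_hat

    @property
    def ages(self) -> list[int]:
        return [r.x for r in self.rows]

    def to_frame(self):
        """Life table as a pandas DataFrame (one row per age interval)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "x_start": [r.x for r in self.rows],
                "x_end": [r.x + 1 for r in self.rows[:-1]] + [None],
                "d": [r.d for r in self.rows],
                "l": [r.l for r in self.rows],
                "q_hat": [r.q_hat for r in self.rows],
                "a_hat": [r.a_hat for r in self.rows],
                "L": [r.L for r in self.rows],
                "T": [r.T for r in self.rows],
                "e_hat": [r.e_hat for r in self.rows],
                "e_lo": [r.e_lo for r in self.rows],
                "e_hi": [r.e_hi for r in self.rows],
            }
        )


# ---------------------------------------------------------------------------
# registry record I/O


def _parse_date(raw: str, animal_id: str, column: str, warnings: list[str]) -> Optional[date]:
    raw = (raw or "").strip()
    if not raw:
        return None
    try:
        return date.fromisoformat(raw)
    except ValueError:
        warnings.append(f"{animal_id}: unparseable {column} {raw!r} treated as absent")
        return None


def _parse_enum(cls, raw: str, default):
    raw = (raw or "").strip().lower()
    if not raw:
        return default
    try:
        return cls(raw)
    except ValueError:
        return default


def _parse_bool(raw: str) -> Optional[bool]:
    raw = (raw or "").strip().lower()
    if raw in ("true", "1", "yes"):
        return True
    if raw in ("false", "0", "no"):
        return False
    return None


def read_records(
    path: str | Path, dialect: Optional[Mapping[str, str]] = None
) -> list[DeathRecord]:
    """Read a registry CSV into :class:`DeathRecord` objects.

    ``dialect`` optionally maps canonical field names to the file's column
    names; the canonical header is used as-is when omitted.  Dates must be
    ISO-8601; an unparseable date becomes an absent date with a logged
    warning rather than an error (cleaning decides what to do with it).

    Raises
    ------
    ConfigurationError
        if a mandatory column cannot be resolved.
    DataError
        if animal ids are duplicated.
    """
    colmap = {c: c for c in CANONICAL_COLUMNS}
    if dialect:
        colmap.update(dialect)

    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        header = reader.fieldnames or []
        for canonical in MANDATORY_COLUMNS:
            if colmap[canonical] not in header:
                raise ConfigurationError(
                    f"mandatory column {colmap[canonical]!r} (field {canonical}) "
                    f"missing from {path}"
                )
        warnings: list[str] = []
        records: list[DeathRecord] = []
        for row in reader:
            get = lambda k: row.get(colmap[k], "") or ""
            animal_id = get("animal_id").strip()
            records.append(
                DeathRecord(
                    animal_id=animal_id,
                    breed=get("breed").strip(),
                    sex=_parse_enum(Sex, get("sex"), Sex.UNKNOWN),
                    neuter_status=_parse_enum(
                        NeuterStatus, get("neuter_status"), NeuterStatus.UNKNOWN
                    ),
                    birth_date=_parse_date(get("birth_date"), animal_id, "birth_date", warnings),
                    death_date=_parse_date(get("death_date"), animal_id, "death_date", warnings),
                    death_mechanism=_parse_enum(
                        DeathMechanism, get("death_mechanism"), DeathMechanism.UNRECORDED
                    ),
                    clinical_note=get("clinical_note"),
                    treatment_text=get("treatment_text"),
                    insured=_parse_bool(get("insured")),
                )
            )

    seen: dict[str, int] = {}
    for rec in records:
        seen[rec.animal_id] = seen.get(rec.animal_id, 0) + 1
    dupes = sorted(k for k, v in seen.items() if v > 1)
    if dupes:
        raise DataError(f"duplicate animal_id values: {dupes}")

    for w in warnings:
        log.warning(w)
    log.info("read %d records from %s (%d date warnings)", len(records), path, len(warnings))
    return records


def write_records(records: Iterable[DeathRecord], path: str | Path) -> None:
    """Write records in the canonical registry CSV dialect."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CANONICAL_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.animal_id,
                    r.breed,
                    r.sex.value,
                    r.neuter_status.value,
                    r.birth_date.isoformat() if r.birth_date else "",
                    r.death_date.isoformat() if r.death_date else "",
                    r.death_mechanism.value,
                    r.clinical_note,
                    r.treatment_text,
                    "" if r.insured is None else str(r.insured).lower(),
                ]
            )


# ---------------------------------------------------------------------------
# life-table I/O


def read_aggregate_table(
    path: str | Path,
    stratum: Optional[dict[str, str]] = None,
    check_tolerance: float = 0.02,
) -> LifeTable:
    """Rebuild a life table from an aggregate CSV of ``x_start, d, a_hat``.

    Derived columns (``l``, ``q_hat``, ``L``, ``T``, ``e_hat``), when present
    in the file, are compared against the recomputation and mismatches beyond
    ``check_tolerance`` are logged — published tables typically print rounded
    values, so small discrepancies are expected and tolerated.
    """
    from .lifetable import build_from_aggregates

    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        header = reader.fieldnames or []
        for col in ("x_start", "d", "a_hat"):
            if col not in header:
                raise ConfigurationError(f"aggregate table {path} missing column {col!r}")
        raw_rows = list(reader)

    xs = [int(r["x_start"]) for r in raw_rows]
    d = [int(r["d"]) for r in raw_rows]
    a = [float(r["a_hat"]) for r in raw_rows]
    if any(di < 0 for di in d):
        raise DataError(f"negative death count in {path}")
    if xs != list(range(xs[0], xs[0] + len(xs))):
        raise DataError(f"non-contiguous ages in {path}: {xs}")
    if xs[0] != 0:
        raise DataError(f"aggregate table must start at age 0, got {xs[0]}")

    table = build_from_aggregates(d, a, stratum=stratum)

    checkable = {"l": "l", "q_hat": "q_hat", "L": "L", "T": "T", "e_hat": "e_hat"}
    for col, attr in checkable.items():
        if col in header:
            for raw, row in zip(raw_rows, table.rows):
                if not (raw.get(col) or "").strip():
                    continue
                provided = float(raw[col])
                got = getattr(row, attr)
                if abs(provided - got) > check_tolerance * max(1.0, abs(provided)):
                    log.warning(
                        "%s: provided %s at age %d (%s) differs from recomputed %s",
                        path, col, row.x, provided, got,
                    )
    return table


def write_life_table(
    table: LifeTable,
    path: str | Path,
    kind: str = "data",
    header_comment: Optional[str] = None,
) -> None:
    """Write a life table to CSV.

    ``kind="data"`` keeps full floating-point precision; ``kind="report"``
    renders probabilities to 3 decimals and years to 2 decimals, matching how
    published tables are printed, so the file is directly comparable by eye.
    """
    if not table.rows:
        raise DataError("refusing to write a life table with no rows")
    if kind not in ("data", "report"):
        raise ConfigurationError(f"unknown rendering kind {kind!r}")

    def fmt_prob(v):
        if v is None:
            return ""
        return f"{v:.3f}" if kind == "report" else repr(float(v))

    def fmt_years(v):
        if v is None:
            return ""
        return f"{v:.2f}" if kind == "report" else repr(float(v))

    path = Path(path)
    with path.open("w", newline="") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(
            ["x_start", "x_end", "d", "l", "q_hat", "a_hat", "L", "T", "e_hat", "e_lo", "e_hi"]
        )
        for row in table.rows:
            is_open = row.x == table.final_open_start
            writer.writerow(
                [
                    row.x,
                    "" if is_open else row.x + 1,
                    row.d,
                    row.l,
                    fmt_prob(row.q_hat),
                    fmt_prob(row.a_hat) if not is_open else fmt_years(row.a_hat),
                    fmt_years(row.L),
                    fmt_years(row.T),
                    fmt_years(row.e_hat),
                    fmt_years(row.e_lo),
                    fmt_years(row.e_hi),
                ]
            )


def read_life_table(path: str | Path) -> LifeTable:
    """Read back a full-precision life-table CSV written by :func:`write_life_table`."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(row for row in fh if not row.startswith("#"))
        rows = []
        for r in reader:
            rows.append(
                LifeTableRow(
                    x=int(r["x_start"]),
                    d=int(r["d"]),
                    l=int(r["l"]),
                    q_hat=float(r["q_hat"]),
                    a_hat=float(r["a_hat"]) if r["a_hat"] else None,
                    L=float(r["L"]),
                    T=float(r["T"]),
                    e_hat=float(r["e_hat"]),
                    e_lo=float(r["e_lo"]) if r["e_lo"] else None,
                    e_hi=float(r["e_hi"]) if r["e_hi"] else None,
                )
            )
    if not rows:
        raise DataError(f"no rows in {path}")
    return LifeTable(
        stratum={},
        rows=rows,
        final_open_start=rows[-1].x,
        eligible=True,
        n_animals=rows[0].l,
    )


def reference_aggregates_path() -> Path:
    """Path of the packaged UK companion-dog aggregate fixture."""
    return Path(str(resources.files("dogyears.data") / "uk_dogs_overall.csv"))


def load_reference_aggregates() -> LifeTable:
    """The packaged overall UK companion-dog life table, rebuilt from its
    printed death counts and mean-fraction-lived columns."""
    return read_aggregate_table(reference_aggregates_path(), stratum={"overall": "all"})
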