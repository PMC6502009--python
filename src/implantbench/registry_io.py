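"""Reading, validation and derivation of analysis variables from a
procedure-level arthroplasty registry table.

The at-risk unit throughout is the *procedure* (one row per primary hip
replacement).  A prosthesis construct is the combination of femoral stem
brand, acetabular cup brand and bearing couple; brand strings are free text
and are normalised (whitespace collapsed, case-insensitive) before they are
used as grouping keys.

Follow-up is measured in years of 365.25 days from the primary operation.
Failure is the first linked surgical revision; death and the administrative
data-extract date censor follow-up.
"""

from __future__ import annotations

import csv
import datetime as dt
import enum
import re
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

#: days per year used for all date arithmetic (removes calendar ambiguity)
YEAR_DAYS = 365.25


class Bearing(str, enum.Enum):
    """Bearing couple of a construct (articulating material pair)."""

    MoP = "MoP"  # metal-on-polyethylene
    CoP = "CoP"  # ceramic-on-polyethylene
    CoC = "CoC"  # ceramic-on-ceramic
    MoM = "MoM"  # metal-on-metal (never analysed)
    OTHER = "other"


#: bearings retained by :func:`apply_exclusions`
ELIGIBLE_BEARINGS = frozenset({Bearing.MoP, Bearing.CoP, Bearing.CoC})

AGE_BANDS = ("<55", "55-75", ">75")

_WS_RUN = re.compile(r"\s+")


def normalise_brand(name: str) -> str:
    """Normalise a free-text brand string for use in a grouping key.

    Leading/trailing whitespace is stripped, internal runs of whitespace
    collapse to one space, and comparison is case-insensitive (casefold).
    """
    return _WS_RUN.sub(" ", name.strip()).casefold()


@dataclass(frozen=True, order=True)
class ConstructKey:
    """Identity of a prosthesis construct: stem brand, cup brand, bearing.

    Components are stored in normalised form so equality is exact string
    match after whitespace/case normalisation.
    """

    stem: str
    cup: str
    bearing: str

    @classmethod
    def of(cls, stem: str, cup: str, bearing: Bearing | str) -> "ConstructKey":
        b = bearing.value if isinstance(bearing, Bearing) else str(bearing)
        return cls(normalise_brand(stem), normalise_brand(cup), b)

    @property
    def label(self) -> str:
        """Display label in the registry-report convention ``bearing stem/cup``."""
        return f"{self.bearing} {self.stem}/{self.cup}"


@dataclass(frozen=True)
class ProcedureRecord:
    """One primary hip replacement procedure."""

    procedure_id: str
    gender: Optional[str]  # "M" / "F" / None when missing
    age_at_primary: Optional[int]
    stem_brand: str
    cup_brand: str
    bearing: Bearing
    primary_date: dt.date
    revision_date: Optional[dt.date] = None
    death_date: Optional[dt.date] = None
    mortality_traceable: bool = True

    @property
    def construct(self) -> ConstructKey:
        return ConstructKey.of(self.stem_brand, self.cup_brand, self.bearing)


@dataclass(frozen=True)
class EventTime:
    """Follow-up of one procedure: years since primary and revision status."""

    time: float  # years (365.25-day years), strictly positive
    event: bool  # True = revised at `time`, False = censored at `time`


class ZeroFollowUpError(ValueError):
    """Raised when a record's derived follow-up time is not positive."""


@dataclass(frozen=True)
class Stratum:
    """A gender x age-band cell (or a marginal, via ``"all"``)."""

    gender: str = "all"  # "M", "F" or "all"
    age_band: str = "all"  # "<55", "55-75", ">75" or "all"

    def __post_init__(self) -> None:
        if self.gender not in ("M", "F", "all"):
            raise ValueError(f"unknown gender filter {self.gender!r}")
        if self.age_band not in AGE_BANDS + ("all",):
            raise ValueError(f"unknown age band {self.age_band!r}")

    @property
    def label(self) -> str:
        g = {"M": "men", "F": "women", "all": "all"}[self.gender]
        return g if self.age_band == "all" else f"{g} {self.age_band}"


def default_strata() -> list[Stratum]:
    """The stratification grid the full analysis runs: overall, each gender,
    and each gender x age band."""
    out = [Stratum("all", "all"), Stratum("M", "all"), Stratum("F", "all")]
    out += [Stratum(g, b) for g in ("M", "F") for b in AGE_BANDS]
    return out


def age_band_of(age: int) -> str:
    """Band an integer age.  The three bands partition the integers:
    ``<55`` is age <= 54, ``55-75`` is 55 <= age <= 75, ``>75`` is age >= 76.
    The boundary convention (75 belongs to the middle band) is a documented
    constant of this package."""
    if age <= 54:
        return "<55"
    if age <= 75:
        return "55-75"
    return ">75"


def stratify(record: ProcedureRecord, stratum: Stratum) -> bool:
    """Membership test of a record in a stratum (requires age and gender)."""
    if stratum.gender != "all" and record.gender != stratum.gender:
        return False
    if stratum.age_band != "all":
        if record.age_at_primary is None:
            return False
        return age_band_of(record.age_at_primary) == stratum.age_band
    return True


# ---------------------------------------------------------------------------
# CSV input

DEFAULT_SCHEMA: Mapping[str, str] = {
    "procedure_id": "procedure_id",
    "gender": "gender",
    "age": "age",
    "stem": "stem",
    "cup": "cup",
    "bearing": "bearing",
    "primary_date": "primary_date",
    "revision_date": "revision_date",
    "death_date": "death_date",
    "traceable": "traceable",
}

_MANDATORY = ("procedure_id", "gender", "age", "stem", "cup", "bearing",
              "primary_date")

_BEARING_ALIASES = {
    "mop": Bearing.MoP,
    "cop": Bearing.CoP,
    "coc": Bearing.CoC,
    "mom": Bearing.MoM,
}


class SchemaError(ValueError):
    """A mandatory column is missing from the input table."""


@dataclass(frozen=True)
class RowIssue:
    """A per-row validation problem surfaced by :func:`read_registry`."""

    row: int  # 1-based data-row number (header excluded)
    field: str
    message: str
    fatal: bool  # fatal issues exclude the record from the output


@dataclass
class ReadResult:
    records: list[ProcedureRecord]
    issues: list[RowIssue]

    @property
    def warnings(self) -> list[RowIssue]:
        return [i for i in self.issues if not i.fatal]


def _parse_date(raw: str) -> Optional[dt.date]:
    if raw == "":
        return None
    return dt.date.fromisoformat(raw)


def read_registry(path: str | Path,
                  schema: Optional[Mapping[str, str]] = None) -> ReadResult:
    """Read a procedure-level registry CSV into :class:`ProcedureRecord`s.

    ``schema`` maps logical field names (the keys of ``DEFAULT_SCHEMA``) to
    the column names used in the file; unknown extra columns are ignored.
    Dates are ISO-8601 and the empty string means missing.  Rows violating a
    record invariant (revision or death before the primary, negative age,
    unparseable date) are excluded and reported with their row number;
    unknown bearing strings are mapped to ``other`` with a warning so the
    exclusion tally can count them.
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for logical in _MANDATORY:
        if colmap[logical] not in df.columns:
            raise SchemaError(f"missing mandatory column {colmap[logical]!r} "
                              f"(field {logical!r})")

    def col(logical: str, row: Mapping[str, str]) -> str:
        name = colmap[logical]
        return row.get(name, "").strip()

    records: list[ProcedureRecord] = []
    issues: list[RowIssue] = []
    for i, row in enumerate(df.to_dict(orient="records"), start=1):
        fatal = False

        def issue(field: str, msg: str, is_fatal: bool) -> None:
            nonlocal fatal
            issues.append(RowIssue(i, field, msg, is_fatal))
            fatal = fatal or is_fatal

        raw_bearing = col("bearing", row)
        bearing = _BEARING_ALIASES.get(raw_bearing.casefold())
        if bearing is None:
            bearing = Bearing.OTHER
            if raw_bearing:
                issue("bearing", f"unknown bearing {raw_bearing!r}", False)

        gender = col("gender", row).upper() or None
        if gender not in ("M", "F", None):
            issue("gender", f"unknown gender {gender!r}", False)
            gender = None

        age: Optional[int] = None
        raw_age = col("age", row)
        if raw_age:
            try:
                age = int(raw_age)
            except ValueError:
                issue("age", f"unparseable age {raw_age!r}", False)
            else:
                if age < 0:
                    issue("age", f"negative age {age}", True)

        dates: dict[str, Optional[dt.date]] = {}
        for field in ("primary_date", "revision_date", "death_date"):
            try:
                dates[field] = _parse_date(col(field, row))
            except ValueError:
                issue(field, f"unparseable date {col(field, row)!r}", True)
                dates[field] = None
        if dates["primary_date"] is None and not fatal:
            issue("primary_date", "missing primary date", True)

        primary = dates["primary_date"]
        if primary is not None:
            for field in ("revision_date", "death_date"):
                d = dates[field]
                if d is not None and d < primary:
                    issue(field, f"{field} precedes primary date", True)

        if fatal:
            continue
        traceable_raw = col("traceable", row).casefold()
        traceable = traceable_raw not in ("0", "false", "no", "n")
        records.append(ProcedureRecord(
            procedure_id=col("procedure_id", row),
            gender=gender,
            age_at_primary=age,
            stem_brand=col("stem", row),
            cup_brand=col("cup", row),
            bearing=bearing,
            primary_date=primary,  # type: ignore[arg-type]
            revision_date=dates["revision_date"],
            death_date=dates["death_date"],
            mortality_traceable=traceable,
        ))
    return ReadResult(records, issues)


# ---------------------------------------------------------------------------
# Exclusions

#: fixed precedence of exclusion reasons so each record is tallied once
EXCLUSION_REASONS = ("non-eligible bearing", "missing age/gender",
                     "untraceable mortality")


def apply_exclusions(
        records: Iterable[ProcedureRecord],
) -> tuple[list[ProcedureRecord], Counter]:
    """Apply the cohort eligibility rules.

    Retains procedures with a MoP, CoP or CoC bearing, complete age and
    gender, and traceable mortality.  Metal-on-metal and other bearings are
    dropped first; then missing age/gender; then untraceable mortality —
    each record counts toward exactly one reason, in that order.
    """
    tally: Counter = Counter({r: 0 for r in EXCLUSION_REASONS})
    kept: list[ProcedureRecord] = []
    for rec in records:
        if rec.bearing not in ELIGIBLE_BEARINGS:
            tally["non-eligible bearing"] += 1
        elif rec.age_at_primary is None or rec.gender is None:
            tally["missing age/gender"] += 1
        elif not rec.mortality_traceable:
            tally["untraceable mortality"] += 1
        else:
            kept.append(rec)
    return kept, tally


def write_exclusion_tally(tally: Mapping[str, int], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["reason", "count"])
        for reason in EXCLUSION_REASONS:
            w.writerow([reason, tally.get(reason, 0)])


# ---------------------------------------------------------------------------
# Event-time derivation

def derive_event_time(record: ProcedureRecord,
                      admin_censor_date: dt.date) -> EventTime:
    """Derive the analysis event time of one retained procedure.

    The first linked revision is the failure event; follow-up without a
    revision is censored at death or at the administrative censoring date,
    whichever is earlier.  A revision recorded on the same date as death
    counts as a revision.  Times are (days since primary) / 365.25.

    Raises :class:`ZeroFollowUpError` when the derived time is not
    positive (same-day outcomes or a primary after the extract date).
    """
    censor = admin_censor_date
    if record.death_date is not None and record.death_date < censor:
        censor = record.death_date
    if record.revision_date is not None and record.revision_date <= censor:
        end, event = record.revision_date, True
    else:
        end, event = censor, False
    days = (end - record.primary_date).days
    if days <= 0:
        raise ZeroFollowUpError(
            f"procedure {record.procedure_id}: zero follow-up")
    return EventTime(days / YEAR_DAYS, event)


def build_event_table(records: Sequence[ProcedureRecord],
                      admin_censor_date: dt.date) -> pd.DataFrame:
    """Derive event times for a cohort and return one analysis row per
    procedure with the grouping variables downstream stages need.

    Records with zero follow-up are dropped (their count is in the
    ``attrs["n_zero_followup"]`` of the returned frame).
    """
    rows = []
    n_zero = 0
    for rec in records:
        try:
            et = derive_event_time(rec, admin_censor_date)
        except ZeroFollowUpError:
            n_zero += 1
            continue
        key = rec.construct
        rows.append((rec.procedure_id, rec.gender, rec.age_at_primary,
                     age_band_of(rec.age_at_primary)
                     if rec.age_at_primary is not None else None,
                     key.stem, key.cup, key.bearing, et.time, et.event))
    df = pd.DataFrame(rows, columns=[
        "procedure_id", "gender", "age", "age_band",
        "stem", "cup", "bearing", "time", "event"])
    df.attrs["n_zero_followup"] = n_zero
    return df


def write_registry_csv(records: Iterable[ProcedureRecord],
                       path: str | Path) -> None:
    """Write records in the default CSV dialect (the inverse of
    :func:`read_registry` with the default schema)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(list(DEFAULT_SCHEMA.values()))
        for r in records:
            w.writerow([
                r.procedure_id,
                r.gender or "",
                "" if r.age_at_primary is None else r.age_at_primary,
                r.stem_brand,
                r.cup_brand,
                r.bearing.value,
                r.primary_date.isoformat(),
                r.revision_date.isoformat() if r.revision_date else "",
                r.death_date.isoformat() if r.death_date else "",
                "1" if r.mortality_traceable else "0",
            ])
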