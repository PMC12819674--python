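"""Reading and assembling FAERS-style quarterly report tables.

The quarterly release dialect is four ``$``-delimited ASCII tables with
one header row: DEMO (one row per report version), DRUG, REAC and THER
(one row per drug / reaction / therapy episode). A *case* (CASEID) can
appear as several report versions (PRIMARYID); deduplication keeps, per
CASEID, the version with the latest FDA receipt date, breaking ties by
the highest PRIMARYID. Target-drug reports are those listing a matching
drug in the primary-suspect (PS) role.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from pvsignals.meddra import normalize_term

__all__ = [
    "AGE_TO_YEARS",
    "WEIGHT_TO_KG",
    "IngestError",
    "ProcessingLog",
    "QuarterlyFiles",
    "QuarterTables",
    "RawRecord",
    "ReportRecord",
    "assemble_reports",
    "deduplicate",
    "filter_primary_suspect",
    "read_quarter",
]

# Unit conversion factors to canonical years / kilograms.
AGE_TO_YEARS = {
    "YR": 1.0,
    "DEC": 10.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.18,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}
WEIGHT_TO_KG = {"KG": 1.0, "KGS": 1.0, "LBS": 0.453592, "GMS": 0.001}

_DEMO_COLS = ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE", "AGE_COD",
              "SEX", "WT", "WT_COD", "OCCP_COD"]
_DRUG_COLS = ["PRIMARYID", "CASEID", "DRUGNAME", "ROLE_COD"]
_REAC_COLS = ["PRIMARYID", "CASEID", "PT"]
_THER_COLS = ["PRIMARYID", "CASEID", "START_DT"]

SUSPECT_ROLES = ("PS", "SS")


class IngestError(ValueError):
    """Raised for unreadable files or malformed headers/rows."""


@dataclass(frozen=True)
class QuarterlyFiles:
    """Locations of the four tables making up one quarterly release."""

    demo_path: Path
    drug_path: Path
    reac_path: Path
    ther_path: Path
    quarter_label: str = ""


@dataclass
class QuarterTables:
    """Parsed tables of one quarter, demographics in canonical units."""

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    quarter_label: str = ""


@dataclass
class RawRecord:
    """One report version from DEMO, before table joins."""

    primaryid: str
    caseid: str
    fda_dt: int | None
    event_dt: int | None
    sex: str | None
    age_years: float | None
    weight_kg: float | None
    reporter_code: str | None


@dataclass
class ReportRecord(RawRecord):
    """A fully assembled report: demographics plus drugs and reactions."""

    drugs: list[tuple[str, str]] = field(default_factory=list)
    pts: set[str] = field(default_factory=set)
    therapy_start_dt: int | None = None
    is_target: bool = False


@dataclass
class ProcessingLog:
    """Per-stage record counts, writable as a processing-log CSV."""

    rows: list[tuple[str, int, int]] = field(default_factory=list)

    def add(self, stage: str, records_in: int, records_out: int) -> None:
        self.rows.append((stage, records_in, records_out))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=["stage", "records_in", "records_out"])

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


# ---------------------------------------------------------------------------
# parsing


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not Path(path).exists():
        raise IngestError(f"{path}: file not found")
    try:
        df = pd.read_csv(path, sep="$", dtype=str, keep_default_na=False,
                         engine="python")
    except Exception as exc:  # pandas raises several parser error types
        raise IngestError(f"{path}: unparseable ({exc})") from exc
    df.columns = [c.strip().upper() for c in df.columns]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise IngestError(f"{path}: missing required columns {missing}")
    return df


def _to_int(value: str) -> int | None:
    value = value.strip()
    if not value:
        return None
    try:
        return int(value)
    except ValueError:
        return None


def _convert_units(df: pd.DataFrame, value_col: str, unit_col: str,
                   factors: dict[str, float], out_col: str, path: Path) -> None:
    def conv(row) -> float | None:
        raw = row[value_col].strip()
        if not raw:
            return None
        unit = row[unit_col].strip().upper() or ("YR" if value_col == "AGE" else "KG")
        if unit not in factors:
            raise IngestError(
                f"{path}: row {row.name + 2}: unknown {unit_col} code {unit!r}")
        try:
            return float(raw) * factors[unit]
        except ValueError as exc:
            raise IngestError(
                f"{path}: row {row.name + 2}: non-numeric {value_col} {raw!r}") from exc

    df[out_col] = df.apply(conv, axis=1) if len(df) else None


def read_quarter(files: QuarterlyFiles) -> QuarterTables:
    """Parse one quarterly release into DataFrames with canonical units.

    Empty fields become missing values; AGE is converted to years from
    AGE_COD and WT to kilograms from WT_COD. Unknown unit codes and
    non-numeric values raise :class:`IngestError` with the file and
    (1-based, header-inclusive) row number.
    """
    demo = _read_table(Path(files.demo_path), _DEMO_COLS)
    drug = _read_table(Path(files.drug_path), _DRUG_COLS)
    reac = _read_table(Path(files.reac_path), _REAC_COLS)
    ther = _read_table(Path(files.ther_path), _THER_COLS)
    _convert_units(demo, "AGE", "AGE_COD", AGE_TO_YEARS, "AGE_YEARS", Path(files.demo_path))
    _convert_units(demo, "WT", "WT_COD", WEIGHT_TO_KG, "WEIGHT_KG", Path(files.demo_path))
    return QuarterTables(demo=demo, drug=drug, reac=reac, ther=ther,
                         quarter_label=files.quarter_label)


def _none_if_nan(value) -> float | None:
    if value is None or pd.isna(value):
        return None
    return float(value)


def _records_from_demo(demo: pd.DataFrame) -> list[RawRecord]:
    records = []
    for _, row in demo.iterrows():
        records.append(RawRecord(
            primaryid=row["PRIMARYID"].strip(),
            caseid=row["CASEID"].strip(),
            fda_dt=_to_int(row["FDA_DT"]),
            event_dt=_to_int(row["EVENT_DT"]),
            sex=row["SEX"].strip() or None,
            age_years=_none_if_nan(row.get("AGE_YEARS")),
            weight_kg=_none_if_nan(row.get("WEIGHT_KG")),
            reporter_code=row["OCCP_COD"].strip() or None,
        ))
    return records


# ---------------------------------------------------------------------------
# deduplication and suspect filtering


def _primaryid_key(primaryid: str):
    # numeric comparison when possible; lexicographic fallback for
    # non-numeric synthetic identifiers
    try:
        return (1, int(primaryid), "")
    except ValueError:
        return (0, 0, primaryid)


def _dedup_key(r: RawRecord):
    # missing FDA date sorts below any real date: a dated version wins
    fda = r.fda_dt if r.fda_dt is not None else -1
    return (fda, _primaryid_key(r.primaryid))


def deduplicate(records: Sequence[RawRecord]) -> list[RawRecord]:
    """Keep one report version per CASEID.

    Selection is the maximum by (FDA date, then PRIMARYID compared
    numerically); a version with a date always beats one without. The
    result is independent of input order and idempotent, returned in
    first-seen CASEID order.
    """
    best: dict[str, RawRecord] = {}
    order: list[str] = []
    for r in records:
        cur = best.get(r.caseid)
        if cur is None:
            best[r.caseid] = r
            order.append(r.caseid)
        elif _dedup_key(r) > _dedup_key(cur):
            best[r.caseid] = r
    return [best[c] for c in order]


def _matches(name: str, patterns: Sequence[str]) -> bool:
    norm = normalize_term(name)
    return any(normalize_term(p) in norm for p in patterns)


def filter_primary_suspect(reports: Sequence[ReportRecord],
                           name_patterns: Sequence[str]) -> list[ReportRecord]:
    """Reports listing a matching drug in the primary-suspect role.

    Matching is substring-based on the normalized (uppercased,
    whitespace-collapsed) drug name: FAERS DRUGNAME is free text, so
    exact matching would miss brand-name variants.
    """
    if not name_patterns:
        raise ValueError("name_patterns must be non-empty")
    return [r for r in reports
            if any(role == "PS" and _matches(name, name_patterns)
                   for name, role in r.drugs)]


# ---------------------------------------------------------------------------
# assembly


def assemble_reports(quarters: Iterable[QuarterTables] | QuarterTables,
                     name_patterns: Sequence[str],
                     log: ProcessingLog | None = None) -> list[ReportRecord]:
    """Join the four tables into labelled, deduplicated reports.

    Deduplication runs on the full corpus *before* target-drug
    selection, mirroring the corpus-then-extraction order of a real
    quarterly workflow. The returned list is the complete deduplicated
    corpus — target and background — with ``is_target`` marking the
    reports carrying a pattern-matching primary-suspect drug, so that
    disproportionality denominators can be formed downstream. Reports
    with no reaction rows are dropped and counted in the log.
    """
    if isinstance(quarters, QuarterTables):
        quarters = [quarters]
    quarters = list(quarters)
    log = log if log is not None else ProcessingLog()

    demo = pd.concat([q.demo for q in quarters], ignore_index=True)
    drug = pd.concat([q.drug for q in quarters], ignore_index=True)
    reac = pd.concat([q.reac for q in quarters], ignore_index=True)
    ther = pd.concat([q.ther for q in quarters], ignore_index=True)

    raw = _records_from_demo(demo)
    log.add("raw", len(raw), len(raw))
    kept = deduplicate(raw)
    log.add("deduplicate", len(raw), len(kept))

    drugs_by_pid: dict[str, list[tuple[str, str]]] = {}
    for _, row in drug.iterrows():
        drugs_by_pid.setdefault(row["PRIMARYID"].strip(), []).append(
            (row["DRUGNAME"].strip(), row["ROLE_COD"].strip()))
    pts_by_pid: dict[str, set[str]] = {}
    for _, row in reac.iterrows():
        pt = row["PT"].strip()
        if pt:
            pts_by_pid.setdefault(row["PRIMARYID"].strip(), set()).add(pt)
    ther_by_pid: dict[str, list[int]] = {}
    for _, row in ther.iterrows():
        start = _to_int(row["START_DT"])
        if start is not None:
            ther_by_pid.setdefault(row["PRIMARYID"].strip(), []).append(start)

    reports: list[ReportRecord] = []
    n_no_pts = 0
    for r in kept:
        pts = pts_by_pid.get(r.primaryid, set())
        if not pts:
            n_no_pts += 1
            continue
        drugs = drugs_by_pid.get(r.primaryid, [])
        starts = ther_by_pid.get(r.primaryid, [])
        reports.append(ReportRecord(
            primaryid=r.primaryid, caseid=r.caseid, fda_dt=r.fda_dt,
            event_dt=r.event_dt, sex=r.sex, age_years=r.age_years,
            weight_kg=r.weight_kg, reporter_code=r.reporter_code,
            drugs=drugs, pts=pts, therapy_start_dt=min(starts) if starts else None,
        ))
    log.add("drop_zero_pt", len(kept), len(reports))

    targets = filter_primary_suspect(reports, name_patterns)
    target_ids = {r.primaryid for r in targets}
    for r in reports:
        r.is_target = r.primaryid in target_ids
    log.add("primary_suspect_label", len(reports), len(target_ids))
    return reports
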