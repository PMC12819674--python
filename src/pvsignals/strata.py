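"""Subgroup stratification and the co-medication sensitivity analysis.

Subgroup analysis repeats the disproportionality analysis within strata
of sex, age, body weight, or reporter type, with both the target and
background arms restricted to the stratum. Age and weight bins are
left-closed, right-open (so age 18.0 falls in the 18-65 bin); reports
missing the stratifying variable fall into an implicit "missing" bin
that is reported but not signal-tested by default.

The sensitivity analysis re-runs the full pipeline after excluding
reports that carry a common co-medication — either in a non-primary
role or as an additional primary-suspect drug next to the target.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

from pvsignals.ingest import ReportRecord
from pvsignals.meddra import normalize_term
from pvsignals.synthetic import DEFAULT_CO_DRUGS

__all__ = ["StratumSpec", "MISSING_BIN", "age_spec", "reporter_spec",
           "sensitivity_exclude", "sex_spec", "stratify", "weight_spec"]

MISSING_BIN = "missing"

HEALTHCARE_ROLES = {"MD", "PH", "HP"}
NON_HEALTHCARE_ROLES = {"CN", "LW", "OT"}


@dataclass(frozen=True)
class StratumSpec:
    """An ordered set of mutually exclusive bins over reports."""

    dimension: str
    bins: tuple[tuple[str, Callable[[ReportRecord], bool]], ...]


def _range_bins(attr: str, edges: Sequence[float], labels: Sequence[str]):
    def make(lo: float | None, hi: float | None):
        def pred(r: ReportRecord) -> bool:
            v = getattr(r, attr)
            if v is None:
                return False
            return (lo is None or v >= lo) and (hi is None or v < hi)
        return pred

    bounds = [None, *edges, None]
    return tuple((labels[i], make(bounds[i], bounds[i + 1])) for i in range(len(labels)))


def sex_spec() -> StratumSpec:
    return StratumSpec("sex", (
        ("F", lambda r: r.sex == "F"),
        ("M", lambda r: r.sex == "M"),
    ))


def age_spec(edges: Sequence[float] = (18, 65, 85)) -> StratumSpec:
    labels = ["<18", "18-65", "65-85", ">85"]
    return StratumSpec("age", _range_bins("age_years", edges, labels))


def weight_spec(edges: Sequence[float] = (50, 100)) -> StratumSpec:
    labels = ["<50 kg", "50-100 kg", ">100 kg"]
    return StratumSpec("weight", _range_bins("weight_kg", edges, labels))


def reporter_spec() -> StratumSpec:
    return StratumSpec("reporter", (
        ("healthcare", lambda r: r.reporter_code in HEALTHCARE_ROLES),
        ("non-healthcare", lambda r: r.reporter_code in NON_HEALTHCARE_ROLES),
    ))


def stratify(reports: Sequence[ReportRecord],
             spec: StratumSpec) -> dict[str, list[ReportRecord]]:
    """Partition reports into the spec's bins plus the "missing" bin.

    A report matching more than one bin means the spec's predicates
    overlap and raises; a report matching none goes to "missing". The
    union of the returned subsets is exactly the input.
    """
    out: dict[str, list[ReportRecord]] = {label: [] for label, _ in spec.bins}
    out[MISSING_BIN] = []
    for r in reports:
        matches = [label for label, pred in spec.bins if pred(r)]
        if len(matches) > 1:
            raise ValueError(
                f"overlapping bins {matches} in stratum spec {spec.dimension!r} "
                f"for report {r.primaryid}")
        out[matches[0] if matches else MISSING_BIN].append(r)
    return out


def _matches_any(name: str, patterns: Sequence[str]) -> bool:
    norm = normalize_term(name)
    return any(normalize_term(p) in norm for p in patterns)


def sensitivity_exclude(reports: Sequence[ReportRecord],
                        co_drug_patterns: Sequence[str] = DEFAULT_CO_DRUGS,
                        ) -> list[ReportRecord]:
    """Drop reports carrying a listed co-medication.

    A report is excluded when any of its drugs matches a pattern in a
    non-primary-suspect role, or matches as a second primary-suspect
    drug alongside the target. The retained subset re-enters the full
    signal pipeline unchanged.
    """
    if not co_drug_patterns:
        raise ValueError("co_drug_patterns must be non-empty")
    kept = []
    for r in reports:
        n_ps = sum(1 for _name, role in r.drugs if role == "PS")
        drop = False
        for name, role in r.drugs:
            if not _matches_any(name, co_drug_patterns):
                continue
            if role != "PS" or n_ps > 1:
                drop = True
                break
        if not drop:
            kept.append(r)
    return kept
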