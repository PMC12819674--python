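"""Synthetic FAERS-like corpora with known ground truth.

The generator emulates the features of a quarterly spontaneous-report
release that the downstream pipeline has to cope with: multi-drug
multi-event reports with a primary-suspect role code, case-version
duplicates sharing a CASEID, heavy demographic missingness (defaults
follow a large real-world corpus: 44.3% missing age, 60.1% missing
weight), configurable injected drug-event relative reporting rates, and
Weibull-distributed onset times encoded as therapy-start and event
dates. A ground-truth sidecar records the injected rates and, per
CASEID, which report version deduplication must keep, so every stage is
testable without external data.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from pvsignals.ingest import QuarterlyFiles
from pvsignals.meddra import normalize_term

__all__ = ["SyntheticConfig", "SyntheticCase", "generate_cases",
           "generate_dataset", "inject_duplicates", "default_pt_list"]

#: Co-medications commonly reported alongside immunoglobulin therapy;
#: the default exclusion list of the sensitivity analysis.
DEFAULT_CO_DRUGS = (
    "HIZENTRA",
    "DIPHENHYDRAMINE",
    "ACETAMINOPHEN",
    "GAMMAGARD LIQUID",
    "HUMAN IMMUNOGLOBULIN G",
)


def default_pt_list() -> list[str]:
    """Preferred terms of the bundled SOC mapping, in file order."""
    from importlib import resources
    with resources.as_file(resources.files("pvsignals").joinpath("data/pt_soc.csv")) as p:
        return pd.read_csv(p, dtype=str)["pt"].tolist()


@dataclass(frozen=True)
class SyntheticConfig:
    """Knobs of the synthetic corpus; defaults are the study conditions.

    ``signal_table`` maps (drug, PT) pairs to a relative reporting rate
    rho; pairs not listed default to rho = 1 (no signal). For a report
    whose primary-suspect drug is ``drug``, each listed PT occurs with
    probability ``min(1, rho * background_event_rate)`` instead of the
    background rate. Onset times are Weibull(shape, scale) in days;
    the defaults are the early-failure regime reported for intravenous
    immunoglobulin (shape 0.47, scale 189.41 days).
    """

    n_cases: int = 5000
    n_drugs: int = 20
    n_pts: int = 40
    target_drug: str = "IVIG"
    signal_table: dict[tuple[str, str], float] = field(default_factory=dict)
    background_event_rate: float = 0.04
    duplicate_rate: float = 0.0
    missing_age: float = 0.443
    missing_weight: float = 0.601
    missing_sex: float = 0.092
    onset_shape: float = 0.47
    onset_scale: float = 189.41
    target_fraction: float = 0.3
    comed_rate: float = 0.0
    comed_drugs: tuple[str, ...] = DEFAULT_CO_DRUGS
    n_quarters: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_cases", "n_drugs", "n_pts", "n_quarters"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("missing_age", "missing_weight", "missing_sex",
                     "background_event_rate", "target_fraction", "comed_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 <= self.duplicate_rate < 1.0):
            raise ValueError(f"duplicate_rate must lie in [0, 1), got {self.duplicate_rate}")
        for name in ("onset_shape", "onset_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for (drug, pt), rho in self.signal_table.items():
            if rho < 0:
                raise ValueError(f"signal_table rho for ({drug}, {pt}) must be >= 0")


@dataclass
class SyntheticCase:
    """One report version, pre-serialization."""

    primaryid: int
    caseid: int
    fda_dt: int
    event_dt: int
    start_dt: int
    age: float | None
    sex: str | None
    weight: float | None
    occp: str
    drugs: list[tuple[str, str]]
    pts: list[str]
    is_keep: bool = True  # ground truth: the version dedup must retain


_EPOCH = dt.date(2004, 1, 1)
_LAST_START = dt.date(2023, 6, 30)


def _to_yyyymmdd(d: dt.date) -> int:
    return d.year * 10000 + d.month * 100 + d.day


def _from_ordinal(o: int) -> dt.date:
    return dt.date.fromordinal(o)


def generate_cases(config: SyntheticConfig) -> list[SyntheticCase]:
    """Draw the base (duplicate-free) corpus from the config."""
    rng = np.random.default_rng(config.seed)
    drug_names = [f"DRUG{i:03d}" for i in range(1, config.n_drugs + 1)]
    pt_pool = default_pt_list()
    if config.n_pts > len(pt_pool):
        pt_pool = pt_pool + [f"SYNTHETIC PT {k}" for k in range(config.n_pts - len(pt_pool))]
    pts = pt_pool[: config.n_pts]
    rho = {(normalize_term(d), normalize_term(p)): r
           for (d, p), r in config.signal_table.items()}

    start_lo, start_hi = _EPOCH.toordinal(), _LAST_START.toordinal()
    cases: list[SyntheticCase] = []
    for i in range(config.n_cases):
        caseid = 10_000_000 + i
        primaryid = caseid * 10 + 1
        is_target = rng.random() < config.target_fraction
        primary = config.target_drug if is_target else str(rng.choice(drug_names))
        drugs = [(primary, "PS")]
        for _ in range(int(rng.integers(0, 3))):
            extra = str(rng.choice(drug_names))
            if extra != primary:
                drugs.append((extra, "C"))
        if config.comed_rate and rng.random() < config.comed_rate:
            drugs.append((str(rng.choice(np.array(config.comed_drugs))), "C"))

        pkey = normalize_term(primary)
        probs = np.full(len(pts), config.background_event_rate)
        for j, p in enumerate(pts):
            r = rho.get((pkey, normalize_term(p)))
            if r is not None:
                probs[j] = min(1.0, r * config.background_event_rate)
        hits = rng.random(len(pts)) < probs
        case_pts = [p for p, h in zip(pts, hits) if h]
        if not case_pts:
            case_pts = [pts[int(rng.integers(0, len(pts)))]]

        start = _from_ordinal(int(rng.integers(start_lo, start_hi + 1)))
        onset = max(0, int(round(config.onset_scale * rng.weibull(config.onset_shape))))
        event = start + dt.timedelta(days=onset)
        fda = event + dt.timedelta(days=int(rng.integers(5, 120)))

        age = float(np.round(rng.uniform(1.0, 90.0), 0))
        if rng.random() < config.missing_age:
            age = None
        sex = "F" if rng.random() < 0.58 else "M"
        if rng.random() < config.missing_sex:
            sex = None
        weight = float(np.round(np.clip(rng.normal(75.0, 15.0), 30.0, 150.0), 1))
        if rng.random() < config.missing_weight:
            weight = None
        occp = str(rng.choice(["CN", "HP", "MD", "OT", "PH"],
                              p=[0.33, 0.21, 0.18, 0.15, 0.13]))

        cases.append(SyntheticCase(
            primaryid=primaryid, caseid=caseid,
            fda_dt=_to_yyyymmdd(fda), event_dt=_to_yyyymmdd(event),
            start_dt=_to_yyyymmdd(start), age=age, sex=sex, weight=weight,
            occp=occp, drugs=drugs, pts=case_pts))
    return cases


def inject_duplicates(cases: list[SyntheticCase], duplicate_rate: float,
                      seed: int) -> list[SyntheticCase]:
    """Add 1-3 extra report versions for a sampled fraction of cases.

    Extra versions share the CASEID, get distinct higher PRIMARYIDs and
    FDA dates at or after the original's. Exactly one member of each
    group keeps ``is_keep=True``: the one with the latest FDA date,
    ties broken by the highest PRIMARYID — the version the dedup rule
    must select.
    """
    if not (0.0 <= duplicate_rate < 1.0):
        raise ValueError(f"duplicate_rate must lie in [0, 1), got {duplicate_rate}")
    if duplicate_rate == 0.0:
        return list(cases)
    rng = np.random.default_rng(seed)
    out: list[SyntheticCase] = []
    for case in cases:
        group = [replace(case)]
        if rng.random() < duplicate_rate:
            fda = dt.date(case.fda_dt // 10000, case.fda_dt // 100 % 100, case.fda_dt % 100)
            for v in range(2, 2 + int(rng.integers(1, 4))):
                fda = fda + dt.timedelta(days=int(rng.integers(0, 60)))
                group.append(replace(case, primaryid=case.caseid * 10 + v,
                                     fda_dt=_to_yyyymmdd(fda)))
        keep = max(group, key=lambda c: (c.fda_dt, c.primaryid))
        for c in group:
            c.is_keep = c is keep
        out.extend(group)
    return out


def _blank(value) -> str:
    if value is None:
        return ""
    if isinstance(value, float) and value == int(value):
        return str(int(value))
    return str(value)


def generate_dataset(config: SyntheticConfig, out_dir: str | Path) -> list[QuarterlyFiles]:
    """Write a synthetic corpus in the FAERS ``$``-delimited dialect.

    Produces DEMO/DRUG/REAC/THER files per quarter plus two sidecars:
    ``ground_truth_keep.csv`` (the PRIMARYID dedup must keep per
    CASEID) and ``ground_truth_signals.csv`` (the injected rho per
    drug-PT pair). Identical config and seed give byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cases = generate_cases(config)
    cases = inject_duplicates(cases, config.duplicate_rate, config.seed + 1)

    year, q = 2024, 4
    quarters: list[QuarterlyFiles] = []
    by_quarter: dict[int, list[SyntheticCase]] = {i: [] for i in range(config.n_quarters)}
    for case in cases:
        by_quarter[case.caseid % config.n_quarters].append(case)

    labels = []
    for i in range(config.n_quarters):
        labels.append(f"{year}Q{q}")
        q -= 1
        if q == 0:
            year, q = year - 1, 4

    for i, label in enumerate(labels):
        chunk = by_quarter[i]
        demo_rows, drug_rows, reac_rows, ther_rows = [], [], [], []
        for c in chunk:
            demo_rows.append({
                "PRIMARYID": c.primaryid, "CASEID": c.caseid, "FDA_DT": c.fda_dt,
                "EVENT_DT": c.event_dt, "AGE": _blank(c.age),
                "AGE_COD": "YR" if c.age is not None else "",
                "SEX": _blank(c.sex), "WT": _blank(c.weight),
                "WT_COD": "KG" if c.weight is not None else "",
                "OCCP_COD": c.occp})
            for name, role in c.drugs:
                drug_rows.append({"PRIMARYID": c.primaryid, "CASEID": c.caseid,
                                  "DRUGNAME": name, "ROLE_COD": role})
            for pt in c.pts:
                reac_rows.append({"PRIMARYID": c.primaryid, "CASEID": c.caseid, "PT": pt})
            ther_rows.append({"PRIMARYID": c.primaryid, "CASEID": c.caseid,
                              "START_DT": c.start_dt})
        suffix = label.lower()
        paths = {}
        for name, rows, cols in (
                ("demo", demo_rows, ["PRIMARYID", "CASEID", "FDA_DT", "EVENT_DT", "AGE",
                                     "AGE_COD", "SEX", "WT", "WT_COD", "OCCP_COD"]),
                ("drug", drug_rows, ["PRIMARYID", "CASEID", "DRUGNAME", "ROLE_COD"]),
                ("reac", reac_rows, ["PRIMARYID", "CASEID", "PT"]),
                ("ther", ther_rows, ["PRIMARYID", "CASEID", "START_DT"])):
            path = out_dir / f"{name}_{suffix}.txt"
            pd.DataFrame(rows, columns=cols).to_csv(path, sep="$", index=False,
                                                    lineterminator="\n")
            paths[name] = path
        quarters.append(QuarterlyFiles(
            demo_path=paths["demo"], drug_path=paths["drug"],
            reac_path=paths["reac"], ther_path=paths["ther"], quarter_label=label))

    keep = pd.DataFrame(
        [{"CASEID": c.caseid, "KEEP_PRIMARYID": c.primaryid} for c in cases if c.is_keep])
    keep.sort_values("CASEID").to_csv(out_dir / "ground_truth_keep.csv", index=False)
    sig = pd.DataFrame(
        [{"DRUGNAME": d, "PT": p, "RHO": r} for (d, p), r in sorted(config.signal_table.items())],
        columns=["DRUGNAME", "PT", "RHO"])
    sig.to_csv(out_dir / "ground_truth_signals.csv", index=False)
    return quarters
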