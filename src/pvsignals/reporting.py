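"""Summary surfaces: demographics table, annual counts, ranked signals.

Percentages follow the display convention of regulatory summary
tables: round half-up to one decimal place, then render with two
decimals (58.03% of reports prints as "58.00%", 60.093% as "60.10%").
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, is_dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Sequence

import pandas as pd

from pvsignals.ingest import ReportRecord
from pvsignals.strata import age_spec, sex_spec, stratify, weight_spec

__all__ = ["annual_counts", "demographics_table", "percent_display", "rank_terms",
           "read_signal_csv", "write_manifest", "write_signal_csv"]


def percent_display(count: int, total: int) -> str:
    """Percentage string: half-up rounding to 1 decimal, 2-decimal display."""
    if total <= 0:
        raise ValueError("total must be positive")
    pct = Decimal(count) * 100 / Decimal(total)
    rounded = pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    return f"{rounded.quantize(Decimal('0.01'))}%"


def demographics_table(reports: Sequence[ReportRecord]) -> pd.DataFrame:
    """Counts and display percentages by sex, weight, age and reporter role.

    Per dimension, the bin counts (including the missing bin) sum to the
    corpus size. Raises on an empty corpus.
    """
    if not reports:
        raise ValueError("cannot summarise an empty corpus")
    n = len(reports)
    rows = [{"category": "Overall", "label": "Overall", "count": n,
             "percent_display": ""}]
    for spec in (sex_spec(), weight_spec(), age_spec()):
        for label, subset in stratify(reports, spec).items():
            rows.append({"category": spec.dimension, "label": label,
                         "count": len(subset),
                         "percent_display": percent_display(len(subset), n)})
    role_counts: dict[str, int] = {}
    for r in reports:
        role_counts[r.reporter_code or "missing"] = \
            role_counts.get(r.reporter_code or "missing", 0) + 1
    for label in sorted(role_counts):
        rows.append({"category": "role", "label": label, "count": role_counts[label],
                     "percent_display": percent_display(role_counts[label], n)})
    return pd.DataFrame(rows, columns=["category", "label", "count", "percent_display"])


def annual_counts(reports: Sequence[ReportRecord]) -> dict:
    """Reports per FDA-receipt year; missing dates counted as "unknown"."""
    out: dict = {}
    for r in reports:
        key = r.fda_dt // 10000 if r.fda_dt is not None else "unknown"
        out[key] = out.get(key, 0) + 1
    return dict(sorted(out.items(), key=lambda kv: (isinstance(kv[0], str), kv[0])))


def rank_terms(results: pd.DataFrame, by: str = "frequency",
               top_n: int | None = 50) -> pd.DataFrame:
    """Order a signal table by frequency or ROR, descending.

    Ties on the chosen key break by the other key (descending), then by
    term name; the result is truncated to ``top_n`` rows.
    """
    if results.empty:
        raise ValueError("results must be non-empty")
    keys = {"frequency": ["n_reports", "ROR"], "ror": ["ROR", "n_reports"]}
    if by not in keys:
        raise ValueError(f"unknown ranking key {by!r}; expected 'frequency' or 'ror'")
    primary, secondary = keys[by]
    ranked = results.sort_values([primary, secondary, "term"],
                                 ascending=[False, False, True], ignore_index=True)
    return ranked.head(top_n) if top_n is not None else ranked


def write_signal_csv(table: pd.DataFrame, path: str | Path,
                     decimals: int = 2) -> None:
    """Write a signal table, rounding numeric columns for display."""
    out = table.copy()
    for col in out.columns:
        if out[col].dtype.kind == "f":
            out[col] = out[col].round(decimals)
    out.to_csv(path, index=False)


def read_signal_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_manifest(out_dir: str | Path, config: object | dict | None,
                   seed: int | None) -> Path:
    """Record config hash, seed and versions so a run can be reproduced."""
    import numpy
    import scipy

    import pvsignals

    if is_dataclass(config) and not isinstance(config, type):
        cfg = asdict(config)
    else:
        cfg = config if isinstance(config, dict) else {}
    blob = json.dumps(cfg, sort_keys=True, default=str)
    manifest = {
        "config_sha256": hashlib.sha256(blob.encode()).hexdigest(),
        "seed": seed,
        "versions": {
            "pvsignals": pvsignals.__version__,
            "python": platform.python_version(),
            "numpy": numpy.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
    }
    path = Path(out_dir) / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2) + "\n")
    return path
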