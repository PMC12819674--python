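"""End-to-end drivers: corpus -> ranked signal tables.

These helpers wire the modules together the way a full analysis runs:
fit the MGPS prior once over all drug-event pairs of the corpus, then
evaluate every observed term at PT or SOC level against the target
drug, apply the combined all-four criterion and return a tidy table.
"""

from __future__ import annotations

from typing import Sequence

import pandas as pd

from pvsignals.ingest import ReportRecord
from pvsignals.meddra import MedDRAMap, UNMAPPED
from pvsignals.signal_stats import (
    GammaMixturePrior,
    Thresholds,
    build_all_tables,
    build_pair_tables,
    evaluate_signal,
    fit_prior,
)
from pvsignals.strata import StratumSpec, stratify, MISSING_BIN

__all__ = ["corpus_prior", "signal_table", "subgroup_signal_tables"]

SIGNAL_COLUMNS = ["term", "level", "n_reports", "ROR", "ROR95L", "ROR95U", "PRR",
                  "chi2", "IC", "IC025", "EBGM", "EBGM05", "ror_pos", "prr_pos",
                  "bcpnn_pos", "mgps_pos", "combined_pos"]


def corpus_prior(reports: Sequence[ReportRecord],
                 min_tables: int = 50) -> GammaMixturePrior:
    """Fit the MGPS mixture prior over every drug-event pair in the corpus."""
    return fit_prior(build_pair_tables(reports).values(), min_tables=min_tables)


def signal_table(reports: Sequence[ReportRecord], level: str = "PT",
                 mapping: MedDRAMap | None = None,
                 prior: GammaMixturePrior | None = None,
                 thresholds: Thresholds = Thresholds(),
                 drop_unmapped: bool = True,
                 include_no_event_term: bool = True) -> pd.DataFrame:
    """Evaluate all observed terms at one level and return a tidy table.

    ``reports`` is the labelled deduplicated corpus. When no prior is
    given one is fitted from the corpus itself (requires enough pairs).
    Rows are sorted by report count descending. The "No adverse event"
    PT is kept by default; ``include_no_event_term=False`` drops it.
    Values are full precision — rounding happens only at the reporting
    layer.
    """
    if prior is None:
        prior = corpus_prior(reports)
    tables = build_all_tables(reports, level=level, mapping=mapping)
    rows = []
    for term, tab in tables.items():
        if level == "SOC" and drop_unmapped and term == UNMAPPED:
            continue
        if not include_no_event_term and term.strip().upper() == "NO ADVERSE EVENT":
            continue
        res = evaluate_signal(tab, term, level=level, prior=prior, thresholds=thresholds)
        rows.append({
            "term": res.term, "level": res.level, "n_reports": res.a,
            "ROR": res.ror, "ROR95L": res.ror_lo, "ROR95U": res.ror_hi,
            "PRR": res.prr, "chi2": res.chi2, "IC": res.ic, "IC025": res.ic025,
            "EBGM": res.ebgm, "EBGM05": res.ebgm05,
            "ror_pos": res.ror_pos, "prr_pos": res.prr_pos,
            "bcpnn_pos": res.bcpnn_pos, "mgps_pos": res.mgps_pos,
            "combined_pos": res.combined_pos})
    df = pd.DataFrame(rows, columns=SIGNAL_COLUMNS)
    return df.sort_values(["n_reports", "term"], ascending=[False, True],
                          ignore_index=True)


def subgroup_signal_tables(reports: Sequence[ReportRecord], spec: StratumSpec,
                           level: str = "PT", mapping: MedDRAMap | None = None,
                           thresholds: Thresholds = Thresholds(),
                           min_tables: int = 50,
                           include_missing: bool = False,
                           ) -> dict[str, pd.DataFrame]:
    """Per-stratum signal tables, both arms restricted to the stratum.

    Each stratum gets its own prior fit; strata too small to support
    one (fewer pairs than ``min_tables``) are skipped. The missing bin
    is excluded by default.
    """
    out: dict[str, pd.DataFrame] = {}
    for label, subset in stratify(reports, spec).items():
        if label == MISSING_BIN and not include_missing:
            continue
        if not subset or not any(r.is_target for r in subset):
            continue
        try:
            out[label] = signal_table(subset, level=level, mapping=mapping,
                                      thresholds=thresholds)
        except ValueError:
            continue  # stratum too small for a prior fit
    return out
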