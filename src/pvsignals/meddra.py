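"""Preferred-term to system-organ-class mapping.

MedDRA is a licensed dictionary, so a small bundled table covering the
preferred terms used throughout the package's examples and synthetic
corpora stands in for it. Users with a MedDRA licence can supply a full
table in the same two-column CSV format (``pt,soc``). Only the primary
SOC of each PT is supported: each PT maps to exactly one SOC.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = ["MedDRAMap", "UNMAPPED", "default_mapping", "load_mapping", "normalize_term"]

UNMAPPED = "UNMAPPED"


def normalize_term(term: str) -> str:
    """Canonical lookup key: uppercase, trimmed, inner whitespace collapsed."""
    return " ".join(str(term).upper().split())


@dataclass
class MedDRAMap:
    """Case-insensitive PT -> primary SOC lookup with an unmapped counter."""

    pt_to_soc_map: dict[str, str]
    version_label: str = "toy"
    unmapped_seen: dict[str, int] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pt_to_soc_map)

    def pt_to_soc(self, pt: str) -> str:
        """Primary SOC for ``pt``, or the ``UNMAPPED`` sentinel.

        Unknown PTs are tallied in ``unmapped_seen`` so a run can report
        its dictionary coverage.
        """
        soc = self.pt_to_soc_map.get(normalize_term(pt))
        if soc is None:
            key = normalize_term(pt)
            self.unmapped_seen[key] = self.unmapped_seen.get(key, 0) + 1
            return UNMAPPED
        return soc

    def socs(self) -> list[str]:
        return sorted(set(self.pt_to_soc_map.values()))


def load_mapping(path: str | Path, version_label: str | None = None) -> MedDRAMap:
    """Load a two-column (pt, soc) CSV into a :class:`MedDRAMap`.

    Duplicate PT rows are allowed when they agree on the SOC; a PT
    appearing with two different SOCs is a conflict and raises.
    """
    df = pd.read_csv(path, dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["pt", "soc"]:
        raise ValueError(f"{path}: expected header columns 'pt,soc', got {list(df.columns)}")
    if df.empty:
        raise ValueError(f"{path}: mapping file contains no rows")
    mapping: dict[str, str] = {}
    for _, row in df.iterrows():
        key = normalize_term(row.iloc[0])
        soc = str(row.iloc[1]).strip()
        if key in mapping and mapping[key] != soc:
            raise ValueError(
                f"conflicting SOC for PT {row.iloc[0]!r}: {mapping[key]!r} vs {soc!r}")
        mapping[key] = soc
    label = version_label or Path(path).stem
    return MedDRAMap(pt_to_soc_map=mapping, version_label=label)


def default_mapping() -> MedDRAMap:
    """The bundled toy mapping (a small subset of MedDRA 27.1 primary SOCs)."""
    with resources.as_file(resources.files("pvsignals").joinpath("data/pt_soc.csv")) as p:
        return load_mapping(p, version_label="27.1-toy")
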