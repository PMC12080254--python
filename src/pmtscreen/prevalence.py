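"""MACCS-key occurrence proportions within compound subsets.

The prevalence table answers "which substructures recur among the screened
positives": for each MACCS key, the share of compounds in a subset whose
fingerprint sets the bit, sorted by occurrence count.  Strata (synthetic vs
natural/undefined origin) are compared by set difference on the top-k keys.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .features import (
    maccs_key_description,
    maccs_key_name,
    fingerprint_matrix,
    is_noncyclic,
)
from .io import CompoundRecord


@dataclass
class PrevalenceEntry:
    key_number: int
    key_name: str
    description: str
    count: int
    proportion: float  # exact percent, 0-100

    @property
    def proportion_display(self) -> int:
        """Integer percent for table display; exact value kept internally."""
        return round(self.proportion)


@dataclass
class PrevalenceTable:
    label: str
    size: int
    k: int
    entries: list[PrevalenceEntry]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "feature_number": [e.key_number for e in self.entries],
                "feature_name": [e.key_name for e in self.entries],
                "description": [e.description for e in self.entries],
                "count": [e.count for e in self.entries],
                "proportion_pct": [e.proportion for e in self.entries],
                "proportion_display": [e.proportion_display for e in self.entries],
            }
        )

    def to_markdown(self) -> str:
        lines = [
            f"### {self.label} (n = {self.size})",
            "",
            "| Feature number | Feature name | Description | Proportion |",
            "| --- | --- | --- | --- |",
        ]
        for e in self.entries:
            lines.append(
                f"| {e.key_number} | {e.key_name} | {e.description} "
                f"| {e.proportion_display}% |"
            )
        return "\n".join(lines)


def prevalence_table(
    fingerprints: pd.DataFrame,
    subset: list[str] | None = None,
    k: int = 10,
    label: str = "subset",
) -> PrevalenceTable:
    """Top-k MACCS keys by occurrence count within a compound subset.

    ``fingerprints`` is the compound x key matrix from
    :func:`pmtscreen.features.fingerprint_matrix`.  Ties break by key number
    ascending so tables are deterministic.
    """
    if subset is None:
        sub = fingerprints
    else:
        missing = set(subset) - set(fingerprints.index)
        if missing:
            raise KeyError(f"no fingerprints for {sorted(missing)[:5]}")
        sub = fingerprints.loc[list(subset)]
    n = len(sub)
    if n == 0:
        raise ValueError("empty subset")
    counts = sub.sum(axis=0).astype(int)
    order = sorted(counts.index, key=lambda key: (-counts[key], key))
    entries = []
    for key in order[:k]:
        c = int(counts[key])
        if c == 0:
            break
        entries.append(
            PrevalenceEntry(
                key_number=int(key),
                key_name=maccs_key_name(int(key)),
                description=maccs_key_description(int(key)),
                count=c,
                proportion=100.0 * c / n,
            )
        )
    return PrevalenceTable(label=label, size=n, k=k, entries=entries)


def contrast_tables(a: PrevalenceTable, b: PrevalenceTable) -> dict:
    """Shared keys and keys unique to each of two equal-k prevalence tables."""
    if a.k != b.k:
        raise ValueError(f"tables have different k ({a.k} vs {b.k})")
    keys_a = [e.key_number for e in a.entries]
    keys_b = [e.key_number for e in b.entries]
    set_a, set_b = set(keys_a), set(keys_b)
    return {
        "shared": [key for key in keys_a if key in set_b],
        "unique_to_a": [key for key in keys_a if key not in set_b],
        "unique_to_b": [key for key in keys_b if key not in set_a],
    }


def noncyclic_fraction(
    records: list[CompoundRecord], subset: set[str] | None = None
) -> float:
    """Percent of compounds in the subset with zero rings (exact value;
    display convention is one decimal place)."""
    if subset is not None:
        records = [r for r in records if r.compound_id in subset]
    if not records:
        raise ValueError("empty subset")
    n_open = sum(1 for r in records if is_noncyclic(r))
    return 100.0 * n_open / len(records)


def origin_strata_tables(
    records: list[CompoundRecord],
    subset: set[str],
    k: int = 20,
) -> dict[str, PrevalenceTable]:
    """Prevalence tables for the whole subset and its two origin strata
    (synthetic vs natural/undefined grouped)."""
    by_id = {r.compound_id: r for r in records}
    ids = [cid for cid in subset if cid in by_id]
    fps = fingerprint_matrix([by_id[cid] for cid in ids])
    synth = [cid for cid in ids if by_id[cid].origin == "synthetic"]
    other = [cid for cid in ids if by_id[cid].origin in ("natural", "undefined")]
    out = {"all": prevalence_table(fps, ids, k=k, label="identified PMT/vPvM")}
    if synth:
        out["synthetic"] = prevalence_table(
            fps, synth, k=k, label="PMT/vPvM of synthetic origin"
        )
    if other:
        out["natural_or_other"] = prevalence_table(
            fps, other, k=k, label="PMT/vPvM of natural or other origin"
        )
    return out
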