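"""Composition-table arithmetic: enrichment factors and taxon counts.

Works on plain relative-abundance tables (sample_id, taxon, relative
abundance in percent), e.g. the output of an amplicon profiling service.
Taxonomy handling and diversity statistics beyond unique-taxon counts are out
of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["CompositionTable", "fold_enrichment", "unique_taxa_count", "enrichment_table"]

_COLS = ["sample_id", "taxon", "abundance_pct"]


@dataclass
class CompositionTable:
    """Long-format relative-abundance table.

    Rows are (sample_id, taxon, abundance_pct).  Abundances must be
    non-negative and each sample must sum to at most 100 plus a rounding
    tolerance.  Duplicate (sample, taxon) rows are summed on construction.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = pd.DataFrame(self.data)
        missing = [c for c in _COLS if c not in df.columns]
        if missing:
            raise ValueError(f"missing columns: {missing}")
        df = df[_COLS].copy()
        df["abundance_pct"] = df["abundance_pct"].astype(float)
        if (df["abundance_pct"] < 0).any():
            raise ValueError("abundances must be >= 0")
        df = df.groupby(["sample_id", "taxon"], as_index=False)["abundance_pct"].sum()
        sums = df.groupby("sample_id")["abundance_pct"].sum()
        bad = sums[sums > 100 + 0.5]
        if len(bad):
            raise ValueError(f"per-sample abundances exceed 100%: {dict(bad)}")
        self.data = df

    @classmethod
    def from_csv(cls, path) -> "CompositionTable":
        return cls(pd.read_csv(path))

    def samples(self) -> list:
        return sorted(self.data["sample_id"].unique().tolist())

    def abundance(self, sample_id, taxon) -> float:
        sel = self.data[
            (self.data["sample_id"] == sample_id) & (self.data["taxon"] == taxon)
        ]
        return float(sel["abundance_pct"].sum())


def fold_enrichment(abundance_after: float, abundance_before: float) -> float:
    """Fold change of a relative abundance (after / before, both in %).

    Undefined when the taxon was absent before; report an absolute change
    instead in that case.
    """
    if abundance_before <= 0:
        raise ValueError(
            "abundance_before must be > 0; fold change is undefined for a taxon "
            "absent from the input - report the absolute abundance change instead"
        )
    if abundance_after < 0:
        raise ValueError("abundance_after must be >= 0")
    return abundance_after / abundance_before


def unique_taxa_count(table: CompositionTable, sample_id) -> int:
    """Number of taxa with nonzero abundance in one sample."""
    if sample_id not in set(table.data["sample_id"]):
        raise KeyError(f"unknown sample {sample_id!r}")
    sub = table.data[table.data["sample_id"] == sample_id]
    return int((sub["abundance_pct"] > 0).sum())


def enrichment_table(
    before: CompositionTable,
    after: CompositionTable,
    before_sample=None,
    after_sample=None,
) -> pd.DataFrame:
    """Per-taxon fold enrichment between two samples.

    Taxa absent from the ``before`` sample get NaN fold (undefined) with the
    absolute change still reported.  ``fold_rounded`` is a convenience integer
    column for reporting ("22-fold").
    """
    bs = before_sample if before_sample is not None else before.samples()[0]
    as_ = after_sample if after_sample is not None else after.samples()[0]
    b = before.data[before.data["sample_id"] == bs].set_index("taxon")["abundance_pct"]
    a = after.data[after.data["sample_id"] == as_].set_index("taxon")["abundance_pct"]
    taxa = sorted(set(b.index) | set(a.index))
    rows = []
    for t in taxa:
        ab, aa = float(b.get(t, 0.0)), float(a.get(t, 0.0))
        fold = aa / ab if ab > 0 else np.nan
        rows.append(
            {
                "taxon": t,
                "abundance_before_pct": ab,
                "abundance_after_pct": aa,
                "abs_change_pct": aa - ab,
                "fold": fold,
                "fold_rounded": int(round(fold)) if np.isfinite(fold) else pd.NA,
            }
        )
    return pd.DataFrame(rows)
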