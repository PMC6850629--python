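"""Per-sample community properties from pollen counts and the trait table.

Eight properties per sample: four community-weighted mean (CWM) traits (wood
density, ln leaf area, adult height, seed mass), three category percentages
(% compound-leaved, % zoochorous, % useful pollen) and the Poaceae : tree
pollen ratio (landscape openness).  A CWM is the count-weighted average over
taxa with trait data; taxa without data drop out of both numerator and
denominator, and the fraction of tree pollen they represent is reported as a
per-trait coverage diagnostic.

All properties depend only on relative abundances (scale invariance) and every
CWM lies inside the range of contributing taxon trait values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import PollenRecord, ValidationError
from .traits import TABLE_TRAITS, TraitTable

logger = logging.getLogger("pollentraits")

__all__ = [
    "CWMSeries",
    "CWM_PROPERTIES",
    "TRAIT_PROPERTIES",
    "cwm",
    "pct_category",
    "poaceae_tree_ratio",
    "coverage",
    "build_cwm_series",
]

CWM_PROPERTIES = (
    "cwm_wood_density",
    "cwm_ln_leaf_area",
    "cwm_adult_height",
    "cwm_seed_mass",
    "pct_compound",
    "pct_zoochorous",
    "pct_useful",
    "poaceae_tree_ratio",
)
# the seven trait-based properties (everything except the Poaceae:tree ratio,
# which is not a trait and is excluded from the trait-shuffle null)
TRAIT_PROPERTIES = CWM_PROPERTIES[:-1]

_PROPERTY_TRAIT = {
    "cwm_wood_density": "wood_density",
    "cwm_ln_leaf_area": "ln_leaf_area",
    "cwm_adult_height": "adult_height",
    "cwm_seed_mass": "seed_mass",
    "pct_compound": "compound_leaves",
    "pct_zoochorous": "zoochorous",
    "pct_useful": "useful",
}


@dataclass
class CWMSeries:
    """Community property time series (one row per sample, oldest first)."""

    data: pd.DataFrame  # index age_bp; property columns + coverage_* columns
    resolution: str

    @property
    def ages(self) -> np.ndarray:
        return self.data.index.to_numpy(dtype=float)

    def properties(self) -> pd.DataFrame:
        return self.data[list(CWM_PROPERTIES)]

    def coverages(self) -> pd.DataFrame:
        return self.data[[c for c in self.data.columns if c.startswith("coverage_")]]

    def mean_coverage(self) -> pd.Series:
        """Across-sample mean trait coverage (the run-report diagnostic)."""
        return self.coverages().mean()


def cwm(counts: pd.Series, trait_values: pd.Series) -> float:
    """Count-weighted mean trait over taxa with trait data (NaN if none counted)."""
    common = counts.index.intersection(trait_values.index)
    t = trait_values.loc[common]
    n = counts.loc[common].astype(float)
    ok = t.notna() & (n > 0)
    if not ok.any() or n[ok].sum() == 0:
        return float("nan")
    return float((n[ok] * t[ok]).sum() / n[ok].sum())


def pct_category(counts: pd.Series, flag: pd.Series) -> float:
    """100 x flagged pollen / pollen of taxa with flag data (NaN denominator taxa excluded)."""
    common = counts.index.intersection(flag.index)
    f = flag.loc[common]
    n = counts.loc[common].astype(float)
    ok = f.notna() & (n > 0)
    denom = n[ok].sum()
    if denom == 0:
        return float("nan")
    return float(100.0 * n[ok & (f > 0)].sum() / denom)


def poaceae_tree_ratio(counts: pd.Series, record: PollenRecord) -> float:
    """Poaceae pollen / tree pollen (vegetation openness); NaN if no tree pollen."""
    tree = [t.name for t in record.taxa if t.is_tree]
    poa = [t.name for t in record.taxa if t.is_poaceae]
    n_tree = float(counts.reindex(tree).fillna(0).sum())
    n_poa = float(counts.reindex(poa).fillna(0).sum())
    if n_tree == 0:
        logger.warning("sample has zero tree pollen; Poaceae:tree ratio missing")
        return float("nan")
    return n_poa / n_tree


def coverage(counts: pd.Series, trait_values: pd.Series, denominator_taxa: list[str]) -> float:
    """Fraction of denominator pollen whose taxon has data for the trait."""
    n = counts.reindex(denominator_taxa).fillna(0).astype(float)
    total = n.sum()
    if total == 0:
        return float("nan")
    has = trait_values.reindex(denominator_taxa).notna()
    return float(n[has].sum() / total)


def build_cwm_series(
    record: PollenRecord, trait_table: TraitTable, resolution: str | None = None
) -> CWMSeries:
    """Compute the eight community properties plus coverages for every sample.

    CWMs, percentages and coverages use tree taxa at the trait table's
    resolution; the % useful denominator additionally includes Arecaceae; the
    Poaceae : tree ratio uses all tree pollen regardless of rank.
    """
    resolution = resolution or trait_table.resolution
    if resolution != trait_table.resolution:
        raise ValidationError(
            f"trait table was built at {trait_table.resolution!r}, requested {resolution!r}"
        )
    counts_mat = record.counts_matrix()
    table = trait_table.data
    tree_taxa = [t for t in table.index if record.taxon(t).is_tree]
    arecaceae = [t.name for t in record.taxa if t.is_arecaceae]

    rows = []
    for age, counts in counts_mat.iterrows():
        counts = counts[counts > 0]
        row = {"age_bp": age}
        tree_counts = counts.reindex(tree_taxa).fillna(0)
        for prop in ("cwm_wood_density", "cwm_ln_leaf_area", "cwm_adult_height", "cwm_seed_mass"):
            row[prop] = cwm(tree_counts, table[_PROPERTY_TRAIT[prop]])
        row["pct_compound"] = pct_category(tree_counts, table["compound_leaves"])
        row["pct_zoochorous"] = pct_category(tree_counts, table["zoochorous"])
        # usefulness: denominator includes Arecaceae (all flagged useful or not in metadata)
        useful_flags = table["useful"].copy()
        for a in arecaceae:
            useful_flags.loc[a] = float(record.taxon(a).is_useful)
        useful_counts = counts.reindex(tree_taxa + arecaceae).fillna(0)
        row["pct_useful"] = pct_category(useful_counts, useful_flags)
        row["poaceae_tree_ratio"] = poaceae_tree_ratio(counts, record)
        for trait in TABLE_TRAITS:
            row[f"coverage_{trait}"] = coverage(counts, table[trait], tree_taxa)
        rows.append(row)

    data = pd.DataFrame(rows).set_index("age_bp")
    missing = data[list(CWM_PROPERTIES)].isna().sum()
    if missing.any():
        logger.info("CWM series missing cells per property: %s", missing[missing > 0].to_dict())
    return CWMSeries(data=data, resolution=resolution)
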