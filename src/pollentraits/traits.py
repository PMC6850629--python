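"""Aggregate species-level trait records to genus/family means.

A taxon enters the trait table for a given trait only if the inclusion rule
passes: trait data for at least three species of the genus/family, or — for
genera with fewer than nine species — data for at least 30% of its species.
Leaf area is averaged on the raw scale and the taxon mean then ln-transformed
(the alternative, ln-before-averaging, is available via ``log_before_mean``).
Boolean traits use a strict species majority; exact ties leave the cell absent.
Usefulness comes from the taxon metadata ('useful' genus list), not from
species records.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import (
    BOOLEAN_TRAITS,
    NUMERIC_TRAITS,
    SpeciesTraitRecord,
    TaxonInfo,
    ValidationError,
)

logger = logging.getLogger("pollentraits")

__all__ = ["TraitTable", "inclusion_rule", "aggregate_traits", "trait_variance_explained"]

# column names in the aggregated table (leaf area is stored ln-transformed)
TABLE_TRAITS = ("wood_density", "ln_leaf_area", "adult_height", "seed_mass", "compound_leaves", "zoochorous")
_SOURCE_OF = {
    "wood_density": "wood_density",
    "ln_leaf_area": "leaf_area",
    "adult_height": "adult_height",
    "seed_mass": "seed_mass",
    "compound_leaves": "compound_leaves",
    "zoochorous": "zoochorous",
}


@dataclass
class TraitTable:
    """Taxa x trait matrix plus a per-decision audit trail.

    ``data`` holds one row per taxon (columns: the six traits plus ``useful``);
    a missing cell means the inclusion rule failed or species data were absent.
    ``audit`` records, per taxon and trait, the species counts and which rule
    branch decided inclusion.
    """

    data: pd.DataFrame
    audit: pd.DataFrame
    resolution: str

    @property
    def taxa(self) -> list[str]:
        return list(self.data.index)

    def trait_values(self, trait: str) -> pd.Series:
        return self.data[trait]

    def complete_taxa(self, traits: Sequence[str] = TABLE_TRAITS) -> list[str]:
        """Taxa with data for every listed trait (the fourth-corner subset)."""
        return list(self.data.index[self.data[list(traits)].notna().all(axis=1)])


def inclusion_rule(n_with_data: int, n_in_taxon: int | None = None) -> bool:
    """Whether a taxon-level trait mean is reliable enough to use.

    True iff data exist for >= 3 species, or the taxon is known to have fewer
    than nine species and >= 30% of them have data.  With an unknown species
    count only the three-species clause can pass.
    """
    if n_with_data < 0:
        raise ValidationError("n_with_data must be >= 0")
    if n_in_taxon is not None and n_with_data > n_in_taxon:
        raise ValidationError(f"n_with_data={n_with_data} exceeds n_in_taxon={n_in_taxon}")
    if n_with_data >= 3:
        return True
    if n_in_taxon is not None and n_in_taxon < 9 and n_with_data / n_in_taxon >= 0.30:
        return True
    return False


def _species_frame(records: Sequence[SpeciesTraitRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species": r.species,
                "genus": r.genus,
                "family": r.family,
                **{t: r.trait(t) for t in NUMERIC_TRAITS},
                **{
                    t: (np.nan if r.trait(t) is None else float(r.trait(t)))
                    for t in BOOLEAN_TRAITS
                },
            }
            for r in records
        ]
    )


def aggregate_traits(
    records: Sequence[SpeciesTraitRecord],
    taxa: Sequence[TaxonInfo],
    resolution: str = "genus_only",
    species_counts: Mapping[str, int] | str | None = "from_table",
    log_before_mean: bool = False,
) -> TraitTable:
    """Build the taxa x trait table at the chosen taxonomic resolution.

    ``resolution`` is ``'genus_only'`` (tree taxa identified to genus) or
    ``'genus_and_family'`` (genus- plus family-level tree taxa; family means
    use all species records in the family, including those of included genera).
    ``species_counts`` supplies the known number of species per taxon for the
    30% clause; the default ``'from_table'`` treats the species table as a
    census of each taxon.  Pass ``None`` if the true species counts are
    unknown (only the >= 3 clause can then pass).
    """
    if resolution not in ("genus_only", "genus_and_family"):
        raise ValidationError(f"unknown resolution {resolution!r}")
    df = _species_frame(records)
    rows, audit = {}, []
    for taxon in taxa:
        if not taxon.is_tree:
            continue
        if taxon.rank == "family" and resolution == "genus_only":
            continue
        key = "genus" if taxon.rank == "genus" else "family"
        grp = df[df[key] == taxon.name] if not df.empty else df
        row: dict[str, float] = {}
        for trait in TABLE_TRAITS:
            src = _SOURCE_OF[trait]
            values = grp[src].dropna() if not grp.empty else pd.Series(dtype=float)
            n_with = len(values)
            if species_counts == "from_table":
                n_in = len(grp) if not grp.empty else 0
            elif species_counts is None:
                n_in = None
            else:
                n_in = species_counts.get(taxon.name)
            try:
                included = n_with > 0 and inclusion_rule(n_with, n_in)
            except ValidationError:
                raise
            branch = "none"
            if included:
                branch = ">=3_species" if n_with >= 3 else "30pct_small_genus"
            value = np.nan
            if included:
                if trait == "ln_leaf_area":
                    value = np.mean(np.log(values)) if log_before_mean else np.log(values.mean())
                elif trait in BOOLEAN_TRAITS:
                    frac = values.mean()
                    if frac == 0.5:
                        logger.info(
                            "taxon %s: %s tie among %d species; cell left absent",
                            taxon.name, trait, n_with,
                        )
                        value, included, branch = np.nan, False, "tie"
                    else:
                        value = float(frac > 0.5)
                else:
                    value = float(values.mean())
            row[trait] = value
            audit.append(
                {
                    "taxon": taxon.name,
                    "rank": taxon.rank,
                    "trait": trait,
                    "n_with_data": n_with,
                    "n_in_taxon": -1 if n_in is None else n_in,
                    "branch": branch,
                    "included": bool(included),
                }
            )
        row["useful"] = float(taxon.is_useful)
        rows[taxon.name] = row
    data = pd.DataFrame.from_dict(rows, orient="index").reindex(columns=list(TABLE_TRAITS) + ["useful"])
    data.index.name = "taxon"
    excluded = data[list(TABLE_TRAITS)].isna().all(axis=1)
    if excluded.any():
        logger.info("taxa with no usable trait data: %s", list(data.index[excluded]))
    return TraitTable(data=data, audit=pd.DataFrame(audit), resolution=resolution)


def trait_variance_explained(
    records: Sequence[SpeciesTraitRecord], grouping: str, trait: str
) -> float:
    """One-way between-group R^2 of a species-level trait.

    R^2 = between-group sum of squares / total sum of squares, with groups
    defined by genus or family.  Quantifies how informative taxon-level means
    are about species values (e.g. wood density is strongly conserved within
    genera; leaf area much less so).
    """
    if grouping not in ("genus", "family"):
        raise ValidationError(f"grouping must be 'genus' or 'family', got {grouping!r}")
    df = _species_frame(records)
    src = _SOURCE_OF.get(trait, trait)
    sub = df[[grouping, src]].dropna()
    if sub[grouping].nunique() < 2:
        raise ValidationError("need at least 2 groups with data")
    if len(sub) < 3:
        raise ValidationError("need at least 3 species with data")
    y = sub[src].to_numpy(dtype=float)
    grand = y.mean()
    sst = float(((y - grand) ** 2).sum())
    if sst == 0:
        return 1.0
    ssb = float(
        sum(len(g) * (g.mean() - grand) ** 2 for _, g in sub.groupby(grouping)[src])
    )
    return ssb / sst
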