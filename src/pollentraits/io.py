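"""Domain types and delimited-text readers/writers for the pipeline.

The pipeline works on four kinds of input:

* a pollen count table — samples (age, calibrated years BP) by taxa (grain counts),
  with a companion taxon-metadata table (rank, life-form flags);
* species-level trait records, with genus and family for aggregation;
* three irregular proxy series: speleothem d18O (per-mil), charcoal counts
  (particles per cm^3) and sediment band width (mm/yr).

Time convention: ages are stored as calibrated years BP (larger = older).
Collections are ordered in ascending *calendar* time, i.e. descending BP, so the
oldest sample comes first.  Internal computations that need a real time axis use
t = -ageBP so that "previous" always means "smaller t".

All files are UTF-8, comma- or tab-separated (auto-detected from the header line).
Missing trait cells may be empty or "NA".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("pollentraits")

__all__ = [
    "ValidationError",
    "TaxonInfo",
    "PollenSample",
    "PollenRecord",
    "ProxySeries",
    "SpeciesTraitRecord",
    "read_pollen_table",
    "read_proxy_series",
    "read_species_traits",
    "write_pollen_table",
    "write_proxy_series",
    "write_species_traits",
]

NUMERIC_TRAITS = ("wood_density", "leaf_area", "adult_height", "seed_mass")
BOOLEAN_TRAITS = ("compound_leaves", "zoochorous")
PROXY_KINDS = ("d18O", "charcoal", "bandwidth")


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _sniff_sep(path: Path) -> str:
    with open(path, encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


@dataclass(frozen=True)
class TaxonInfo:
    """Identity and life-form flags of one pollen taxon."""

    name: str
    rank: Literal["genus", "family"]
    is_tree: bool = False
    is_poaceae: bool = False
    is_arecaceae: bool = False
    is_useful: bool = False

    def __post_init__(self) -> None:
        if self.rank not in ("genus", "family"):
            raise ValidationError(f"taxon {self.name!r}: rank must be genus or family, got {self.rank!r}")
        if self.is_poaceae and self.is_tree:
            raise ValidationError(f"taxon {self.name!r}: is_poaceae and is_tree are mutually exclusive")


@dataclass(frozen=True)
class PollenSample:
    """Grain counts of one stratigraphic subsample."""

    age: float  # calibrated years BP
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.age < 0:
            raise ValidationError(f"sample age {self.age} BP is negative")
        total = 0
        for taxon, n in self.counts.items():
            if n < 0:
                raise ValidationError(f"sample at {self.age} BP: negative count for {taxon!r}")
            total += n
        if total <= 0:
            raise ValidationError(f"sample at {self.age} BP has zero total count")

    @property
    def total(self) -> int:
        return int(sum(self.counts.values()))


@dataclass
class PollenRecord:
    """An ordered pollen record: samples (oldest first) plus taxon metadata."""

    samples: list[PollenSample]
    taxa: list[TaxonInfo]

    def __post_init__(self) -> None:
        names = [t.name for t in self.taxa]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicate taxon names: {dupes}")
        known = set(names)
        ages = [s.age for s in self.samples]
        if any(a2 >= a1 for a1, a2 in zip(ages, ages[1:])):
            # oldest (largest BP) first; strictly decreasing BP = ascending calendar time
            raise ValidationError("sample ages must be strictly decreasing in BP (oldest first)")
        for s in self.samples:
            unknown = sorted(set(s.counts) - known)
            if unknown:
                raise ValidationError(
                    f"sample at {s.age} BP counts taxa missing from metadata: {unknown}"
                )

    @property
    def ages(self) -> np.ndarray:
        """Sample ages, years BP, oldest first."""
        return np.array([s.age for s in self.samples], dtype=float)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def taxon(self, name: str) -> TaxonInfo:
        for t in self.taxa:
            if t.name == name:
                return t
        raise KeyError(name)

    def counts_matrix(self) -> pd.DataFrame:
        """Samples x taxa count matrix (rows oldest first, indexed by age BP)."""
        mat = pd.DataFrame(
            [{t.name: s.counts.get(t.name, 0) for t in self.taxa} for s in self.samples],
            index=pd.Index(self.ages, name="age_bp"),
            dtype=int,
        )
        return mat


@dataclass
class ProxySeries:
    """One irregular palaeo-proxy series, ordered oldest first."""

    kind: Literal["d18O", "charcoal", "bandwidth"]
    ages: np.ndarray  # years BP, strictly decreasing
    values: np.ndarray

    UNITS = {"d18O": "per-mil", "charcoal": "particles cm-3", "bandwidth": "mm yr-1"}

    def __post_init__(self) -> None:
        if self.kind not in PROXY_KINDS:
            raise ValidationError(f"unknown proxy kind {self.kind!r}")
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValidationError("ages and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValidationError(f"{self.kind} series contains non-finite values")
        if np.any(np.diff(self.ages) >= 0):
            raise ValidationError(f"{self.kind} series ages must be strictly decreasing (oldest first)")
        if self.kind in ("charcoal", "bandwidth") and np.any(self.values < 0):
            bad = float(self.values[self.values < 0][0])
            raise ValidationError(f"{self.kind} series has negative value {bad}")

    def __len__(self) -> int:
        return len(self.ages)

    @property
    def units(self) -> str:
        return self.UNITS[self.kind]

    @classmethod
    def from_points(cls, kind: str, ages: Iterable[float], values: Iterable[float]) -> "ProxySeries":
        """Build a series from unordered (age, value) pairs, sorting oldest-first."""
        ages = np.asarray(list(ages), dtype=float)
        values = np.asarray(list(values), dtype=float)
        order = np.argsort(-ages, kind="stable")
        ages, values = ages[order], values[order]
        if np.any(np.diff(ages) == 0):
            dup = float(ages[np.where(np.diff(ages) == 0)[0][0]])
            raise ValidationError(f"duplicate age {dup} BP in {kind} series")
        return cls(kind=kind, ages=ages, values=values)


@dataclass(frozen=True)
class SpeciesTraitRecord:
    """Trait measurements of one species (missing traits are None)."""

    species: str
    genus: str
    family: str
    wood_density: float | None = None  # g cm-3
    leaf_area: float | None = None  # raw scale (e.g. cm^2); ln-transform happens at aggregation
    adult_height: float | None = None  # m
    seed_mass: float | None = None  # g
    compound_leaves: bool | None = None
    zoochorous: bool | None = None

    def __post_init__(self) -> None:
        for trait in NUMERIC_TRAITS:
            v = getattr(self, trait)
            if v is not None and not (np.isfinite(v) and v > 0):
                raise ValidationError(f"species {self.species!r}: {trait} must be finite and > 0, got {v}")
        if all(getattr(self, t) is None for t in NUMERIC_TRAITS + BOOLEAN_TRAITS):
            raise ValidationError(f"species {self.species!r} has no trait values")

    def trait(self, name: str):
        return getattr(self, name)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

_TRUE = {"true", "1", "t", "yes", "y"}
_FALSE = {"false", "0", "f", "no", "n"}


def _parse_bool(value, context: str) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    s = str(value).strip().lower()
    if s in ("", "na", "nan"):
        return None
    if s in _TRUE:
        return True
    if s in _FALSE:
        return False
    raise ValidationError(f"{context}: cannot parse boolean value {value!r}")


def read_pollen_table(path, taxon_metadata) -> PollenRecord:
    """Read a pollen count table plus its taxon metadata table.

    The count table has the age (years BP) in its first column and one count
    column per taxon.  The metadata table maps each taxon name to its rank and
    life-form flags (columns: taxon, rank, is_tree, is_poaceae, is_arecaceae,
    is_useful).  Rows whose counts sum to zero are dropped with a warning.
    """
    path, meta_path = Path(path), Path(taxon_metadata)
    counts = pd.read_csv(path, sep=_sniff_sep(path))
    meta = pd.read_csv(meta_path, sep=_sniff_sep(meta_path))

    age_col = counts.columns[0]
    ages = counts[age_col].astype(float)
    if ages.duplicated().any():
        dup = float(ages[ages.duplicated()].iloc[0])
        raise ValidationError(f"duplicate sample age {dup} BP in {path.name}")

    taxa = []
    for row in meta.itertuples(index=False):
        d = row._asdict()
        taxa.append(
            TaxonInfo(
                name=str(d["taxon"]),
                rank=str(d["rank"]),
                is_tree=bool(_parse_bool(d.get("is_tree", False), "is_tree")),
                is_poaceae=bool(_parse_bool(d.get("is_poaceae", False), "is_poaceae")),
                is_arecaceae=bool(_parse_bool(d.get("is_arecaceae", False), "is_arecaceae")),
                is_useful=bool(_parse_bool(d.get("is_useful", False), "is_useful")),
            )
        )
    known = {t.name for t in taxa}
    count_cols = [c for c in counts.columns if c != age_col]
    unknown = sorted(set(count_cols) - known)
    if unknown:
        raise ValidationError(f"taxa counted in {path.name} but absent from metadata: {unknown}")

    block = counts[count_cols]
    if (block.to_numpy() < 0).any():
        raise ValidationError(f"negative counts in {path.name}")

    samples = []
    for age, (_, row) in zip(ages, block.iterrows()):
        c = {k: int(v) for k, v in row.items() if v > 0}
        if not c:
            logger.warning("dropping sample at %s BP: zero total pollen count", age)
            continue
        samples.append(PollenSample(age=float(age), counts=c))
    samples.sort(key=lambda s: -s.age)
    return PollenRecord(samples=samples, taxa=taxa)


def read_proxy_series(path, kind: str) -> ProxySeries:
    """Read a two-column (age BP, value) proxy file; rows are sorted oldest-first."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.shape[1] < 2:
        raise ValidationError(f"{path.name}: expected two columns (age, value)")
    return ProxySeries.from_points(kind, df.iloc[:, 0].astype(float), df.iloc[:, 1].astype(float))


def read_species_traits(path) -> list[SpeciesTraitRecord]:
    """Read species-level trait records; blank or NA cells mark traits absent."""
    path = Path(path)
    df = pd.read_csv(path, sep=_sniff_sep(path))
    if df.empty:
        logger.warning("species trait file %s is empty", path.name)
        return []
    records: list[SpeciesTraitRecord] = []
    for _, row in df.iterrows():
        kwargs = {
            "species": str(row["species"]),
            "genus": str(row["genus"]),
            "family": str(row["family"]),
        }
        for trait in NUMERIC_TRAITS:
            v = row.get(trait)
            kwargs[trait] = None if v is None or pd.isna(v) else float(v)
        for trait in BOOLEAN_TRAITS:
            kwargs[trait] = _parse_bool(row.get(trait), f"species {kwargs['species']}: {trait}")
        try:
            records.append(SpeciesTraitRecord(**kwargs))
        except ValidationError as err:
            if "has no trait values" in str(err):
                logger.warning("dropping %s", err)
            else:
                raise
    return records


# ---------------------------------------------------------------------------
# writers (full-precision round trip)
# ---------------------------------------------------------------------------

def write_pollen_table(record: PollenRecord, counts_path, metadata_path) -> None:
    mat = record.counts_matrix().reset_index()
    mat.to_csv(counts_path, index=False)
    meta = pd.DataFrame(
        [
            {
                "taxon": t.name,
                "rank": t.rank,
                "is_tree": t.is_tree,
                "is_poaceae": t.is_poaceae,
                "is_arecaceae": t.is_arecaceae,
                "is_useful": t.is_useful,
            }
            for t in record.taxa
        ]
    )
    meta.to_csv(metadata_path, index=False)


def write_proxy_series(series: ProxySeries, path) -> None:
    pd.DataFrame({"age_bp": series.ages, series.kind: series.values}).to_csv(path, index=False)


def write_species_traits(records: Sequence[SpeciesTraitRecord], path) -> None:
    rows = []
    for r in records:
        row = {"species": r.species, "genus": r.genus, "family": r.family}
        for trait in NUMERIC_TRAITS + BOOLEAN_TRAITS:
            v = r.trait(trait)
            row[trait] = "" if v is None else v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
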