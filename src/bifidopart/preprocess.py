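"""Sample selection, taxonomy collapse, rarefaction, diversity and eligibility
filtering for genus-focused community typing.

The functions here implement the bookkeeping that precedes the mixture fit:
keeping one deep stool metagenome per subject, collapsing species counts to
genus level, rarefying for alpha-diversity, binning ages and health labels into
closed vocabularies, and deciding which subjects enter the
Dirichlet-multinomial fit (antibiotic users excluded, low *Bifidobacterium*
totals excluded, zero-count subjects set aside as a dedicated ``no_Bif``
class).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "CountTable",
    "EligibilityReport",
    "AGE_CATEGORIES",
    "HEALTH_CATEGORIES",
    "DEFAULT_HEALTH_MAP",
    "select_samples",
    "collapse_by_genus",
    "rarefy",
    "shannon",
    "categorize_age",
    "map_health_category",
    "dmm_eligibility_filter",
]

AGE_CATEGORIES = ("newborn", "child", "school_age", "adult", "senior")
HEALTH_CATEGORIES = (
    "control",
    "adenoma",
    "colorectal",
    "metabolic",
    "bowel",
    "arthritis",
    "unknown",
)

#: Raw condition label (lower-case) -> aggregated health category.
#: IBD -> bowel; metabolic syndrome conditions -> metabolic; rheumatoid
#: arthritis and Behçet's disease -> arthritis; adenoma subtypes -> adenoma;
#: colorectal cancers including metastases -> colorectal; healthy -> control.
DEFAULT_HEALTH_MAP: dict[str, str] = {
    "healthy": "control",
    "control": "control",
    "ibd": "bowel",
    "inflammatory bowel disease": "bowel",
    "t2d": "metabolic",
    "type 2 diabetes": "metabolic",
    "hypertension": "metabolic",
    "acvd": "metabolic",
    "atherosclerotic cardiovascular disease": "metabolic",
    "hypercholesterolemia": "metabolic",
    "igt": "metabolic",
    "impaired glucose tolerance": "metabolic",
    "metabolic": "metabolic",
    "ra": "arthritis",
    "rheumatoid arthritis": "arthritis",
    "arthritis": "arthritis",
    "bd": "arthritis",
    "behçet's disease": "arthritis",
    "behcet's disease": "arthritis",
    "adenoma": "adenoma",
    "tubular adenoma": "adenoma",
    "advanced adenoma": "adenoma",
    "crc": "colorectal",
    "colorectal cancer": "colorectal",
    "colorectal": "colorectal",
    "metastases": "colorectal",
}


class CountTable:
    """Integer taxa × sample count matrix with an optional species→genus map.

    Parameters
    ----------
    counts
        DataFrame (or array-like convertible to one) with taxa as the row
        index and sample ids as columns.  Entries must be non-negative
        integers.
    taxonomy
        Mapping from species id to genus name.  Optional; required by
        :func:`collapse_by_genus` and genus subsetting.
    """

    def __init__(self, counts, taxonomy: Mapping[str, str] | None = None, validate: bool = True):
        counts = pd.DataFrame(counts)
        if validate:
            if counts.index.has_duplicates:
                raise ValueError("duplicate taxon ids")
            if counts.columns.has_duplicates:
                raise ValueError("duplicate sample ids")
            arr = counts.to_numpy()
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError("counts must be numeric")
            if (arr < 0).any():
                raise ValueError("counts must be non-negative")
            if not np.allclose(arr, np.round(arr)):
                raise ValueError("counts must be integral")
        self.counts = counts.astype(np.int64)
        self.taxonomy = dict(taxonomy) if taxonomy is not None else None

    # -- basic accessors ---------------------------------------------------
    @property
    def taxa(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def sample_totals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def genus_species(self, genus: str) -> list[str]:
        if self.taxonomy is None:
            raise ValueError("CountTable has no taxonomy")
        return [t for t in self.counts.index if self.taxonomy.get(t) == genus]

    def genus_subtable(self, genus: str) -> "CountTable":
        """Sub-table restricted to the species of one genus."""
        sp = self.genus_species(genus)
        return CountTable(self.counts.loc[sp], {s: genus for s in sp}, validate=False)

    def genus_totals(self, genus: str) -> pd.Series:
        """Per-sample total count over the species of `genus`."""
        return self.counts.loc[self.genus_species(genus)].sum(axis=0)

    def subset_samples(self, samples: Iterable[str]) -> "CountTable":
        return CountTable(self.counts.loc[:, list(samples)], self.taxonomy, validate=False)

    def copy(self) -> "CountTable":
        return CountTable(self.counts.copy(), self.taxonomy, validate=False)

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, path, taxonomy_path=None) -> None:
        self.counts.to_csv(path, sep="\t", index_label="taxon")
        if taxonomy_path is not None and self.taxonomy is not None:
            pd.Series(self.taxonomy, name="genus").rename_axis("species").to_csv(
                taxonomy_path, sep="\t"
            )

    @classmethod
    def from_tsv(cls, path, taxonomy_path=None) -> "CountTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        taxonomy = None
        if taxonomy_path is not None:
            tax = pd.read_csv(taxonomy_path, sep="\t", index_col=0)
            taxonomy = tax.iloc[:, 0].to_dict()
        return cls(counts, taxonomy)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"CountTable({self.counts.shape[0]} taxa x {self.counts.shape[1]} samples)"


@dataclass
class EligibilityReport:
    """Outcome of the mixture-eligibility filter.

    ``retained`` + ``zero_bif`` + the excluded counts partition the input.
    """

    retained: list[str]
    zero_bif: list[str]
    excluded: dict[str, int] = field(default_factory=dict)

    @property
    def n_input(self) -> int:
        return len(self.retained) + len(self.zero_bif) + sum(self.excluded.values())


def select_samples(
    metadata: pd.DataFrame,
    min_reads: int = 5_000_000,
    exclude_studies: Iterable[str] = ("LeChatelierE_2013",),
    body_site: str | None = "stool",
) -> list[str]:
    """Keep one deep stool sample per subject.

    Rules: keep samples from `body_site` with strictly more than `min_reads`
    reads, drop `exclude_studies`, and keep for each subject the sample with
    the highest read count (ties broken by lexicographically smallest
    sample id).  Samples with missing read counts are dropped with a warning.
    """
    md = metadata
    if body_site is not None and "body_site" in md.columns:
        md = md[md["body_site"] == body_site]
    missing = md["n_reads"].isna()
    if missing.any():
        warnings.warn(f"dropping {int(missing.sum())} samples with missing n_reads")
        md = md[~missing]
    md = md[~md["study_id"].isin(set(exclude_studies))]
    md = md[md["n_reads"] > min_reads]
    if md.empty:
        return []
    md = md.sort_values(["subject_id", "n_reads", "sample_id"], ascending=[True, False, True])
    best = md.groupby("subject_id", sort=False).head(1)
    keep = set(best["sample_id"])
    return [s for s in metadata["sample_id"] if s in keep]


def collapse_by_genus(table: CountTable) -> CountTable:
    """Sum species counts to genus level.  Column sums are preserved exactly."""
    if table.taxonomy is None:
        raise ValueError("genus collapse requires a species→genus taxonomy")
    missing = [t for t in table.taxa if t not in table.taxonomy]
    if missing:
        raise KeyError(f"species without genus mapping: {missing[:5]}")
    genus = pd.Index([table.taxonomy[t] for t in table.taxa], name="taxon")
    collapsed = table.counts.groupby(genus, sort=True).sum()
    return CountTable(collapsed, {g: g for g in collapsed.index}, validate=False)


def rarefy(
    table: CountTable, depth: int = 1_000_000, seed: int = 0
) -> tuple[CountTable, list[str]]:
    """Subsample every sample without replacement to exactly `depth` counts.

    Samples whose total is below `depth` are dropped and reported (second
    return value); they are not an error because rarefaction is used for
    alpha-diversity only.  Subsampling is exact multivariate hypergeometric.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    rng = np.random.default_rng(seed)
    out = {}
    dropped: list[str] = []
    for s in table.samples:
        col = table.counts[s].to_numpy()
        tot = int(col.sum())
        if tot < depth:
            dropped.append(s)
        elif tot == depth:
            out[s] = col
        else:
            out[s] = rng.multivariate_hypergeometric(col, depth)
    kept = pd.DataFrame(out, index=table.counts.index)
    return CountTable(kept, table.taxonomy, validate=False), dropped


def shannon(counts) -> float:
    """Shannon diversity H = −Σ p_i ln p_i (nats) over non-zero proportions."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    tot = x.sum()
    if tot <= 0:
        raise ValueError("Shannon diversity undefined for an all-zero vector")
    p = x[x > 0] / tot
    return float(-(p * np.log(p)).sum())


def categorize_age(age_years: float) -> str:
    """Bin an age in years into the closed age vocabulary.

    newborn < 1; child [1, 12); school_age [12, 19); senior > 65; adult
    otherwise (the senior rule takes precedence over the overlapping
    adult ≥ 19 definition).
    """
    if age_years is None or (isinstance(age_years, float) and np.isnan(age_years)):
        raise ValueError("age is missing")
    if age_years < 0:
        raise ValueError("age must be non-negative")
    if age_years < 1:
        return "newborn"
    if age_years < 12:
        return "child"
    if age_years < 19:
        return "school_age"
    if age_years > 65:
        return "senior"
    return "adult"


def map_health_category(label, mapping: Mapping[str, str] | None = None) -> str:
    """Map a raw condition label onto the aggregated health vocabulary.

    Unmapped labels return ``"unknown"`` with a warning rather than failing,
    since pooled-study metadata is heterogeneous.
    """
    if mapping is None:
        mapping = DEFAULT_HEALTH_MAP
    if label is None or (isinstance(label, float) and np.isnan(label)):
        return "unknown"
    key = str(label).strip().lower()
    if key in ("", "unknown", "na", "nan"):
        return "unknown"
    if key in mapping:
        return mapping[key]
    warnings.warn(f"unmapped health label {label!r} -> unknown")
    return "unknown"


def dmm_eligibility_filter(
    metadata: pd.DataFrame,
    bif_totals: pd.Series,
    min_total: int = 500,
    exclude_antibiotic: tuple[str, ...] = ("yes", "unknown"),
) -> EligibilityReport:
    """Decide which subjects enter the mixture fit.

    Step 1 removes subjects whose antibiotic status is in
    `exclude_antibiotic` (default: declared users and unknowns — the only
    reading consistent with the cohort margins, exposed as a switch).
    Step 2 removes subjects with 0 < total < `min_total` (genus
    underdetection).  Step 3 sets subjects with a zero total aside as the
    ``zero_bif`` class, later labelled ``no_Bif``.
    """
    sample_ids = list(metadata["sample_id"])
    totals = bif_totals.reindex(sample_ids)
    if totals.isna().any():
        raise KeyError("bif_totals missing for some metadata rows")
    anti = metadata.set_index("sample_id")["antibiotic_use"].reindex(sample_ids)

    excluded: dict[str, int] = {}
    keep = ~anti.isin(set(exclude_antibiotic))
    excluded["antibiotic"] = int((~keep).sum())

    t = totals[keep.to_numpy()]
    low = (t > 0) & (t < min_total)
    excluded["low_bif_count"] = int(low.sum())
    zero = t == 0
    retained = list(t.index[~(low | zero)])
    zero_bif = list(t.index[zero])
    return EligibilityReport(retained=retained, zero_bif=zero_bif, excluded=excluded)
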