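"""Synthetic cohorts, metadata and MAG collections with known ground truth.

The generators mirror the statistical structure the analysis assumes so that
every downstream stage can be exercised without external downloads:

* mixed-membership Dirichlet-multinomial *Bifidobacterium* sub-communities
  over 32 species, with a configurable fraction of samples carrying no
  *Bifidobacterium* reads at all;
* background taxa with lognormal-Poisson counts and partition-linked
  multiplicative abundance shifts (the generative counterpart of the
  butyrate-producer enrichment the differential-abundance stage detects);
* a deterministic metadata table whose marginal counts reproduce the pooled
  cohort's published margins (9,515 subjects), used to check the eligibility
  filter arithmetic and the summary-table percentages;
* MAG collections per species with a planted, phylogenetically clustered
  phage-gene cassette, within/between-subclade SNP rates and simulated
  completeness.

All outputs are bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .pangenome import MAGRecord
from .preprocess import CountTable

__all__ = [
    "BIF_SPECIES_32",
    "CohortConfig",
    "MagSimConfig",
    "GroundTruth",
    "default_components",
    "default_partition_effects",
    "generate_partitioned_cohort",
    "generate_table1_fixture",
    "generate_mag_collection",
]

#: The 32 gut *Bifidobacterium* species tracked by the cohort generator.
BIF_SPECIES_32 = [
    "Bifidobacterium_longum",
    "Bifidobacterium_adolescentis",
    "Bifidobacterium_bifidum",
    "Bifidobacterium_pseudocatenulatum",
    "Bifidobacterium_catenulatum",
    "Bifidobacterium_breve",
    "Bifidobacterium_animalis",
    "Bifidobacterium_dentium",
    "Bifidobacterium_angulatum",
    "Bifidobacterium_pseudolongum",
    "Bifidobacterium_gallicum",
    "Bifidobacterium_ruminantium",
    "Bifidobacterium_merycicum",
    "Bifidobacterium_thermophilum",
    "Bifidobacterium_boum",
    "Bifidobacterium_choerinum",
    "Bifidobacterium_cuniculi",
    "Bifidobacterium_magnum",
    "Bifidobacterium_minimum",
    "Bifidobacterium_subtile",
    "Bifidobacterium_asteroides",
    "Bifidobacterium_coryneforme",
    "Bifidobacterium_indicum",
    "Bifidobacterium_scardovii",
    "Bifidobacterium_gallinarum",
    "Bifidobacterium_pullorum",
    "Bifidobacterium_saeculare",
    "Bifidobacterium_tsurumiense",
    "Bifidobacterium_mongoliense",
    "Bifidobacterium_moukalabense",
    "Bifidobacterium_kashiwanohense",
    "Bifidobacterium_stercoris",
]

#: Named background taxa reused by the default partition effects.
BACKGROUND_NAMED = [
    ("Escherichia_coli", "Escherichia"),
    ("Roseburia_faecis", "Roseburia"),
    ("Coprococcus_catus", "Coprococcus"),
    ("Coprococcus_eutactus", "Coprococcus"),
    ("Coprococcus_comes", "Coprococcus"),
    ("Eubacterium_hallii", "Eubacterium"),
    ("Streptococcus_salivarius", "Streptococcus"),
]


def default_components(
    n_species: int = 32,
    k: int = 6,
    pair_mass: float = 0.9,
    concentration: float = 50.0,
) -> list[tuple[float, np.ndarray]]:
    """Equal-weight, well-separated Dirichlet components.

    Component i concentrates `pair_mass` of its Dirichlet mass on the species
    pair (2i, 2i+1) — mimicking partitions dominated by two species — and
    spreads the remainder uniformly.  Total concentration is `concentration`.
    """
    comps = []
    for i in range(k):
        a = np.full(n_species, (1.0 - pair_mass) * concentration / (n_species - 2))
        a[2 * i] = pair_mass * concentration / 2
        a[2 * i + 1] = pair_mass * concentration / 2
        comps.append((1.0 / k, a))
    return comps


def default_partition_effects() -> dict[int, dict[str, float]]:
    """Planted background shifts for the health-associated-like partitions.

    Partitions 1, 2 and 6 (the two-species-dominated analogues) gain butyrate
    producers and lose *E. coli*, mirroring the enrichment the NB stage is
    meant to detect.
    """
    enriched = {
        "Roseburia_faecis": 1.5,
        "Coprococcus_catus": 1.0,
        "Coprococcus_eutactus": 1.0,
        "Coprococcus_comes": 1.0,
        "Eubacterium_hallii": 1.0,
        "Escherichia_coli": -1.5,
    }
    return {p: dict(enriched) for p in (1, 2, 6)}


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort generator.

    `dmm_components` is a list of (weight, alpha) pairs; weights must sum to
    one and alphas must be strictly positive vectors of length
    `n_bif_species`.  Per-sample *Bifidobacterium* depths are uniform on
    `bif_depth_range` (inclusive).  Background taxa are lognormal-Poisson
    with partition-linked log2 fold-changes from `partition_effects`.
    """

    n_samples: int = 2000
    n_bif_species: int = 32
    dmm_components: list[tuple[float, np.ndarray]] = field(default_factory=default_components)
    bif_depth_range: tuple[int, int] = (1000, 20000)
    n_background_taxa: int = 60
    background_log_mean: float = 6.0
    background_log_sd: float = 1.5
    partition_effects: dict[int, dict[str, float]] = field(
        default_factory=default_partition_effects
    )
    zero_bif_fraction: float = 0.0
    health_control_fraction: dict | None = None
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples <= 0 or self.n_bif_species <= 0 or self.n_background_taxa < 0:
            raise ValueError("sizes must be positive")
        if not self.dmm_components:
            raise ValueError("dmm_components must be non-empty")
        w = np.array([c[0] for c in self.dmm_components], dtype=float)
        if not np.isfinite(w).all() or abs(w.sum() - 1.0) > 1e-9 or (w < 0).any():
            raise ValueError("component weights must be non-negative and sum to 1")
        for _, a in self.dmm_components:
            a = np.asarray(a, dtype=float)
            if a.shape != (self.n_bif_species,):
                raise ValueError("alpha length must equal n_bif_species")
            if not np.isfinite(a).all() or (a <= 0).any():
                raise ValueError("alpha entries must be finite and > 0")
        if not 0.0 <= self.zero_bif_fraction <= 1.0:
            raise ValueError("zero_bif_fraction must be a probability")
        lo, hi = self.bif_depth_range
        if lo <= 0 or hi < lo:
            raise ValueError("invalid bif_depth_range")


@dataclass
class GroundTruth:
    """Planted truth for a synthetic cohort and/or MAG collection."""

    sample_component: pd.Series | None = None  # sample -> 1-based component or "no_bif"
    taxon_log2fc: dict | None = None  # partition -> {taxon -> log2 fold-change}
    mag_subclade: pd.Series | None = None  # mag_id -> bool
    cassette_ogs: frozenset | None = None  # OG ids of the planted cassette
    cassette_in_mag: pd.Series | None = None  # mag_id -> bool


def _bif_species_names(n: int) -> list[str]:
    if n <= len(BIF_SPECIES_32):
        return BIF_SPECIES_32[:n]
    extra = [f"Bifidobacterium_sp{i:03d}" for i in range(n - len(BIF_SPECIES_32))]
    return BIF_SPECIES_32 + extra


def _background_taxa(n: int) -> list[tuple[str, str]]:
    named = BACKGROUND_NAMED[:n]
    extra = [(f"Background_species_{i:03d}", f"Background_genus_{i:03d}") for i in range(len(named), n)]
    return named + extra


def generate_partitioned_cohort(
    config: CohortConfig,
) -> tuple[CountTable, pd.DataFrame, GroundTruth]:
    """Draw a cohort from the mixed-membership generative model.

    Each non-zero sample picks a component by weight, a composition from
    Dirichlet(alpha), and counts from a multinomial at a uniform depth.
    Background taxa are Poisson with lognormal rates, multiplied by
    2**log2fc for the sample's partition where `partition_effects` applies.
    Returns the species count table (Bifidobacterium + background), a
    metadata table and the planted truth.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, S = config.n_samples, config.n_bif_species
    bif_names = _bif_species_names(S)
    bg = _background_taxa(config.n_background_taxa)
    bg_names = [s for s, _ in bg]

    weights = np.array([c[0] for c in config.dmm_components], dtype=float)
    alphas = [np.asarray(c[1], dtype=float) for c in config.dmm_components]
    K = len(weights)

    sample_ids = [f"S{i:05d}" for i in range(n)]
    comp_ids = np.empty(n, dtype=object)
    bif_counts = np.zeros((n, S), dtype=np.int64)

    zero_mask = rng.random(n) < config.zero_bif_fraction
    lo, hi = config.bif_depth_range
    for i in range(n):
        if zero_mask[i]:
            comp_ids[i] = "no_bif"
            continue
        c = int(rng.choice(K, p=weights))
        comp_ids[i] = c + 1
        p = rng.dirichlet(alphas[c])
        depth = int(rng.integers(lo, hi + 1))
        bif_counts[i] = rng.multinomial(depth, p)

    # background: count ~ Poisson(LogNormal(mu, sd) * 2**lfc(partition))
    bg_counts = np.zeros((n, len(bg_names)), dtype=np.int64)
    if bg_names:
        lam = rng.lognormal(config.background_log_mean, config.background_log_sd, (n, len(bg_names)))
        lfc = np.zeros((n, len(bg_names)))
        name_ix = {t: j for j, t in enumerate(bg_names)}
        for part, effects in (config.partition_effects or {}).items():
            rows = np.array([comp_ids[i] == part for i in range(n)])
            if not rows.any():
                continue
            for taxon, fc in effects.items():
                if taxon in name_ix:
                    lfc[rows, name_ix[taxon]] = fc
        bg_counts = rng.poisson(lam * np.exp2(lfc))

    counts = pd.DataFrame(
        np.hstack([bif_counts, bg_counts]).T,
        index=pd.Index(bif_names + bg_names, name="taxon"),
        columns=sample_ids,
    )
    taxonomy = {s: "Bifidobacterium" for s in bif_names}
    taxonomy.update({s: g for s, g in bg})
    table = CountTable(counts, taxonomy, validate=False)

    # metadata: adult, no-antibiotic, westernized cohort; health status is
    # control with a per-partition probability when configured
    hcf = config.health_control_fraction
    health = []
    for i in range(n):
        if hcf is None:
            health.append("control")
        else:
            frac = hcf.get(comp_ids[i], hcf.get("no_bif", 0.7) if comp_ids[i] == "no_bif" else 0.8)
            health.append("control" if rng.random() < frac else "metabolic")
    metadata = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"subj{i:05d}" for i in range(n)],
            "study_id": "sim_cohort",
            "body_site": "stool",
            "n_reads": 30_000_000,
            "age_years": 35.0,
            "age_category": "adult",
            "lifestyle": "westernized",
            "antibiotic_use": "no",
            "health_category": health,
        }
    )

    truth = GroundTruth(
        sample_component=pd.Series(comp_ids, index=sample_ids),
        taxon_log2fc={p: dict(e) for p, e in (config.partition_effects or {}).items()},
    )
    return table, metadata, truth


# ---------------------------------------------------------------------------
# deterministic cohort-margin metadata fixture


def _fill(n: int, spec: list[tuple[str, int]]) -> list[str]:
    """Expand [(value, count), ...] into a list of length n (counts must sum to n)."""
    out: list[str] = []
    for value, count in spec:
        out.extend([value] * count)
    if len(out) != n:
        raise AssertionError(f"fixture margin mismatch: {len(out)} != {n}")
    return out


_AGE_YEARS = {"newborn": 0.5, "child": 5.0, "school_age": 15.0, "adult": 35.0, "senior": 70.0}


def generate_table1_fixture() -> pd.DataFrame:
    """Deterministic 9,515-row metadata table with the pooled cohort's margins.

    Marginals: 216 antibiotic-yes, 3,571 antibiotic-unknown, 5,728 no;
    health 7,016 control / 153 adenoma / 439 colorectal / 656 metabolic /
    535 bowel / 94 arthritis / 20 Behçet's disease / 602 unknown; ages
    278 / 322 / 135 / 7,745 / 1,035; 8,701 westernized.  The joint layout is
    chosen so the no-antibiotic column (control 4,876 of 5,728) and the adult
    no-antibiotic column (control 4,348 of 4,921; 4,774 westernized) hold as
    well.  Among the antibiotic-eligible subjects, 380 carry a zero
    *Bifidobacterium* total and 19 a non-zero total below 500.
    """
    rows = []

    # --- no-antibiotic block: 4,921 adults then 807 non-adults -----------
    adult_no_cond = _fill(
        4921,
        [
            ("control", 4348),
            ("adenoma", 29),
            ("colorectal", 74),
            ("metabolic", 320),
            ("bowel", 45),
            ("arthritis", 85),
            ("BD", 20),
        ],
    )
    adult_no_west = [True] * 4774 + [False] * (4921 - 4774)
    for i in range(4921):
        rows.append(("no", "adult", adult_no_cond[i], adult_no_west[i]))

    nonadult_no_age = _fill(
        807, [("newborn", 137), ("child", 160), ("school_age", 88), ("senior", 422)]
    )
    nonadult_no_cond = _fill(
        807,
        [
            ("control", 528),
            ("adenoma", 10),
            ("colorectal", 36),
            ("metabolic", 175),
            ("bowel", 54),
            ("arthritis", 4),
        ],
    )
    nonadult_no_west = [True] * 803 + [False] * 4
    for i in range(807):
        rows.append(("no", nonadult_no_age[i], nonadult_no_cond[i], nonadult_no_west[i]))

    # --- antibiotic yes (216) + unknown (3,571) block ---------------------
    ab = ["yes"] * 216 + ["unknown"] * 3571
    ab_age = _fill(
        3787,
        [("newborn", 141), ("child", 162), ("school_age", 47), ("adult", 2824), ("senior", 613)],
    )
    ab_cond = _fill(
        3787,
        [
            ("control", 2140),
            ("adenoma", 114),
            ("colorectal", 329),
            ("metabolic", 161),
            ("bowel", 436),
            ("arthritis", 5),
            ("unknown", 602),
        ],
    )
    ab_west = [True] * 3124 + [False] * (3787 - 3124)
    for i in range(3787):
        rows.append((ab[i], ab_age[i], ab_cond[i], ab_west[i]))

    df = pd.DataFrame(rows, columns=["antibiotic_use", "age_category", "condition", "westernized"])
    n = len(df)
    df.insert(0, "sample_id", [f"T1S{i:05d}" for i in range(n)])
    df.insert(1, "subject_id", [f"T1subj{i:05d}" for i in range(n)])
    df["study_id"] = "table1_fixture"
    df["body_site"] = "stool"
    df["n_reads"] = 30_000_000
    df["age_years"] = df["age_category"].map(_AGE_YEARS)
    df["lifestyle"] = np.where(df["westernized"], "westernized", "non_westernized")
    # BD folds into arthritis in the aggregated vocabulary
    df["health_category"] = df["condition"].replace({"BD": "arthritis"})

    # Bifidobacterium totals: within the no-antibiotic block the last 399
    # rows carry the planted zero (380) and low-count (19) totals.
    bif = np.full(n, 0, dtype=np.int64)
    no_idx = np.nonzero((df["antibiotic_use"] == "no").to_numpy())[0]
    assert len(no_idx) == 5728
    bif[no_idx] = 1000 + (no_idx % 500)
    bif[no_idx[-399:-19]] = 0
    bif[no_idx[-19:]] = 100 + np.arange(19)
    # antibiotic-excluded rows get ordinary totals
    other_idx = np.nonzero((df["antibiotic_use"] != "no").to_numpy())[0]
    bif[other_idx] = 800 + (other_idx % 300)
    df["bif_total"] = bif
    return df


# ---------------------------------------------------------------------------
# MAG collections


@dataclass
class MagSimConfig:
    """Parameters of the synthetic MAG-collection generator.

    Each species has an ancestral genome of `genes_per_genome` random genes;
    a deterministic fraction of its MAGs form a subclade derived from a
    diverged ancestor (`snp_rate_between`), every MAG then mutates at
    `snp_rate_within`.  A cassette of `cassette_size` extra genes — each its
    own orthologous group, sequence-distinct from the core — is included per
    MAG with subclade-dependent probability.  Completeness is simulated by
    uniform dropout of core genes to a level drawn from `completeness_range`
    (percent).
    """

    n_species: int = 3
    genes_per_genome: int = 60
    gene_length: int = 600
    n_mags_per_species: int = 40
    subclade_fraction: float = 0.4
    snp_rate_within: float = 0.002
    snp_rate_between: float = 0.02
    cassette_size: int = 15
    cassette_prevalence_in_subclade: float = 1.0
    cassette_prevalence_outside: float = 0.0
    completeness_range: tuple[float, float] = (85.0, 100.0)
    seed: int = 0

    def validate(self) -> None:
        for p in (
            self.subclade_fraction,
            self.cassette_prevalence_in_subclade,
            self.cassette_prevalence_outside,
            self.snp_rate_within,
            self.snp_rate_between,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if self.snp_rate_within > self.snp_rate_between:
            raise ValueError("snp_rate_within must not exceed snp_rate_between")
        lo, hi = self.completeness_range
        if not (0.0 < lo <= hi <= 100.0):
            raise ValueError("completeness_range must lie in (0, 100]")
        if min(self.n_species, self.genes_per_genome, self.gene_length, self.n_mags_per_species) <= 0:
            raise ValueError("sizes must be positive")


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _random_gene(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, length)]


def _mutate(rng: np.random.Generator, seq: np.ndarray, rate: float) -> np.ndarray:
    if rate <= 0:
        return seq.copy()
    out = seq.copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    if hits.size:
        # substitute with a uniformly random *different* base
        shift = rng.integers(1, 4, hits.size)
        cur = np.searchsorted(_BASES, out[hits])
        out[hits] = _BASES[(cur + shift) % 4]
    return out


def generate_mag_collection(
    config: MagSimConfig,
) -> tuple[list[MAGRecord], pd.DataFrame, GroundTruth]:
    """Simulate MAGs with a planted phage-like cassette.

    Returns the MAG records (gene id -> sequence), a gene-level annotation
    table (gene, og, cazy) and the planted truth (subclade flags, cassette
    OG ids, per-MAG cassette presence).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)

    cassette = [
        (f"cassette_{j:02d}", _random_gene(rng, config.gene_length), f"OG_phage{j:02d}")
        for j in range(config.cassette_size)
    ]

    mags: list[MAGRecord] = []
    ann_rows: list[tuple[str, str, str]] = []
    subclade_flags: dict[str, bool] = {}
    cassette_flags: dict[str, bool] = {}

    lo, hi = config.completeness_range
    n_sub = round(config.n_mags_per_species * config.subclade_fraction)
    for s in range(1, config.n_species + 1):
        core = []
        for g in range(config.genes_per_genome):
            name = f"sp{s}_core{g:03d}"
            og = f"OG_sp{s}_{g:03d}"
            cazy = f"GH{20 + 5 * s + g}" if g < 3 else "-"
            core.append((name, _random_gene(rng, config.gene_length), og, cazy))
        sub_ancestor = {name: _mutate(rng, seq, config.snp_rate_between) for name, seq, _, _ in core}

        for m in range(config.n_mags_per_species):
            mag_id = f"sp{s}_mag{m:03d}"
            in_sub = m < n_sub
            subclade_flags[mag_id] = in_sub
            completeness = float(rng.uniform(lo, hi))
            n_keep = max(1, round(completeness / 100.0 * config.genes_per_genome))
            keep = set(rng.choice(config.genes_per_genome, size=n_keep, replace=False))

            genes: dict[str, str] = {}
            for g, (name, seq, og, cazy) in enumerate(core):
                if g not in keep:
                    continue
                base = sub_ancestor[name] if in_sub else seq
                mut = _mutate(rng, base, config.snp_rate_within)
                gid = f"{mag_id}|{name}"
                genes[gid] = mut.tobytes().decode("ascii")
                ann_rows.append((gid, og, cazy))

            p_cas = (
                config.cassette_prevalence_in_subclade
                if in_sub
                else config.cassette_prevalence_outside
            )
            has_cassette = bool(rng.random() < p_cas)
            cassette_flags[mag_id] = has_cassette
            if has_cassette:
                for name, seq, og in cassette:
                    gid = f"{mag_id}|{name}"
                    genes[gid] = seq.tobytes().decode("ascii")
                    ann_rows.append((gid, og, "-"))

            mags.append(
                MAGRecord(
                    mag_id=mag_id,
                    sample_id=f"sp{s}_subj{m:03d}",
                    study_id="sim_mags",
                    species=f"Bifidobacterium_synthetic_sp{s}",
                    completeness=completeness,
                    genes=genes,
                )
            )

    annotations = pd.DataFrame(ann_rows, columns=["gene", "og", "cazy"])
    truth = GroundTruth(
        mag_subclade=pd.Series(subclade_flags),
        cassette_ogs=frozenset(og for _, _, og in cassette),
        cassette_in_mag=pd.Series(cassette_flags),
    )
    return mags, annotations, truth
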