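"""End-to-end orchestration: simulate → preprocess → partition → associate →
diffabund → pangenome → sketch, with one global seed, per-stage substreams
and a content-hashed manifest.

Each stage draws its randomness from ``stage_seed(global_seed, name)``
(a sha256-derived 31-bit substream), so toggling one stage never perturbs
another's stream and identical (config, seed) pairs yield byte-identical
manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, diffabund, dmm, pangenome, preprocess, sketch as sk, synthetic

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "default_demo_config"]

STAGES = ("simulate", "preprocess", "partition", "associate", "diffabund", "pangenome", "sketch")


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic 31-bit per-stage seed derived from the global seed."""
    digest = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All stage parameters; the defaults are the published analysis values
    (read floor 5e6, rarefaction depth 1e6, minimum genus total 500,
    k in [1, 30] with 5 fit / 3 vote seeds, catalog identity 0.95 /
    coverage 0.90, completeness floor 80, >= 30 MAGs per species,
    FDR 0.05 / 0.1, prevalence cutoff 0.25)."""

    out_dir: str = "pipeline_out"
    seed: int = 0
    stages: dict = field(default_factory=lambda: {s: True for s in STAGES})
    # simulate
    cohort: synthetic.CohortConfig = field(default_factory=synthetic.CohortConfig)
    mags: synthetic.MagSimConfig = field(default_factory=synthetic.MagSimConfig)
    # preprocess
    min_reads: int = 5_000_000
    rarefy_depth: int = 1_000_000
    min_bif_total: int = 500
    focal_genus: str = "Bifidobacterium"
    # partition
    k_range: tuple[int, int] = (1, 30)
    n_fit_seeds: int = 5
    n_vote_seeds: int = 3
    # associate
    health_threshold: float = 0.9
    # diffabund: contrasts between partition classes; "classes" tests pooled
    # health_associated vs other, "all-pairs" tests every partition pair
    contrasts: str = "classes"
    # pangenome
    catalog_identity: float = 0.95
    catalog_coverage: float = 0.90
    min_completeness: float = 80.0
    min_mags_per_species: int = 30
    marker_fdr: float = 0.05
    partition_fdr: float = 0.1
    prevalence_cutoff: float = 0.25
    # sketch
    kmer_size: int = 21
    sketch_size: int = 1000
    hash_seed: int = 42

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["dmm_components"] = [
            [float(w), [float(x) for x in np.asarray(a)]]
            for w, a in d["cohort"]["dmm_components"]
        ]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "cohort" in d and isinstance(d["cohort"], dict):
            c = dict(d["cohort"])
            if "dmm_components" in c:
                c["dmm_components"] = [(float(w), np.asarray(a, dtype=float)) for w, a in c["dmm_components"]]
            if "bif_depth_range" in c:
                c["bif_depth_range"] = tuple(c["bif_depth_range"])
            d["cohort"] = synthetic.CohortConfig(**c)
        if "mags" in d and isinstance(d["mags"], dict):
            m = dict(d["mags"])
            if "completeness_range" in m:
                m["completeness_range"] = tuple(m["completeness_range"])
            d["mags"] = synthetic.MagSimConfig(**m)
        if "k_range" in d:
            d["k_range"] = tuple(d["k_range"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def default_demo_config(out_dir: str = "pipeline_out", seed: int = 0) -> PipelineConfig:
    """A small configuration that exercises every stage in minutes."""
    cohort = synthetic.CohortConfig(
        n_samples=400,
        dmm_components=synthetic.default_components(k=3),
        n_background_taxa=20,
        zero_bif_fraction=0.05,
        health_control_fraction={1: 0.95, 2: 0.95, 3: 0.7, "no_bif": 0.7},
        partition_effects={p: synthetic.default_partition_effects()[1] for p in (1, 2)},
    )
    mags = synthetic.MagSimConfig(n_species=2, n_mags_per_species=36, genes_per_genome=40, gene_length=400)
    return PipelineConfig(
        out_dir=out_dir,
        seed=seed,
        cohort=cohort,
        mags=mags,
        rarefy_depth=2000,
        k_range=(1, 5),
        n_fit_seeds=3,
        n_vote_seeds=3,
        min_mags_per_species=20,
    )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_json(obj, path: Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=str)


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in order; return {relative path: sha256}."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(path: Path) -> None:
        written.append(path)

    on = {s: config.stages.get(s, True) for s in STAGES}

    table = metadata = truth = None
    mags = annotations = mag_truth = None

    # ---- simulate --------------------------------------------------------
    if on["simulate"]:
        ccfg = dataclasses.replace(config.cohort, seed=stage_seed(config.seed, "simulate"))
        table, metadata, truth = synthetic.generate_partitioned_cohort(ccfg)
        table.to_tsv(out / "counts.tsv", out / "taxonomy.tsv")
        metadata.to_csv(out / "metadata.tsv", sep="\t", index=False)
        truth.sample_component.rename("component").rename_axis("sample_id").to_csv(
            out / "truth_components.tsv", sep="\t"
        )
        emit(out / "counts.tsv"), emit(out / "taxonomy.tsv")
        emit(out / "metadata.tsv"), emit(out / "truth_components.tsv")

        mcfg = dataclasses.replace(config.mags, seed=stage_seed(config.seed, "simulate_mags"))
        mags, annotations, mag_truth = synthetic.generate_mag_collection(mcfg)
        pangenome.write_gene_fasta(mags, out / "mag_genes.fasta")
        annotations.to_csv(out / "annotations.tsv", sep="\t", index=False)
        pd.DataFrame(
            [
                {
                    "mag_id": m.mag_id,
                    "sample_id": m.sample_id,
                    "study_id": m.study_id,
                    "species": m.species,
                    "completeness": m.completeness,
                }
                for m in mags
            ]
        ).to_csv(out / "mag_metadata.tsv", sep="\t", index=False, float_format="%.6f")
        mag_truth.mag_subclade.rename("subclade").rename_axis("mag_id").to_csv(
            out / "truth_mag_subclade.tsv", sep="\t"
        )
        emit(out / "mag_genes.fasta"), emit(out / "annotations.tsv")
        emit(out / "mag_metadata.tsv"), emit(out / "truth_mag_subclade.tsv")
    if table is None:
        raise ValueError("pipeline currently requires the simulate stage for inputs")

    # ---- preprocess ------------------------------------------------------
    report = None
    diversity = None
    if on["preprocess"]:
        selected = preprocess.select_samples(metadata, min_reads=config.min_reads)
        sub = table.subset_samples(selected)
        genus = preprocess.collapse_by_genus(sub)
        genus.to_tsv(out / "genus_counts.tsv")
        emit(out / "genus_counts.tsv")

        bif = sub.genus_subtable(config.focal_genus)
        bif.to_tsv(out / "bif_counts.tsv")
        emit(out / "bif_counts.tsv")

        report = preprocess.dmm_eligibility_filter(
            metadata[metadata["sample_id"].isin(selected)],
            sub.genus_totals(config.focal_genus),
            min_total=config.min_bif_total,
        )
        _write_json(
            {
                "retained": report.retained,
                "zero_bif": report.zero_bif,
                "excluded": report.excluded,
            },
            out / "eligibility.json",
        )
        emit(out / "eligibility.json")

        rare, dropped = preprocess.rarefy(
            sub, depth=config.rarefy_depth, seed=stage_seed(config.seed, "preprocess")
        )
        div = {s: preprocess.shannon(rare.counts[s]) for s in rare.samples}
        diversity = pd.Series(div, name="shannon")
        diversity.rename_axis("sample_id").to_csv(out / "diversity.tsv", sep="\t", float_format="%.10g")
        emit(out / "diversity.tsv")

    # ---- partition -------------------------------------------------------
    assignment = None
    fit = None
    if on["partition"]:
        if report is None:
            raise ValueError("partition stage requires preprocess")
        bif = table.genus_subtable(config.focal_genus)
        fit_counts = bif.counts.loc[:, report.retained].T  # samples x species
        base = stage_seed(config.seed, "partition")
        k_sel, bic_table = dmm.select_k(
            fit_counts,
            k_range=config.k_range,
            n_fit_seeds=config.n_fit_seeds,
            n_vote_seeds=config.n_vote_seeds,
            seed=base,
        )
        bic_table.to_csv(out / "bic_table.tsv", sep="\t", float_format="%.10g")
        emit(out / "bic_table.tsv")

        # final fit: best BIC over the fit seeds at the selected k
        seeds = [(base + 1009 * i) % (2**31) for i in range(config.n_fit_seeds)]
        best = min(seeds, key=lambda s: bic_table.loc[k_sel, s])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = dmm.fit_dmm(fit_counts, k_sel, seed=best)
        fit.to_json(out / "dmm_fit.json")
        emit(out / "dmm_fit.json")

        assignment = dmm.assign_partitions(fit, fit_counts, zero_bif_ids=report.zero_bif)
        assignment.to_tsv(out / "assignments.tsv")
        emit(out / "assignments.tsv")

        contribs = dmm.scaled_contributions(fit)
        contribs.to_tsv(out / "contributions.tsv")
        emit(out / "contributions.tsv")
        names = dmm.name_partitions(contribs)
        _write_json({str(k): v for k, v in names.items()}, out / "partition_names.json")
        emit(out / "partition_names.json")

    # ---- associate -------------------------------------------------------
    classes = None
    if on["associate"]:
        if assignment is None:
            raise ValueError("associate stage requires partition")
        classes = association.classify_partitions_by_health(
            assignment.labels, metadata, threshold=config.health_threshold
        )
        _write_json({str(k): v for k, v in classes.items()}, out / "partition_classes.json")
        emit(out / "partition_classes.json")

        health = metadata.set_index("sample_id")["health_category"].reindex(assignment.labels.index)
        ct = pd.crosstab(assignment.labels.astype(str), health)
        stats = {}
        try:
            chi2, dof, p = association.chi_squared(ct.to_numpy())
            stats["partition_vs_health"] = {"chi2": chi2, "df": dof, "p": p}
        except ValueError as exc:
            stats["partition_vs_health"] = {"error": str(exc)}
        if diversity is not None:
            by_group = {}
            for part in pd.unique(assignment.labels):
                ids = [s for s in assignment.labels.index[assignment.labels == part] if s in diversity.index]
                if len(ids) >= 2:
                    by_group[str(part)] = diversity.loc[ids].to_numpy()
            if len(by_group) >= 2:
                try:
                    gc = association.kruskal_wallis(by_group, variable="shannon")
                    stats["shannon_vs_partition"] = {"H": gc.statistic, "p": gc.p}
                except ValueError as exc:
                    stats["shannon_vs_partition"] = {"error": str(exc)}
        _write_json(stats, out / "association_stats.json")
        emit(out / "association_stats.json")

    # ---- differential abundance -----------------------------------------
    if on["diffabund"]:
        if assignment is None or classes is None:
            raise ValueError("diffabund stage requires partition and associate")
        fitted = [s for s in assignment.labels.index if assignment.labels[s] != dmm.NO_BIF_LABEL]
        sub = table.subset_samples(fitted)
        keep = sub.counts.index[(sub.counts > 0).any(axis=1)]
        sub = preprocess.CountTable(sub.counts.loc[keep], table.taxonomy, validate=False)
        sf = diffabund.poscounts_size_factors(sub)
        labels = {s: str(assignment.labels[s]) for s in fitted}
        results = []
        if config.contrasts == "classes":
            cls_of = {s: classes[assignment.labels[s]] for s in fitted}
            results += diffabund.nb_wald_pairwise(sub, sf, cls_of, ("health_associated", "other"))
        else:
            parts = sorted({str(v) for v in labels.values()})
            for i in range(len(parts)):
                for j in range(i + 1, len(parts)):
                    results += diffabund.nb_wald_pairwise(sub, sf, labels, (parts[i], parts[j]))
        if len(set(labels.values())) >= 3:
            results += diffabund.nb_lrt_global(sub, sf, labels)
        diffabund.results_to_frame(results).to_csv(
            out / "diffabund.tsv", sep="\t", index=False, float_format="%.10g"
        )
        emit(out / "diffabund.tsv")

    # ---- pangenome -------------------------------------------------------
    presence = None
    qc = None
    mag_class = None
    if on["pangenome"]:
        if mags is None or classes is None or assignment is None:
            raise ValueError("pangenome stage requires simulate, partition and associate")
        all_genes = {g: s for m in mags for g, s in m.genes.items()}
        catalog = pangenome.cluster_genes(
            all_genes, identity=config.catalog_identity, coverage=config.catalog_coverage
        )
        catalog.to_tsv(out / "gene_catalog.tsv")
        emit(out / "gene_catalog.tsv")

        qc = pangenome.qc_filter_mags(
            mags,
            min_completeness=config.min_completeness,
            min_mags_per_species=config.min_mags_per_species,
        )
        presence = pangenome.og_presence(qc, catalog, annotations)

        # link each MAG to a donor subject: subclade MAGs draw their subject
        # from "other"-class partitions, the rest from health-associated ones
        rng = np.random.default_rng(stage_seed(config.seed, "pangenome"))
        fitted = [s for s in assignment.labels.index]
        health_subjects = [s for s in fitted if classes.get(assignment.labels[s]) == "health_associated"]
        other_subjects = [s for s in fitted if classes.get(assignment.labels[s]) == "other"]
        mag_class = {}
        link_rows = []
        for m in qc:
            sub_flag = bool(mag_truth.mag_subclade.get(m.mag_id, False)) if mag_truth is not None else False
            pool = other_subjects if sub_flag else health_subjects
            if not pool:
                pool = fitted
            subj = pool[int(rng.integers(0, len(pool)))]
            mag_class[m.mag_id] = classes.get(assignment.labels[subj], "other")
            link_rows.append({"mag_id": m.mag_id, "linked_sample": subj, "partition_class": mag_class[m.mag_id]})
        pd.DataFrame(link_rows).to_csv(out / "mag_links.tsv", sep="\t", index=False)
        emit(out / "mag_links.tsv")

        species_of = {m.mag_id: m.species for m in qc}
        markers = pangenome.species_marker_ogs(presence, species_of, fdr=config.marker_fdr)
        markers.to_csv(out / "species_marker_ogs.tsv", sep="\t", index=False, float_format="%.6g")
        emit(out / "species_marker_ogs.tsv")

        assoc = pangenome.partition_associated_ogs(
            presence, species_of, mag_class, fdr=config.partition_fdr
        )
        assoc.to_csv(out / "partition_ogs.tsv", sep="\t", index=False, float_format="%.6g")
        emit(out / "partition_ogs.tsv")
        selected = pangenome.asymmetric_prevalence_filter(assoc, cutoff=config.prevalence_cutoff)
        selected.to_csv(out / "phage_rule_ogs.tsv", sep="\t", index=False, float_format="%.6g")
        emit(out / "phage_rule_ogs.tsv")

    # ---- sketch ----------------------------------------------------------
    if on["sketch"]:
        if mags is None:
            raise ValueError("sketch stage requires simulate")
        pool = qc if qc else list(mags)
        counts: dict[str, int] = {}
        for m in pool:
            counts[m.species] = counts.get(m.species, 0) + 1
        focal = max(sorted(counts), key=lambda s: counts[s])
        focal_mags = [m for m in pool if m.species == focal]
        sketches = [
            sk.minhash_sketch(
                m.genes,
                mag_id=m.mag_id,
                kmer_size=config.kmer_size,
                sketch_size=config.sketch_size,
                hash_seed=config.hash_seed,
            )
            for m in focal_mags
        ]
        dmat = sk.pairwise_mash(sketches)
        dmat.to_tsv(out / "mash_distances.tsv")
        emit(out / "mash_distances.tsv")
        dend = sk.ward2_cluster(dmat)
        (out / "dendrogram.nwk").write_text(sk.to_newick(dend) + "\n")
        emit(out / "dendrogram.nwk")

        og_flags = None
        if presence is not None and mag_truth is not None and mag_truth.cassette_ogs:
            cas = [o for o in sorted(mag_truth.cassette_ogs) if o in presence.columns]
            if cas:
                og_flags = presence.loc[[m.mag_id for m in focal_mags if m.mag_id in presence.index], cas]
        mat, ann = sk.annotate_heatmap_export(dmat, og_flags, mag_class)
        mat.rename_axis("mag_id").to_csv(out / "heatmap_matrix.tsv", sep="\t", float_format="%.10g")
        ann.rename_axis("mag_id").to_csv(out / "heatmap_annotations.tsv", sep="\t")
        emit(out / "heatmap_matrix.tsv"), emit(out / "heatmap_annotations.tsv")

    manifest = {str(p.relative_to(out)): _sha256(p) for p in sorted(set(written))}
    _write_json(manifest, out / "manifest.json")
    return manifest
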