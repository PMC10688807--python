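"""Nonredundant gene catalogs and gene-prevalence analysis of MAG collections.

A gene catalog is built by greedy incremental clustering: sequences are
visited in order of decreasing length (ties by id) and each joins the first
existing representative it matches at >= 95% nucleotide identity with >= 90%
coverage of the shorter sequence, otherwise it founds a new cluster.  A
shared-16-mer prefilter is a pure speed-up: at the default thresholds two
matching sequences must share at least one exact 16-mer, so skipping
candidates without one never changes the result.

Downstream, MAGs are quality-filtered (completeness strictly > 80%, species
with >= 30 surviving MAGs), orthologous-group (OG) presence/absence is
summarised per group, and chi-squared tests (BH-adjusted within species)
flag species-marker OGs and OGs associated with health-associated community
partitions, including the asymmetric-prevalence rule used to isolate
phage-like cassettes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import edlib
import numpy as np
import pandas as pd
from scipy.stats import chi2 as chi2_dist

__all__ = [
    "MAGRecord",
    "GeneCatalog",
    "cluster_genes",
    "qc_filter_mags",
    "og_presence",
    "og_prevalence",
    "species_marker_ogs",
    "partition_associated_ogs",
    "asymmetric_prevalence_filter",
    "write_gene_fasta",
    "read_gene_fasta",
]


@dataclass
class MAGRecord:
    """A metagenome-assembled genome: identity, QC fields and gene content."""

    mag_id: str
    sample_id: str
    study_id: str
    species: str
    completeness: float  # percent, in (0, 100]
    genes: dict[str, str] = field(default_factory=dict)  # gene id -> nucleotide sequence

    def __post_init__(self):
        if not 0.0 < self.completeness <= 100.0:
            raise ValueError("completeness must be in (0, 100]")


@dataclass
class GeneCatalog:
    """Clusters of a nonredundant gene catalog (representative -> members)."""

    clusters: dict[str, list[str]]
    identity: float
    coverage: float

    @property
    def gene_to_rep(self) -> dict[str, str]:
        return {g: rep for rep, members in self.clusters.items() for g in members}

    def to_tsv(self, path) -> None:
        rows = [(rep, g) for rep, members in sorted(self.clusters.items()) for g in members]
        pd.DataFrame(rows, columns=["representative", "member"]).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# FASTA I/O (headers are ``magID|geneID``)


def write_gene_fasta(mags: Iterable[MAGRecord], path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=gid, description="")
        for mag in mags
        for gid, seq in mag.genes.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_gene_fasta(path) -> dict[str, str]:
    from Bio.SeqIO import parse as seqio_parse

    return {rec.id: str(rec.seq).upper() for rec in seqio_parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# greedy catalog clustering


def _kmer_set(seq: str, k: int = 16) -> set[str]:
    return {seq[i : i + k] for i in range(0, len(seq) - k + 1)}


def _align_stats(shorter: str, longer: str) -> tuple[float, float]:
    """(identity, coverage-of-shorter) from a semi-global alignment.

    The shorter sequence is aligned end-to-end against the best-matching
    region of the longer one (free end gaps on the longer sequence only).
    Identity is matches / alignment columns; coverage is the fraction of
    shorter-sequence bases aligned against a base of the longer sequence.
    """
    res = edlib.align(shorter, longer, mode="HW", task="path")
    cigar = res["cigar"]
    if cigar is None:  # pragma: no cover - edlib always returns a path here
        return 0.0, 0.0
    matches = mismatches = q_gap = t_gap = 0
    num = ""
    for ch in cigar:
        if ch.isdigit():
            num += ch
            continue
        L = int(num)
        num = ""
        if ch == "=":
            matches += L
        elif ch == "X":
            mismatches += L
        elif ch == "I":  # consumes query (shorter) only
            q_gap += L
        elif ch == "D":  # consumes target (longer) only
            t_gap += L
    columns = matches + mismatches + q_gap + t_gap
    identity = matches / columns if columns else 0.0
    aligned_bases = matches + mismatches
    coverage = aligned_bases / len(shorter) if shorter else 0.0
    return identity, coverage


def cluster_genes(
    sequences: Mapping[str, str],
    identity: float = 0.95,
    coverage: float = 0.90,
    prefilter: bool = True,
) -> GeneCatalog:
    """Greedy incremental clustering of nucleotide sequences.

    Sequences are sorted by decreasing length (ties by id); each joins the
    first representative whose alignment reaches the identity and
    shorter-sequence coverage thresholds, else founds a new cluster.
    Non-ACGT symbols are treated as mismatches by the aligner.
    """
    order = sorted(sequences, key=lambda g: (-len(sequences[g]), g))
    reps: list[str] = []
    rep_kmers: list[set[str]] = []
    clusters: dict[str, list[str]] = {}
    exact: dict[str, str] = {}  # sequence -> representative shortcut

    for gid in order:
        seq = sequences[gid].upper()
        if not seq:
            raise ValueError(f"empty sequence: {gid}")
        hit = exact.get(seq)
        if hit is None:
            kmers = _kmer_set(seq) if prefilter else None
            for ri, rep in enumerate(reps):
                rseq = sequences[rep].upper()
                # a >=95%-identity, >=90%-coverage match over >=100 bp must
                # share an exact 16-mer, so this skip cannot change results
                if (
                    prefilter
                    and len(seq) >= 100
                    and kmers is not None
                    and rep_kmers[ri] is not None
                    and kmers.isdisjoint(rep_kmers[ri])
                ):
                    continue
                shorter, longer = (seq, rseq) if len(seq) <= len(rseq) else (rseq, seq)
                ident, cov = _align_stats(shorter, longer)
                if ident >= identity and cov >= coverage:
                    hit = rep
                    break
        if hit is None:
            reps.append(gid)
            rep_kmers.append(_kmer_set(seq) if prefilter else None)
            clusters[gid] = [gid]
            exact.setdefault(seq, gid)
        else:
            clusters[hit].append(gid)
    return GeneCatalog(clusters=clusters, identity=identity, coverage=coverage)


# ---------------------------------------------------------------------------
# MAG QC and OG prevalence


def qc_filter_mags(
    mags: Iterable[MAGRecord],
    min_completeness: float = 80.0,
    min_mags_per_species: int = 30,
) -> list[MAGRecord]:
    """Completeness strictly above the floor, then species with enough MAGs."""
    passing = [m for m in mags if m.completeness > min_completeness]
    counts: dict[str, int] = {}
    for m in passing:
        counts[m.species] = counts.get(m.species, 0) + 1
    return [m for m in passing if counts[m.species] >= min_mags_per_species]


def _gene_og_map(catalog: GeneCatalog, annotations: pd.DataFrame) -> dict[str, str]:
    """Gene -> OG, propagating the representative's annotation to members."""
    ann = annotations.set_index("gene")["og"]
    out: dict[str, str] = {}
    for rep, members in catalog.clusters.items():
        og = ann.get(rep)
        if og is None or og == "-" or (isinstance(og, float) and np.isnan(og)):
            # fall back to any annotated member
            for g in members:
                cand = ann.get(g)
                if cand is not None and cand != "-":
                    og = cand
                    break
        if og is None or og == "-":
            continue
        for g in members:
            out[g] = og
    return out


def og_presence(
    mags: Iterable[MAGRecord], catalog: GeneCatalog, annotations: pd.DataFrame
) -> pd.DataFrame:
    """Boolean MAG × OG presence matrix (>=1 gene of the MAG maps to the OG)."""
    gene_og = _gene_og_map(catalog, annotations)
    mags = list(mags)
    ogs = sorted(set(gene_og.values()))
    og_ix = {o: j for j, o in enumerate(ogs)}
    mat = np.zeros((len(mags), len(ogs)), dtype=bool)
    for i, mag in enumerate(mags):
        for g in mag.genes:
            og = gene_og.get(g)
            if og is not None:
                mat[i, og_ix[og]] = True
    return pd.DataFrame(mat, index=[m.mag_id for m in mags], columns=ogs)


def og_prevalence(presence: pd.DataFrame, grouping: Mapping[str, str]) -> pd.DataFrame:
    """OG × group prevalence (fraction of the group's MAGs carrying the OG)."""
    groups = pd.Series({m: grouping[m] for m in presence.index})
    out = {}
    for g, idx in groups.groupby(groups).groups.items():
        if len(idx) == 0:
            raise ValueError(f"empty group {g}")
        out[g] = presence.loc[idx].mean(axis=0)
    if not out:
        raise ValueError("no groups")
    return pd.DataFrame(out)


def _chi2_2x2(a: int, b: int, c: int, d: int) -> tuple[float, float] | None:
    """Pearson chi-squared (1 df, no continuity correction) on [[a,b],[c,d]].

    Returns None when a margin is zero or any expected count is below 1
    (small-count rule: the test is skipped and reported upstream).
    """
    obs = np.array([[a, b], [c, d]], dtype=float)
    rs, cs, n = obs.sum(1), obs.sum(0), obs.sum()
    if (rs == 0).any() or (cs == 0).any():
        return None
    exp = np.outer(rs, cs) / n
    if (exp < 1.0).any():
        return None
    stat = float(((obs - exp) ** 2 / exp).sum())
    p = float(chi2_dist.sf(stat, 1))
    return stat, p


def species_marker_ogs(
    presence: pd.DataFrame,
    species: Mapping[str, str],
    fdr: float = 0.05,
) -> pd.DataFrame:
    """OGs whose prevalence separates one species from the rest.

    For each species s and OG o: chi-squared on the 2x2 table
    (MAG in s / not) x (o present / absent), BH-adjusted within species;
    rows with q < `fdr` are flagged ``selected``.  Degenerate tables are
    skipped (reported via the `tested` column).
    """
    from .diffabund import bh_adjust

    sp = pd.Series({m: species[m] for m in presence.index})
    rows = []
    for s in sorted(sp.unique()):
        in_s = presence.loc[sp[sp == s].index]
        out_s = presence.loc[sp[sp != s].index]
        if len(out_s) == 0:
            warnings.warn(f"species {s} has no comparison MAGs; skipped")
            continue
        stats, ps, metas = [], [], []
        for og in presence.columns:
            a = int(in_s[og].sum())
            b = len(in_s) - a
            c = int(out_s[og].sum())
            d = len(out_s) - c
            res = _chi2_2x2(a, b, c, d)
            metas.append((og, a / len(in_s), c / len(out_s), res is not None))
            if res is None:
                stats.append(np.nan)
                ps.append(np.nan)
            else:
                stats.append(res[0])
                ps.append(res[1])
        qs = bh_adjust(ps)
        for (og, prev_in, prev_out, tested), stat, p, q in zip(metas, stats, ps, qs):
            rows.append(
                {
                    "species": s,
                    "og": og,
                    "prev_in_species": prev_in,
                    "prev_other": prev_out,
                    "chi2": stat,
                    "p": p,
                    "q": q,
                    "tested": tested,
                    "selected": bool(tested and q < fdr),
                }
            )
    return pd.DataFrame(rows)


def partition_associated_ogs(
    presence: pd.DataFrame,
    species: Mapping[str, str],
    partition_class: Mapping[str, str],
    fdr: float = 0.1,
) -> pd.DataFrame:
    """OGs associated with health-associated vs other community partitions.

    Each MAG carries its donor subject's partition class
    (``health_associated`` / ``other``); MAGs without a class are dropped.
    Within each species having both classes, OG presence x class is tested
    by chi-squared with BH adjustment within species; q < `fdr` flags the OG.
    """
    from .diffabund import bh_adjust

    keep = [m for m in presence.index if partition_class.get(m) in ("health_associated", "other")]
    presence = presence.loc[keep]
    sp = pd.Series({m: species[m] for m in keep})
    cls = pd.Series({m: partition_class[m] for m in keep})

    rows = []
    for s in sorted(sp.unique()):
        mags_s = sp[sp == s].index
        cls_s = cls.loc[mags_s]
        health = presence.loc[cls_s[cls_s == "health_associated"].index]
        other = presence.loc[cls_s[cls_s == "other"].index]
        if len(health) == 0 or len(other) == 0:
            warnings.warn(f"species {s} has MAGs in only one partition class; skipped")
            continue
        stats, ps, metas = [], [], []
        for og in presence.columns:
            a = int(health[og].sum())
            b = len(health) - a
            c = int(other[og].sum())
            d = len(other) - c
            res = _chi2_2x2(a, b, c, d)
            metas.append((og, a / len(health), c / len(other), res is not None))
            if res is None:
                stats.append(np.nan)
                ps.append(np.nan)
            else:
                stats.append(res[0])
                ps.append(res[1])
        qs = bh_adjust(ps)
        for (og, prev_h, prev_o, tested), stat, p, q in zip(metas, stats, ps, qs):
            rows.append(
                {
                    "species": s,
                    "og": og,
                    "prev_health_associated": prev_h,
                    "prev_other": prev_o,
                    "chi2": stat,
                    "p": p,
                    "q": q,
                    "tested": tested,
                    "selected": bool(tested and q < fdr),
                }
            )
    return pd.DataFrame(rows)


def asymmetric_prevalence_filter(results: pd.DataFrame, cutoff: float = 0.25) -> pd.DataFrame:
    """OGs depleted from health-associated partitions but common elsewhere.

    Keeps flagged OGs with prevalence < `cutoff` among health-associated
    MAGs AND > `cutoff` among the others (the phage-cassette selection rule).
    """
    if results.empty:
        return results
    sel = results[
        results["selected"]
        & (results["prev_health_associated"] < cutoff)
        & (results["prev_other"] > cutoff)
    ]
    return sel.reset_index(drop=True)
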