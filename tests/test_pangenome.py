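import numpy as np
import pandas as pd
import pytest

from bifidopart.pangenome import (
    MAGRecord,
    asymmetric_prevalence_filter,
    cluster_genes,
    og_presence,
    og_prevalence,
    partition_associated_ogs,
    qc_filter_mags,
    species_marker_ogs,
)
from bifidopart.synthetic import MagSimConfig, generate_mag_collection


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), n))


def _mutate(rng, seq, rate):
    out = list(seq)
    for i in range(len(out)):
        if rng.random() < rate:
            out[i] = rng.choice([b for b in "ACGT" if b != out[i]])
    return "".join(out)


# ---------------------------------------------------------------------------
# independent alignment oracle built on Biopython


def _oracle_identity_coverage(shorter, longer):
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -1
    # free end gaps on the longer sequence (semi-global)
    aligner.target_left_open_gap_score = 0
    aligner.target_left_extend_gap_score = 0
    aligner.target_right_open_gap_score = 0
    aligner.target_right_extend_gap_score = 0
    aln = aligner.align(shorter, longer)[0]
    sq, st = aln[0], aln[1]
    # trim columns where the *longer* (target) sequence runs beyond the match
    start = 0
    while sq[start] == "-":
        start += 1
    end = len(sq)
    while sq[end - 1] == "-":
        end -= 1
    matches = mism = qgap = tgap = 0
    for cq, ct in zip(sq[start:end], st[start:end]):
        if cq == "-":
            tgap += 1
        elif ct == "-":
            qgap += 1
        elif cq == ct:
            matches += 1
        else:
            mism += 1
    cols = matches + mism + qgap + tgap
    identity = matches / cols if cols else 0.0
    coverage = (matches + mism) / len(shorter)
    return identity, coverage


def _oracle_greedy(sequences, identity=0.95, coverage=0.90):
    order = sorted(sequences, key=lambda g: (-len(sequences[g]), g))
    clusters = {}
    for gid in order:
        seq = sequences[gid]
        hit = None
        for rep in clusters:
            rseq = sequences[rep]
            shorter, longer = (seq, rseq) if len(seq) <= len(rseq) else (rseq, seq)
            ident, cov = _oracle_identity_coverage(shorter, longer)
            if ident >= identity and cov >= coverage:
                hit = rep
                break
        if hit is None:
            clusters[gid] = [gid]
        else:
            clusters[hit].append(gid)
    return clusters


class TestClusterGenes:
    def test_identical_sequences_one_cluster(self, rng):
        s = _random_seq(rng, 300)
        cat = cluster_genes({"g1": s, "g2": s})
        assert len(cat.clusters) == 1

    def test_exact_substring_joins(self, rng):
        s = _random_seq(rng, 1000)
        cat = cluster_genes({"long": s, "short": s[50:900]})
        assert len(cat.clusters) == 1

    def test_diverged_copy_below_identity_splits(self, rng):
        s = _random_seq(rng, 1000)
        diverged = _mutate(np.random.default_rng(1), s, 0.10)
        cat = cluster_genes({"a": s, "b": diverged})
        assert len(cat.clusters) == 2

    def test_matches_all_pairs_alignment_oracle(self):
        rng = np.random.default_rng(3)
        seqs = {}
        for i in range(12):
            base = _random_seq(rng, int(rng.integers(200, 400)))
            seqs[f"base{i:02d}"] = base
            # a close copy, a fragment, and occasionally a diverged copy
            seqs[f"copy{i:02d}"] = _mutate(rng, base, 0.02)
            if i % 3 == 0:
                seqs[f"frag{i:02d}"] = base[: int(0.95 * len(base))]
            if i % 4 == 0:
                seqs[f"far{i:02d}"] = _mutate(rng, base, 0.12)
        assert len(seqs) >= 30
        cat = cluster_genes(seqs)
        oracle = _oracle_greedy(seqs)

        def membership(clusters):
            return sorted(frozenset(v) for v in clusters.values())

        assert membership(cat.clusters) == membership(oracle)

    def test_prefilter_never_changes_results(self, rng):
        seqs = {}
        for i in range(10):
            base = _random_seq(rng, 250)
            seqs[f"b{i}"] = base
            seqs[f"c{i}"] = _mutate(np.random.default_rng(i), base, 0.03)
        with_f = cluster_genes(seqs, prefilter=True)
        without = cluster_genes(seqs, prefilter=False)
        assert with_f.clusters == without.clusters

    def test_clusters_partition_input(self, small_mags):
        mags, _, _ = small_mags
        seqs = {g: s for m in mags[:10] for g, s in m.genes.items()}
        cat = cluster_genes(seqs)
        members = [g for v in cat.clusters.values() for g in v]
        assert sorted(members) == sorted(seqs)

    def test_empty_input(self):
        assert cluster_genes({}).clusters == {}


class TestQCFilter:
    @staticmethod
    def _mag(mid, species, completeness):
        return MAGRecord(mid, f"samp_{mid}", "study", species, completeness, {f"{mid}|g": "ACGT"})

    def test_completeness_boundary_is_strict(self):
        mags = [self._mag(f"m{i}", "sp1", 80.0) for i in range(40)]
        assert qc_filter_mags(mags) == []

    def test_species_mag_count_threshold(self):
        mags29 = [self._mag(f"a{i}", "sp1", 90.0) for i in range(29)]
        mags30 = [self._mag(f"b{i}", "sp2", 90.0) for i in range(30)]
        out = qc_filter_mags(mags29 + mags30)
        assert {m.species for m in out} == {"sp2"}
        assert len(out) == 30

    def test_matches_direct_filter_oracle(self, small_mags):
        mags, _, _ = small_mags
        out = qc_filter_mags(mags, min_completeness=80, min_mags_per_species=30)
        passing = [m for m in mags if m.completeness > 80]
        from collections import Counter

        sp = Counter(m.species for m in passing)
        oracle = [m for m in passing if sp[m.species] >= 30]
        assert [m.mag_id for m in out] == [m.mag_id for m in oracle]


@pytest.fixture(scope="module")
def planted_presence():
    """QC'd presence matrix and truth for the default planted collection."""
    cfg = MagSimConfig(
        n_species=2,
        n_mags_per_species=32,
        genes_per_genome=40,
        gene_length=400,
        completeness_range=(100.0, 100.0),
        seed=5,
    )
    mags, annotations, truth = generate_mag_collection(cfg)
    seqs = {g: s for m in mags for g, s in m.genes.items()}
    catalog = cluster_genes(seqs)
    qc = qc_filter_mags(mags)
    presence = og_presence(qc, catalog, annotations)
    species = {m.mag_id: m.species for m in qc}
    return presence, species, truth


class TestOGPrevalence:
    def test_planted_cassette_prevalence_exact(self, planted_presence):
        presence, species, truth = planted_presence
        grouping = {m: ("sub" if truth.mag_subclade[m] else "main") for m in presence.index}
        prev = og_prevalence(presence, grouping)
        for og in truth.cassette_ogs:
            assert prev.loc[og, "sub"] == 1.0
            assert prev.loc[og, "main"] == 0.0

    def test_core_ogs_everywhere_in_species(self, planted_presence):
        presence, species, _ = planted_presence
        prev = og_prevalence(presence, species)
        sp = sorted(set(species.values()))[0]
        core = [c for c in presence.columns if c.startswith("OG_sp1_")]
        assert np.allclose(prev.loc[core, sp], 1.0)

    def test_duplicated_gene_does_not_change_prevalence(self, small_mags):
        mags, annotations, _ = small_mags
        sub = mags[:6]
        seqs = {g: s for m in sub for g, s in m.genes.items()}
        catalog = cluster_genes(seqs)
        p1 = og_presence(sub, catalog, annotations)
        # duplicate one gene inside the first MAG
        import copy

        dup = copy.deepcopy(sub)
        g0, s0 = next(iter(dup[0].genes.items()))
        dup[0].genes[g0 + "_dup"] = s0
        ann2 = pd.concat(
            [annotations, pd.DataFrame([{"gene": g0 + "_dup", "og": "ignored", "cazy": "-"}])]
        )
        catalog2 = cluster_genes({g: s for m in dup for g, s in m.genes.items()})
        p2 = og_presence(dup, catalog2, ann2)
        pd.testing.assert_frame_equal(p1, p2.loc[p1.index, p1.columns])


class TestSpeciesMarkers:
    def test_full_split_is_significant(self):
        mags = [f"a{i}" for i in range(50)] + [f"b{i}" for i in range(50)]
        presence = pd.DataFrame(
            {"OG_X": [True] * 50 + [False] * 50, "OG_Y": [True] * 100}, index=mags
        )
        species = {m: ("spA" if m.startswith("a") else "spB") for m in mags}
        res = species_marker_ogs(presence, species)
        row = res[(res.species == "spA") & (res.og == "OG_X")].iloc[0]
        assert row.q < 0.05 and row.selected

    def test_equal_prevalence_not_selected(self):
        rng = np.random.default_rng(0)
        mags = [f"m{i}" for i in range(80)]
        presence = pd.DataFrame({"OG_X": rng.random(80) < 0.5}, index=mags)
        species = {m: ("spA" if i < 40 else "spB") for i, m in enumerate(mags)}
        res = species_marker_ogs(presence, species)
        assert not res["selected"].any()

    def test_planted_markers_recovered(self, planted_presence):
        presence, species, truth = planted_presence
        res = species_marker_ogs(presence, species)
        # species-1 core OGs are absent from species 2 and vice versa
        sp1 = sorted(set(species.values()))[0]
        sel = set(res[(res.species == sp1) & res.selected]["og"])
        core1 = {c for c in presence.columns if c.startswith("OG_sp1_")}
        assert core1 <= sel


class TestPartitionAssociation:
    def test_extreme_association_flagged(self):
        mags = [f"h{i}" for i in range(40)] + [f"o{i}" for i in range(40)]
        presence = pd.DataFrame({"OG_X": [False] * 40 + [True] * 30 + [False] * 10}, index=mags)
        species = {m: "sp" for m in mags}
        cls = {m: ("health_associated" if m.startswith("h") else "other") for m in mags}
        res = partition_associated_ogs(presence, species, cls)
        assert res.iloc[0].selected

    def test_balanced_og_not_flagged(self):
        mags = [f"h{i}" for i in range(40)] + [f"o{i}" for i in range(40)]
        presence = pd.DataFrame({"OG_X": ([True, False] * 40)}, index=mags)
        species = {m: "sp" for m in mags}
        cls = {m: ("health_associated" if m.startswith("h") else "other") for m in mags}
        res = partition_associated_ogs(presence, species, cls)
        assert not res.iloc[0].selected

    def test_unclassified_mags_dropped(self):
        mags = [f"h{i}" for i in range(10)] + [f"o{i}" for i in range(10)] + ["x0"]
        presence = pd.DataFrame({"OG_X": [False] * 10 + [True] * 10 + [True]}, index=mags)
        species = {m: "sp" for m in mags}
        cls = {m: ("health_associated" if m.startswith("h") else "other") for m in mags[:-1]}
        res = partition_associated_ogs(presence, species, cls)
        assert res.iloc[0]["prev_other"] == 1.0  # the unlinked MAG did not count

    def test_planted_cassette_flagged(self, planted_presence):
        presence, species, truth = planted_presence
        cls = {m: ("other" if truth.mag_subclade[m] else "health_associated") for m in presence.index}
        res = partition_associated_ogs(presence, species, cls)
        flagged = set(res[res.selected]["og"])
        assert set(truth.cassette_ogs) <= flagged

    def test_null_false_positive_rate_respects_fdr(self):
        # no class/OG association: fraction of replicates with any selection
        # should be near the per-family BH level
        rng = np.random.default_rng(12)
        n_rep, families_hit, families = 20, 0, 0
        for _ in range(n_rep):
            mags = [f"m{i}" for i in range(60)]
            presence = pd.DataFrame(
                rng.random((60, 30)) < 0.5, index=mags, columns=[f"OG{j}" for j in range(30)]
            )
            species = {m: "sp" for m in mags}
            cls = {m: ("health_associated" if i < 30 else "other") for i, m in enumerate(mags)}
            res = partition_associated_ogs(presence, species, cls)
            families += 1
            families_hit += bool(res["selected"].any())
        assert families_hit / families <= 0.25  # nominal 0.1 per family


class TestAsymmetricFilter:
    @staticmethod
    def _frame(prev_h, prev_o, selected=True):
        return pd.DataFrame(
            [
                {
                    "species": "sp",
                    "og": "OG_X",
                    "prev_health_associated": prev_h,
                    "prev_other": prev_o,
                    "chi2": 1.0,
                    "p": 0.01,
                    "q": 0.01,
                    "tested": True,
                    "selected": selected,
                }
            ]
        )

    def test_both_conditions_hold(self):
        assert len(asymmetric_prevalence_filter(self._frame(0.10, 0.60))) == 1

    def test_health_prevalence_too_high(self):
        assert len(asymmetric_prevalence_filter(self._frame(0.30, 0.60))) == 0

    def test_other_prevalence_too_low(self):
        assert len(asymmetric_prevalence_filter(self._frame(0.10, 0.20))) == 0

    def test_unselected_rows_never_pass(self):
        assert len(asymmetric_prevalence_filter(self._frame(0.10, 0.60, selected=False))) == 0
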