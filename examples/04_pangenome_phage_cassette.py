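"""Find a planted phage-like gene cassette through the full pangenome chain:
gene-catalog clustering -> MAG QC -> OG presence -> chi-squared association
with partition classes -> asymmetric prevalence filter.

The generator plants a 15-gene cassette carried by a subclade of each
species; subclade MAGs are linked to 'other'-class subjects, so the filter
should return exactly the 15 cassette OGs.
"""

from bifidopart import (
    asymmetric_prevalence_filter,
    cluster_genes,
    og_presence,
    partition_associated_ogs,
    qc_filter_mags,
)
from bifidopart.synthetic import MagSimConfig, generate_mag_collection

cfg = MagSimConfig(
    n_species=2,
    n_mags_per_species=32,
    genes_per_genome=40,
    gene_length=400,
    cassette_size=15,
    completeness_range=(100.0, 100.0),
    seed=77,
)
mags, annotations, truth = generate_mag_collection(cfg)

seqs = {g: s for m in mags for g, s in m.genes.items()}
catalog = cluster_genes(seqs, identity=0.95, coverage=0.90)
print(f"gene catalog: {len(seqs)} genes -> {len(catalog.clusters)} nonredundant clusters")

qc = qc_filter_mags(mags, min_completeness=80, min_mags_per_species=30)
presence = og_presence(qc, catalog, annotations)
species = {m.mag_id: m.species for m in qc}
classes = {m: ("other" if truth.mag_subclade[m] else "health_associated") for m in presence.index}

assoc = partition_associated_ogs(presence, species, classes, fdr=0.1)
selected = asymmetric_prevalence_filter(assoc, cutoff=0.25)
print(f"OGs associated with partition class (q < 0.1): {assoc.loc[assoc['selected'], 'og'].nunique()}")
print(f"OGs passing the asymmetric <25%/>25% prevalence rule: {selected['og'].nunique()}")
print("selected OGs:", sorted(set(selected["og"])))
print("planted cassette recovered:", set(selected["og"]) == set(truth.cassette_ogs))
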