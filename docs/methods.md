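# Methods

`bifidopart` re-implements, as a tested library, a genus-restricted community
typing workflow for the human gut: species counts of one genus
(*Bifidobacterium*) are modelled with a Dirichlet-multinomial mixture (DMM),
samples are assigned to partitions, and the partitions are related to host
metadata, to the rest of the microbiome (negative-binomial differential
abundance) and to the gene content of metagenome-assembled genomes (MAGs)
via a nonredundant gene catalog, MinHash genome distances and Ward.D2
clustering.  Because the workflow is meant to be testable without external
downloads, a first-class synthetic-data module generates cohorts, metadata
and MAG collections with known ground truth.

## The mixture model and its fit

A sample's species counts x (S species, depth n) are modelled as

    P(x) = Σ_k π_k · DM(x | α_k),
    DM(x | α) = n!/Π x_j! · Γ(A)/Γ(n+A) · Π_j Γ(x_j+α_j)/Γ(α_j),  A = Σ_j α_j.

The log density is evaluated with log-gamma throughout; an all-zero count
vector is given probability one but such samples never enter the fit — they
are set aside by the eligibility filter and attached afterwards as a
dedicated `no_Bif` class.

Fitting is EM.  The E-step computes responsibilities from the current
mixture; the M-step sets π to the mean responsibility and updates each
component's α by Minka-style fixed-point iteration on the
responsibility-weighted DM likelihood (a generalised EM step; three inner
sweeps per outer iteration, positivity floor 1e-10).  Because a generalised
M-step does not guarantee monotonicity by itself, a backtracking safeguard
interpolates the update toward the previous parameters (geometric mean in α,
arithmetic in π) whenever the observed-data log-likelihood would decrease;
the tests assert monotonicity on the recorded history.  Initialisation is
k-means (seeded, k-means++ starts) on centred log-ratio compositions with a
0.5 pseudocount, followed by a moment-matched Dirichlet start.  For k > 1
the EM is multi-started: four k-means initialisations each receive three
short EM sweeps and the best is continued — a standard small-EM defence
against local optima that empirically removes most spurious BIC minima at
the true k.  A component whose total responsibility falls below 1e-6·n is
reseeded from a random sample once, then allowed to die.

Convergence: |Δ log-likelihood| < tol (default 1e-3) or 200 iterations.
BIC = −2·loglik + p·ln(n_samples) with p = (k−1) + k·S free parameters.

### Choosing k

`select_k` fits every k in a range (default [1, 30]) under each of five
seeds, records the BIC table, takes the argmin-BIC k of the first three
seeds and returns the majority vote, breaking ties toward the smaller k.
The two seed counts are separate parameters because fit-stability and
vote-stability are distinct concerns.  On synthetic cohorts with six
well-separated components over 32 species (2,000 samples, depths uniform on
[1,000, 20,000]) the protocol selects k = 6; the acceptance script
recomputes this from scratch.

### Contributions and names

The expected within-component composition is c_kj = α_kj / Σ_j α_kj.  For
display, each species column is scaled by its maximum over components, so
the component in which a species is most abundant scores 1; entries with
α < 1e-5 are masked (the optimisation floor, 1e-10, is deliberately far
below the display mask).  Scaling per species rather than per partition is
a convention choice; it makes the dominant partition of every species
identifiable at a glance.  Partitions are named by joining the 3-letter
abbreviations of their top species (at most three, compositions below 5%
truncated), e.g. `ado_lon`; the zero-count class is always `no_Bif`.

## Cohort bookkeeping

* Sample selection keeps stool metagenomes with strictly more than 5×10⁶
  reads, drops one duplicated study, and retains per subject the sample
  with the most reads (ties to the lexicographically smallest sample id).
* Genus collapse sums species rows; column sums are conserved exactly.
* Rarefaction (for alpha-diversity only) is exact multivariate
  hypergeometric subsampling to 10⁶ counts; samples below the depth are
  dropped from the diversity analysis but never from partitioning.
* Shannon diversity uses natural logarithms (the base is a convention; no
  published value here depends on it).
* Ages bin as newborn < 1, child [1, 12), school age [12, 19),
  senior > 65, adult otherwise — the senior rule takes precedence over the
  overlapping adult definition.
* Health labels map onto {control, adenoma, colorectal, metabolic, bowel,
  arthritis, unknown} through a configurable dictionary (IBD → bowel;
  T2D/hypertension/ACVD/hypercholesterolemia/IGT → metabolic; rheumatoid
  arthritis and Behçet's disease → arthritis; unmapped → unknown with a
  warning).
* The mixture-eligibility filter removes antibiotic users *and* subjects
  with unknown antibiotic status, then subjects with genus totals in
  (0, 500) (underdetection), and sets zero-total subjects aside as
  `no_Bif`.  Excluding unknowns is the only reading consistent with the
  cohort margins the fixture encodes (9,515 − 216 − 3,571 = 5,728, then
  −19 −380 = 5,329); it is exposed as a switch because the alternative
  reading (keep unknowns) is defensible on other datasets.
* Summary tables report n (%) with percent denominators excluding rows
  whose value for that variable is unknown — the only convention that
  reproduces both the 79% control fraction (602 unknowns excluded) and the
  3.6% antibiotic fraction (3,571 excluded) on the fixture.  Display
  rounding: integers at ≥ 10%, one decimal below.

## Association statistics

Quantitative variables across partitions: tie-corrected Kruskal-Wallis with
all-pairs Mann-Whitney post-hocs (two-sided; exact enumeration when both
groups have n ≤ 8 without cross-group ties, otherwise the normal
approximation with tie and continuity corrections), BH-adjusted within the
variable.  Categorical associations: Pearson chi-squared without continuity
correction everywhere — one consistent definition rather than a mixture of
corrected and uncorrected tests.  A partition is called *health-associated*
when strictly more than 90% of its known-status subjects are controls.

## Differential abundance

This is a deliberately simplified NB stage, not a DESeq2 clone; no
dispersion shrinkage, no independent filtering, and equivalence claims are
restricted to sign/recovery properties.  Size factors are "poscounts":
per-taxon reference r_i = exp(Σ_{x>0} ln x / n_samples) (zeros count in the
denominator), per-sample factor = median of x/r over taxa positive in both,
rescaled to geometric mean one.  The NB2 dispersion per taxon is a
method-of-moments estimate on normalised counts pooled within groups,
clipped to [1e-8, 10] — robust at the cohort sizes simulated here.  Means
are fitted by IRLS on a log-link NB GLM with log size factors as offset.
Pairwise contrasts report Wald z = β̂/SE with log2FC = β̂/ln 2 (the
second-listed partition is the reference level); the global partition
effect is a likelihood-ratio test with g − 1 degrees of freedom at fixed
per-taxon dispersion.  BH adjustment is across taxa within a contrast;
all-zero taxa are reported untestable (p = NA) and excluded from the family
size.

## MAG pangenome

The gene catalog uses greedy incremental clustering in CD-HIT's spirit:
sequences sorted by decreasing length (ties by id) join the first
representative reached at ≥ 95% identity and ≥ 90% coverage of the shorter
sequence, computed from a semi-global alignment (the shorter sequence
aligned end-to-end against the best region of the longer; identity =
matches / alignment columns, coverage = fraction of shorter-sequence bases
aligned to a base of the longer).  The exact word filter of CD-HIT is
replaced by an exact computation with a shared-16-mer prefilter that is a
pure speed-up: at these thresholds two matching sequences ≥ 100 bp must
share an exact 16-mer, so skipping pairs without one cannot change the
result (asserted in tests by running with the filter disabled).

MAG QC keeps completeness strictly > 80%, then species with ≥ 30 surviving
MAGs.  An OG is present in a MAG when any of its genes maps to the OG's
cluster (the representative's annotation propagates to members), so
duplicated genes cannot inflate prevalence.  Species-marker OGs: per
species, chi-squared on (in-species vs not) × (present vs absent), BH
within species, q < 0.05.  Partition-associated OGs: each MAG inherits its
donor subject's partition class (health-associated / other; unlinked MAGs
are dropped), chi-squared within species, BH within species, q < 0.1.
Chi-squared tables with a zero margin or any expected count < 1 are skipped
and reported — the source analysis states no small-count rule, so the
conservative option is not to test.  MAG-level counting is used when one
subject contributes several MAGs (subject-level counting would need a
within-subject correlation model the data cannot support); this is
flag-visible in the per-MAG linkage table.  The phage-cassette rule then
keeps flagged OGs with prevalence < 25% among health-associated MAGs and
> 25% among the others.

## MinHash, Mash distance and Ward.D2

Sketches are bottom-s MinHash (defaults k = 21, s = 1000) over canonical
k-mers (lexicographic minimum of k-mer and reverse complement; the 2-bit
A<C<G<T packing preserves lexicographic order; windows with ambiguous bases
are skipped).  The hash is a seeded splitmix64-style 64-bit mixer;
bit-compatibility with the Mash binary is explicitly not a contract — the
tests instead check distributional agreement of the sketch-estimated
Jaccard with the exact Jaccard over all canonical k-mers (within binomial
confidence bounds, and mean error < 0.01 over 50 genome pairs).  The
Jaccard estimate uses the bottom-s′ of the merged hash union
(s′ = min(s, |union|)); the distance is d = −ln(2j/(1+j))/k, capped at 1
when j = 0 because the formula diverges there and no finite convention is
published.

Hierarchical clustering uses the Ward.D2 criterion via the Lance-Williams
recurrence on squared dissimilarities with square-root heights (scipy's
`ward` on a precomputed condensed matrix); the tests pin its merge heights
against R's `hclust(method="ward.D2")` on a frozen matrix.  Dendrograms
export as Newick, and the heatmap export orders the distance matrix by leaf
order with side annotations for cassette-OG presence and partition class
(`missing` for MAGs without partition information).

## The synthetic-data generators

`generate_partitioned_cohort` draws, per sample, a component by weight, a
composition from Dirichlet(α_k) and counts from a multinomial at a depth
uniform on [1,000, 20,000]; a configurable fraction of samples carries no
focal-genus reads at all.  The default mixture has six equal-weight
components over 32 species, each concentrating 90% of a total concentration
of 50 on a distinct species pair — the "two dominant species per partition"
structure the community typing is meant to resolve.  Background taxa are
conditionally independent lognormal-Poisson given the partition
(log-mean 6.0, log-sd 1.5), with partition-linked log2 fold-changes applied
multiplicatively; the defaults plant butyrate-producer enrichment (+1 to
+1.5 log2) and an *E. coli* depletion (−1.5) in the two-species-dominated
partitions, which is what the NB stage is expected to recover.  Depth
heterogeneity is uniform rather than realistic — it exercises the
< 500-count filter without modelling real depth distributions.  Health
status is control vs not with a per-partition probability (defaults 0.95
for the two-species partitions, 0.7 elsewhere), matching the
health-associated / other split the classifier should find.

`generate_table1_fixture` is fully deterministic: 9,515 metadata rows whose
margins equal the pooled cohort's published table (antibiotic 216 yes /
3,571 unknown / 5,728 no; health 7,016/153/439/656/535/94/20/602; ages
278/322/135/7,745/1,035; 8,701 westernized), laid out so the no-antibiotic
and adult-no-antibiotic column margins hold simultaneously, with 380
zero-count and 19 low-count subjects planted among the antibiotic-eligible.
Cells not pinned by any published margin (e.g. which non-adult age bin a
given condition falls in) are filled in deterministic blocks.

`generate_mag_collection` builds, per species, an ancestral genome of
random genes; a deterministic first-round(n·fraction) of its MAGs form a
subclade derived from an ancestor diverged at the between-subclade SNP
rate, and every MAG mutates at the within-subclade rate.  A 15-gene
cassette — each gene its own OG, sequence-random and hence homology-free
with respect to the core — is included per MAG with subclade-dependent
probability.  Completeness is simulated by uniform dropout of core genes to
a level drawn from the completeness range; cassette genes are exempt from
dropout so planted prevalences stay exact (a deliberate simplification —
real completeness loss would attenuate, not bias, the cassette signal).

What the generators do **not** emulate: sequencing error and read-level
artefacts, compositional coupling between the focal genus and the
background, strain-level within-host dynamics, realistic phage biology,
inter-study batch structure.  Passing tests therefore demonstrate that the
statistical machinery recovers truth under its own model assumptions, not
that those assumptions hold for any real cohort.

## Numerical choices and degenerate inputs

* α floor 1e-10 during optimisation; 1e-5 display mask; both configurable.
* Posterior ties in partition assignment go to the lowest component index;
  k-vote ties to the smallest k; catalog-order ties to the smaller id.
* Chi-squared: zero margins are errors (library level) or skips (pangenome
  screening); no Yates correction anywhere.
* BH: NaN p-values (untestable taxa) are excluded from the family size and
  propagate as NaN.
* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage 31-bit substreams as sha256(seed:stage), so toggling one stage
  never perturbs another's stream and a (config, seed) pair yields a
  byte-identical output manifest.

## Problem sizes used in the test and acceptance runs

Synthetic cohorts of 400–2,000 samples over 32 species, k up to 10 with
5 fit seeds; MAG collections of 2–3 species × 16–40 MAGs × 16–60 genes of
300–600 bp; sketches at s = 200–1000 over 20–50 kb genomes.  These sizes
are chosen so the full suite runs on a single CPU in minutes while keeping
every statistical check at a scale where its stated tolerance is
meaningful (e.g. k-recovery uses the full 2,000-sample design; the NB
type-I simulation uses 1,000 null taxa).

## Known limitations

* The NB stage is intentionally not numerically equivalent to DESeq2
  (no shrinkage, MoM dispersions); only sign/recovery behaviour is claimed.
* The greedy catalog reproduces CD-HIT's *logic*, not its word-filter
  heuristics; on borderline pairs near the identity threshold the two can
  legitimately differ.
* MinHash sketches are not bit-compatible with Mash sketches.
* The DMM fit is a local optimiser; multi-start reduces but cannot
  eliminate local optima, which is precisely why the k-selection protocol
  votes across seeds.
* The synthetic metadata fixture pins only published margins; joint cell
  layouts beyond those margins are arbitrary and should not be treated as
  cohort-realistic.
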