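# Methods

## Scope and data model

The pipeline consumes per-sample summary tables produced by standard
upstream metagenomics tools (assembly, binning, quality scoring, taxonomy,
gene clustering, strain profiling, abundance mapping, functional
annotation) and performs everything downstream: the time-course set logic
that calls horizontally transferred gene clusters (HTGCs), engraftment
attribution, enrichment statistics, longitudinal models, retention, and
functional profiling. Sequence-level formats are out of scope by design;
the canonical interchange format is TSV with snake_case headers, validated
on read with every failing row reported.

Species identity is exact string equality on the pre-resolved taxonomy;
"unclassified species" is an explicit boolean on the MAG record rather than
a sentinel string, which avoids prefix-dialect ambiguity.

## HTGC detection

A cluster is called for a participant iff (i) present at week 6, (ii)
absent at baseline, (iii) present in an in-scope donor sample, and (iv)
taxonomically discordant with at least one donor occurrence. All four
criteria are evaluated on *analysable* genes only — genes on high-quality
(completeness > 90, contamination < 5, both strict) and species-classified
MAGs — including the baseline-absence test. Strictness at the boundary is a
deliberate reading of ">90 / <5"; boundary bins are logged. Each distinct
qualifying week-6 gene is its own transfer event, so one cluster can carry
many events.

Donor scope defaults to the whole sex-matched donor cohort for both arms
(`assigned` is available for FMT recipients): a single scope keeps the arms
comparable, and placebo acquisitions are meaningfully evaluated against the
same donor pool. Discordance requires *some* discordant donor occurrence,
not all — a cluster present in two donor species, one matching the
recipient species, still shows transfer evidence from the other.

When a recipient cluster occurs on two recipient MAGs of different species
in the same sample, each gene is its own event using its own MAG's species;
concordant-species genes of the same cluster simply fail criterion (iv).

## Statistics

* **Arm comparison.** Per-participant HTGC frequency (100 × detected
  clusters / distinct analysable week-6 clusters) compared by two-sided
  Wilcoxon rank-sum: exact enumeration over all rank assignments (with
  midranks for ties) when both groups have ≤ 8 observations, tie-corrected
  normal approximation otherwise.
* **Phylum enrichment.** Engrafted strains vs engrafted strains
  contributing transfer events, counted per phylum. Omnibus Pearson
  chi-squared (no continuity correction, matching the default of the
  post-hoc procedure family referenced); per-cell standardized residuals
  r = (O − E)/√(E(1 − row/n)(1 − col/n)) with two-sided normal p and
  Benjamini–Hochberg adjustment across all cells. Phyla with zero counts in
  both columns are dropped and logged; an expected-zero cell raises with
  advice to pool categories. The default counting unit is the distinct
  engrafted (recipient, species) instance; an events-weighted mode is
  exposed for event-scale questions. Phyla missing from MAG taxonomy are
  supplied through a user-editable manual lookup.
* **Longitudinal models.** Per-sample discordant-contig counts are divided
  by species richness; the normalized rate is modelled with a linear mixed
  model (REML): treatment (ref placebo), sex (ref female), timepoint (ref
  baseline) fixed; participant random intercept. A likelihood-ratio test on
  ML fits compares the full (all interactions) against the reduced model;
  the reduced model is reported. Wald 95% CIs and p-values use the normal
  approximation — at trial-scale n the difference from a t/Satterthwaite
  approximation is immaterial. Retention abundance uses the same machinery
  with sex and timepoint (ref week 6) and a recipient random intercept.
* **Retention.** Duplicate events of one cluster collapse to a single
  (recipient, cluster) unit because abundance is cluster-level. "Retained"
  means CPM above a configurable threshold, default 0 (the most permissive
  reading; no published threshold exists). Units without week-6 abundance go
  to a QC report and leave the denominator. Week-26 retention is not forced
  to be a subset of week-12 (re-detection is allowed).
* **Functional profiling.** COG letters map to the four standard major
  classes; multi-category clusters count once per category; unannotated
  clusters form an explicit "no classification" group. PERMANOVA on
  Bray–Curtis dissimilarities of relative-abundance composition vectors,
  rows = HTGC × timepoint (each point a distinct HTGC; a per-sample row
  mode is available through the same function), 999 permutations, p with
  the +1 correction so the attainable minimum is 1/(n_perm+1). The
  permutation engine is seeded and offers exhaustive enumeration for small
  n; CPM is converted to relative abundance within each (sex, timepoint)
  cohort before distances.

## The synthetic trial generator

The generator emulates the structure of a sex-matched, placebo-controlled
adolescent FMT trial: 4 female + 5 male donors (six donation samples each),
22 recipients per arm per sex (~88 total), four recipient timepoints, and a
species universe with the phylum mixture observed in high-quality gut MAGs
(Firmicutes 0.682, Bacteroidetes 0.218, Actinobacteria 0.042, the remaining
0.058 labelled Proteobacteria). Each species owns five gene clusters
(unique to it), each donor carries a subset of species, each recipient a
resident community.

Three acquisition processes operate at week 6:

1. **Species influx, symmetric across arms.** Every recipient gains new
   species from the sex-cohort donor pool at the same per-species rate
   (Bacteroidetes-biased ×2.5, mirroring the promiscuity of Bacteroidales
   in gut HGT networks). In the FMT arm an influx species carried by an
   assigned donor is recorded as a strain engraftment; in the placebo arm
   the same influx is environmental and unrecorded. Influx species appear
   with concordant taxonomy, so they are never HTGCs themselves — but they
   make the arms statistically indistinguishable at the cluster-frequency
   level, which is the study's central null.
2. **Engraftment-dependent transfer (FMT only).** Each engrafted species
   donates each of its clusters to a random resident species with
   probability 0.01 (×6 for Bacteroidetes). Default transfer counts are
   deliberately small relative to background — in the study this subset was
   under 1% of FMT events — so the arm comparison stays null under the
   defaults; characterisation analyses (retention, enrichment) use an
   engraftment-rich configuration with the transfer rate raised.
3. **Background acquisition, identical in both arms.** Clusters from the
   donor-cohort pool (the "environment overlapping the donor pool") land on
   random resident species at rate 0.30 per cluster with per-recipient
   lognormal overdispersion (σ = 0.3). These are real planted HTGCs in both
   arms — placebo HTGC calls are genuine chance acquisitions, not noise.

Every planted acquisition satisfies the detection criteria by construction
and nothing else does (cores are species-unique, resident clusters persist,
influx is concordant), so under the default sex-cohort scope detection must
recover exactly the planted set — the end-to-end recovery oracle. One donor
per sex is dominant (broader species repertoire, heavier attribution
weight), giving the alluvial attribution a planted maximum.

Retention is Bernoulli per unit per later timepoint (defaults 0.858 at week
12, 0.803 at week 26 — the scale of published retention); abundance is
lognormal CPM (μ=3, σ=1). Contig-level HGT counts are built as richness ×
(1.2 + participant effect + 0.37·[week 26] + noise), richness ~120 species,
~96k contigs — putting discordant contigs at ~0.15% of contigs and planting
a week-26 drift of 0.37 on the normalized scale with no arm effect. COG
annotations leave ~19% of clusters unannotated and weight R/S so that
roughly a quarter of annotated clusters are poorly characterised.

One RNG stream per generated table, all spawned from the master seed:
adding a table never perturbs the others, and a fixed seed gives
byte-identical bundles.

### What the generator does *not* emulate

No read-level error, assembly artefacts, chimeric bins, misassigned
taxonomy, strain-level variation within species, or shared clusters between
species. Passing recovery tests therefore demonstrates the correctness of
the set logic and statistics, not robustness to upstream
misclassification — on real data, binning errors can masquerade as
transfer, as the week-6 criteria only see the tables they are given.

## Problem sizes in the test suite

Replicate-heavy experiments (type-I-error of the arm comparison over 200
trials, enrichment flagging over 100 trials, drift-coverage over 100
refitted mixed models, PERMANOVA power over 25 trials) run on a reduced
trial (9 recipients per arm per sex, 40 species) with **all rates at their
defaults** — counts shrink, conditions don't. The PERMANOVA power
experiment plants a 10-fold week-26 abundance change in metabolic clusters
with σ=0.5 dispersion: Bray–Curtis is scale-invariant within a functional
class, so the detectable signal lives only in same-class cross-timepoint
pairs and small shifts are structurally invisible — a known limitation of
composition-level tests on per-HTGC rows.

## Known limitations

* Engraftment matching is on (recipient, species); donor identity is
  reported from the engraftment table and events engrafted from several
  donors are attributed to each but counted once.
* The permutation floor 1/(n_perm+1) is only reached when permutations
  reproducing the observed partition are negligible (≥ ~10 samples per
  group for two groups).
* Mixed-model p-values are Wald-normal; for very small trials an exact or
  Kenward–Roger approach would be preferable.
* The detection criteria cannot see transfers that predate baseline, occur
  off-MAG (e.g. unbinned plasmids), or involve clusters absent from donor
  samples.
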