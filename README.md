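# fmt-hgt

Detection and characterisation of **horizontally transferred gene clusters
(HTGCs)** in donor/recipient metagenome summaries from a faecal microbiota
transplantation (FMT) time course.

## The problem

FMT moves hundreds of bacterial strains from screened donors into a
recipient's gut. Does that influx raise the rate of horizontal gene transfer
(HGT) in the recipient microbiome, and when engrafted donor strains do hand
genes to resident bacteria, which phyla do it and do the transferred genes
persist? Answering this from shotgun metagenomes does not need raw reads once
the standard upstream tools have run: the analysis operates on per-sample
summary tables — genome-bin (MAG) quality and taxonomy, a non-redundant gene
catalogue (gene → cluster membership at >95% identity), strain-engraftment
calls, cluster abundances in copies per million reads (CPM), per-sample
counts of taxonomically discordant contigs, and COG annotations.

This package implements that downstream analysis as a tested, reusable
pipeline, together with a synthetic-trial generator that emulates a two-arm,
sex-matched, placebo-controlled FMT study with planted ground truth, so every
stage is verifiable without any sequencing data.

## The core logic

For a participant *i* (FMT **or** placebo — both arms run through the same
code path) with baseline and week-6 samples, restricted to genes on
high-quality (>90% completeness, <5% contamination), species-classified
MAGs, a gene cluster *c* is called horizontally transferred iff

1. some gene of *c* occurs in *i*'s week-6 sample,
2. no gene of *c* occurs in *i*'s baseline sample,
3. some gene of *c* occurs in a sex-matched donor sample, and
4. the week-6 gene's MAG species differs from at least one donor
   occurrence's MAG species (taxonomic discordance — concordant presence is
   vertical persistence, not transfer).

Each distinct qualifying recipient gene is one transfer event. Downstream:
HTGC frequency per participant (% of week-6 clusters) compared between arms
by Wilcoxon rank-sum; events filtered to those facilitated by engrafted
donor strains; phylum enrichment by chi-squared with standardized-residual
post hocs and Benjamini–Hochberg control; richness-normalized contig-level
HGT counts modelled by a linear mixed model (treatment, sex, timepoint fixed;
participant random intercept); retention of transferred clusters at weeks
12/26; and PERMANOVA (Bray–Curtis, 999 permutations) of COG functional
composition over time.

## Worked example

```sh
fmthgt simulate --out bundle/ --seed 1
fmthgt detect --bundle bundle/ --out detect/
fmthgt report --bundle bundle/ --out report/
```

or, in Python:

```python
from fmt_hgt import SimConfig, simulate, RunConfig, run_all, recovery_report

bundle, truth = simulate(SimConfig(seed=1))
result = run_all(RunConfig(seed=1), bundle=bundle)
print(recovery_report(result, truth))
print({k: result.summary[k] for k in
       ("hq_mag_pct", "excluded_unclassified_pct", "wilcoxon")})
```

prints

```
{'detection_sensitivity': 1.0, 'detection_specificity': 1.0,
 'n_planted': 5096, 'n_detected': 5096,
 'engraftment_sensitivity': 1.0, 'engraftment_set_exact': 1.0}
{'hq_mag_pct': 20.0, 'excluded_unclassified_pct': 5.25,
 'wilcoxon': {'overall': 0.643, 'female': 0.842, 'male': 0.418}}
```

Reading: detection recovered exactly the 5,096 planted cluster acquisitions
(perfect sensitivity and specificity against ground truth); 20.0% of
simulated genome bins were high-quality; 5.25% of genes on high-quality bins
sat on species-unclassified bins and were excluded; and HTGC frequency did
not differ between the FMT and placebo arms (the generator plants equal
background acquisition in both arms, so a non-significant Wilcoxon p is the
correct outcome).

`fmthgt report` writes the figure-level tables (`fig1_normalized_rates.tsv`
… `fig6_functions.tsv`) plus `run_summary.json`; every table carries the
pipeline version and configuration hash, and re-running with the same
configuration is byte-identical.

## Input tables

All inputs are TSV with snake_case headers: `subjects`, `samples`,
`donor_assignment`, `mags`, `genes`, `engraftment`, `abundance`, `waafle`
(per-sample discordant-contig counts + species richness), `cog`. Run
`fmthgt simulate --out example/` for a complete example of every table.
Thin adapters for common upstream dialects (CheckM quality TSV, GTDB-Tk
summary, cd-hit `.clstr`, eggNOG-mapper annotations) live in
`fmt_hgt.adapters`.

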