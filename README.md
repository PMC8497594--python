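# wgdkit

Detection, dating and downstream characterization of ancient **whole-genome
duplications (WGD)** from comparative genomic evidence: synteny against an
outgroup genome, synonymous-divergence (Ks) distributions of retained
duplicates, a kernel-density consensus over per-family Bayesian age
estimates, and enrichment tests relating duplicate retention to expression
response.

It is aimed at plant comparative genomicists analyzing a focal genome that
carries one suspected paleopolyploidy event relative to a diploid outgroup —
the classic setting in which most outgroup regions are collinear with two
regions of the focal genome, and the Ks distribution of the retained
duplicate pairs shows a single peak at the divergence of the event.

## What it computes

- **Codon-level Ka/Ks (NG86).** Protein pairs are aligned globally (affine-gap
  Gotoh, BLOSUM62), back-translated onto the coding sequences, and cleaned:
  a codon column is kept only if no alignment gap occurs within three columns
  on either side; cleaned alignments must exceed 150 aa and cover at least
  half of both proteins. Synonymous/nonsynonymous sites and differences are
  counted per Nei & Gojobori (1986), with equal weighting over all minimal
  stop-free mutational paths, and corrected for multiple hits with
  Jukes–Cantor: `Ks = -(3/4) ln(1 - (4/3) pS)`.
- **Synteny and orthology.** Filtered homology hits (E ≤ 1e-10, best hit per
  query) are chained into collinear blocks by dynamic programming (≥ 5
  anchors, rank gaps ≤ 25). An outgroup gene anchored in two blocks defines a
  1:2 orthology group — its two focal-genome genes are *WGD-retained
  duplicates*; one block defines a 1:1 group (*non-retained*). Adjacent genes
  sharing an outgroup best hit are flagged as tandem duplicates.
- **Ks peak and duplication events.** Pairwise paralog Ks values are
  deduplicated into one event per duplication node via average-linkage
  clustering; the distribution's peak is the mode of a Gaussian KDE
  (bw.nrd0 bandwidth, 512-point grid).
- **Consensus WGD age.** Per-family MCMC traces are screened (burn-in 1000
  samples, ESS ≥ 200 for every statistic), summarized by posterior medians,
  and combined: the consensus age is the KDE mode over family medians, with
  a 95% CI from 1000 ranked bootstrap modes (the 26th and 974th).
- **Retention × expression enrichment.** One 2×2 table per DE direction,
  one-sided Fisher exact test (log-factorial hypergeometric tail), Bonferroni
  over the directions; plus GO enrichment with the elim decorrelation.
- **Population-genetic summaries.** π, Watterson's θ and Tajima's D from
  haplotype matrices (TSV or VCF), and the gene presence filter (< 30%
  ambiguous positions at 5× depth in every sample ⇒ conserved).
- **A synthetic-data generator** producing genomes, codon sequences, hits,
  DE labels, coverage, age sets and coalescent haplotypes with known truth,
  so every stage is testable end to end.

## Worked example

```python
from wgdkit import AnalysisConfig, run_full_analysis
from wgdkit.simulate import SimulationConfig

cfg = AnalysisConfig(seed=1, simulation=SimulationConfig(n_ancestral_genes=500))
report = run_full_analysis(cfg, outdir="out")
print(report.results)
```

prints (exactly reproducible for this seed):

```
ks_peak_mode               0.3157
retained_pct_of_syntenic   64
consensus_age_ma           65.67
consensus_age_ci           [64.68, 67.37]
enrichment_up_p_adjusted   0.0051
enrichment_down_p_adjusted 0.5091
tajimas_d                  -0.548
```

Reading the numbers: the generator diverged duplicate pairs at a true Ks of
0.3 and the KDE peak lands at 0.316; 64% of syntenic genes were recovered as
retained duplicates (the generator's class-weighted retention implies ~62%);
the consensus age estimate 65.7 Ma, CI [64.7, 67.4], covers the true WGD age
of 66 Ma; up-regulated genes are significantly enriched among retained
duplicates (the "drought_up" class is given both higher retention and higher
DE rates) while down-regulation is not; Tajima's D at a single simulated
neutral locus scatters around 0.

The same stages are exposed on the command line:

```bash
wgdkit simulate --seed 1 --n-genes 500 --outdir data/
wgdkit synteny --outgroup data/outgroup_genes.tsv --ingroup data/ingroup_genes.tsv \
               --hits data/hits.tsv --outdir out/
wgdkit enrich --table2 "570,12316,259,7335 402,12484,256,7338"
wgdkit run-all --seed 1 --outdir out/
```

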