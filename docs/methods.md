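# Methods

This note documents the statistical machinery, the defaults, the synthetic
data model and the open design choices. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Ka/Ks estimation (NG86 + Jukes–Cantor)

The estimator is the Nei–Gojobori (1986) counting method:

- **Sites.** For each sense codon, every one of the nine single-nucleotide
  changes is classified; a position contributes (synonymous changes)/3
  synonymous sites. Changes that would create a stop codon count as
  nonsynonymous, so S + N = 3 per codon exactly. Site counts for a pair are
  the average of the two codons'.
- **Differences.** For codons differing at k positions, all k! orderings of
  the changes are enumerated; orderings passing through a stop codon are
  discarded; synonymous/nonsynonymous step counts are averaged with equal
  weight over the surviving paths. If every path is blocked by a stop, the
  codon pair is skipped and counted in `n_skipped_codons`.
- **Correction.** pS = Sd/S and pN = Nd/N are corrected with
  d = −(3/4)·ln(1 − (4/3)·p). When pS or pN ≥ 0.75 the pair is flagged
  `saturated` instead of raising; saturated pairs are excluded from
  distribution summaries.

A codon-model maximum-likelihood estimator (Yang–Nielsen style) would give
slightly different absolute values (typically a few percent at Ks ≈ 0.3);
NG86 was chosen because it is transparent, exactly checkable against a path
enumeration oracle, and adequate for the window filters and distribution
shapes used downstream. All Ks-window thresholds are configurable, and
externally computed Ks tables can be supplied to the dating assembler
directly.

## Alignment and cleaning

Protein pairs are aligned with an affine-gap global aligner (Gotoh; BLOSUM62,
gap open 10, extend 1, a gap of length k costing open + (k−1)·extend). Ties
are broken deterministically: diagonal over gap-in-second over gap-in-first.
The codon alignment mirrors the protein alignment column-for-column.

Cleaning keeps a codon column only if it is gap-free and every *existing*
column within 3 positions on each side is gap-free. The window is **clipped**
at the alignment ends by default, so a fully gap-free alignment survives
intact; a strict variant (`clip_ends=False`), which additionally drops the
first/last 3 columns, is available since the rule's end behavior is a
genuinely open choice. Cleaned alignments pass to Ka/Ks only when strictly
longer than 150 codons ("longer than" read as strict) and covering at least
half of both ungapped proteins ("at least" read as inclusive).

## Synteny chaining

Anchors are homology hits that pass E ≤ 1e-10 and (by default) best-hit-per-
query selection. Within each scaffold pair and orientation, chains must have
strictly increasing outgroup ranks, strictly monotone ingroup ranks, and rank
gaps ≤ 25 on both genomes; chain score is `anchors − 0.05·(total rank gap)`,
kept internally as the integer `20·anchors − gap` so ties are exact. Blocks
are extracted greedily (best chain, remove, repeat) until the best remaining
chain has fewer than `min_block = 5` anchors; ties prefer the chain with the
lexicographically smallest reversed anchor-index sequence, and the same
orientation beats inverted at equal score. `min_block` and `max_gap` follow
the conventional defaults of collinearity scanners; both are exposed.
An outgroup gene anchored in ≥ 3 blocks (possible with tandem arrays or decoy
hits) is excluded from orthology groups and logged rather than guessed.

## Duplication-event deduplication

Pairwise paralog Ks values ≤ `max_ks = 5` join genes into families
(connected components); within a family, average-linkage hierarchical
clustering on the Ks values emits one `DuplicationEvent` per merge, at the
merge height — n − 1 events for an n-gene family. Within-family pairs missing
an estimate are imputed at `max_ks`. Average linkage is the convention of the
deduplication literature this follows; the exact linkage there is not
restated, so it is a documented choice.

## KDE peaks, consensus age, bootstrap CI

All density modes use a Gaussian KDE evaluated on a 512-point grid with the
bw.nrd0 bandwidth (0.9·min(sd, IQR/1.34)·n^(−1/5)) — the default of the R
`density` routine that this meta-analysis convention comes from. Ks grids are
pinned at 0 on the left; age grids span [min − 3h, max + 3h].

The dating meta-analysis consumes per-family MCMC trace logs (sampling itself
is out of scope): discard a burn-in of 1000 samples, require an effective
sample size ≥ 200 for **every** statistic column (ESS = N/ACT with ACT from
the autocorrelation sum truncated at the first negative lag — the Tracer
convention), represent each family by per-node posterior medians, and take
the KDE mode over family medians as the consensus age. The 95% CI takes 1000
bootstrap resamples of the medians, computes each resample's KDE mode, sorts
the modes, and reports the 26th and 974th — i.e. ranks ⌈0.025B⌉+1 and
B−⌈0.025B⌉−1 for general B. (The symmetric upper counterpart of rank 26
would be 975; the 26/974 pair is the published convention and is kept.)
Bootstrap modes are computed by linear binning + FFT convolution, which
matches direct evaluation to within one grid step (verified in the tests).

Dating families have a fixed 8-gene composition: the two focal duplicates
(pair Ks in [0.2, 0.6]), one outgroup-A ortholog (Ks to a focal gene in
[0.5, 1.2]), one clade-X and one clade-Y ortholog per focal gene (Ks in
[0.05, 0.30]), and one outgroup-B gene tied to the outgroup-A gene. All
window bounds are inclusive; candidate ties are broken by lowest Ka, then
lexicographic id; assembled families need a cleaned alignment of ≥ 100 aa.

## Enrichment tests

The Fisher exact test is the hypergeometric tail computed with log-gamma
factorials (numerically exact far beyond the table sizes used; cross-checked
against an independent implementation in the tests). Degenerate margins give
p = 1 with no error. **Sidedness:** the direction-wise retention test is
one-sided (enrichment) with Bonferroni family m = 2 (up and down) by
default — the alternative consistent with both published adjusted values of
the reference contingency table; two-sided is available via a flag. GO
enrichment implements the elim decorrelation: terms are tested
children-before-parents (deepest first), and a term significant at
`elim_threshold = 0.05` (the reporting cutoff; the reference tool's internal
value is not published) has its annotated study genes removed from all
ancestors before those are tested. Classic Fisher p-values and their BH
adjustment are reported alongside; with threshold 0, elim reduces exactly to
classic.

## Population genetics

π is the mean pairwise difference fraction with pairwise deletion of missing
data (per-pair site counts); whole-site deletion is available via a flag, and
both per-gene and concatenated summaries can be formed since which of the two
a "genome-wide average" denotes is ambiguous. θw = S/(a1·L). Tajima's D uses
the standard constants; it is undefined (flagged) when S = 0 or the variance
term vanishes (e.g. n = 3 with S = 1). The presence filter marks a gene
present in a sample iff its ambiguous fraction (missing or sub-threshold
depth, threshold 5× applied upstream) is strictly below 0.30, and conserved
iff present in every sample.

## Synthetic data model

The generator defines the regime the pipeline is tested in; its defaults are
fixed once:

| parameter | default | rationale |
|---|---|---|
| ancestral genes / chromosomes | 2000 / 7 | enough anchors per scaffold pair for chaining; 7 matches a typical haploid count in the target clade |
| duplicate-pair Ks (`wgd_ks`) | 0.3 | the single-peak divergence the analysis targets |
| outgroup ortholog Ks | 1.0 | clearly older than the WGD, inside the 0.5–1.2 dating window |
| retention (pair level) | background 0.42, drought_up 0.70 | implies ~62% of syntenic genes retained as duplicates, the regime being emulated, with class-dependent excess |
| class proportions | drought_up 0.10 | a minority stress-responsive class |
| Ka/Ks (`omega`) | background 0.25, drought_up 0.15 | purifying selection; the preferentially retained class evolves slower at nonsynonymous sites |
| tandem rate | 0.02 | a small local-duplication background |
| DE rates (up) | drought_up 0.30, background 0.04 | true-positive vs false-positive labeling; down-regulation 0.03 for all classes (no retention signal) |
| true WGD age / family sd / families | 66 Ma / 3 Ma / 204 | the dated event's scale and meta-analysis size |
| coalescent | n=20, θ=5/locus, L=2000 | moderate diversity; E[S] ≈ 17.7 |
| coverage | ambiguity ~ Beta(0.5, 9.5), absent rate 0.02 | mostly well-covered genes with occasional dropouts |

Codon evolution is a discrete-event process: Poisson(target_ks·L) uniform
nucleotide proposals, stop-creating proposals rejected, synonymous proposals
always accepted, nonsynonymous accepted with probability ω. Because
synonymous proposals per synonymous site arrive at rate `target_ks` and the
JC correction undoes multiple hits, NG86 recovers `target_ks` in expectation
— the generator and the estimator agree by construction, which is what makes
the recovery tests sharp. Both post-WGD copies evolve `wgd_ks/2` from the
ancestor; the outgroup copy evolves `outgroup_ks − wgd_ks/2` (the WGD placed
immediately after the split, so ortholog divergence is `outgroup_ks` for
every gene).

Gene order after the WGD: both subgenomes inherit the ancestral order; losses
remove slots and ranks are re-indexed, giving clean 2:1 collinearity. Decoy
hits (1% of true hits, sub-best bitscores) exercise anchor filtering. The
coalescent is the standard n-coalescent with infinite-sites mutations mapped
to distinct positions of an L-site locus.

**What the generator does not emulate** — and hence what passing tests do not
establish about real data: indels and alignment error, rate variation across
sites and lineages, gene conversion between duplicates, segmental (non-whole-
genome) duplication, rearrangement beyond block-level inversion being absent
(subgenomes stay perfectly ordered), recombination within loci, demography
and selection in the coalescent, and expression measurement noise beyond
flat per-class label rates.

## Determinism and numerics

One top-level seed; per-component generators are spawned from a numpy
`SeedSequence`, so stages are reproducible in isolation and datasets are
byte-identical across runs. Output tables carry a provenance header (config
hash + seed). Chain scores are integers; alignment traceback ties are fixed;
KDE grids are deterministic functions of the data. Simulation sizes used in
tests and the acceptance script (e.g. 2000 duplicate pairs, 200 dating
replicates, 1000–2000 coalescent replicates) were chosen as the smallest
scales at which the targeted statistical properties are stable.

## Known limitations

- NG86 underestimates Ks relative to codon-ML when base composition or
  transition/transversion bias is strong; windows may need adjusting for
  real data.
- The greedy block extraction stops when the top-scoring chain is shorter
  than `min_block`, which can leave a lower-scoring but long-enough chain
  unextracted in adversarial configurations.
- The elim implementation handles `is_a` edges only; other GO relation types
  must be collapsed beforehand.
- Tajima's D assumes complete data at the variance level; under heavy
  missingness the pairwise-deletion π rescaling is an approximation.
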