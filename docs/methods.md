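# Methods

This note documents the statistical procedures implemented in `chillmeth`,
the parameters that matter, the design decisions taken where the design was
genuinely open, and what the synthetic-data generator does and does not
emulate.

## Windowed DMR calling

**Statistic.** Chromosomes are tiled from position 1 into fixed-width
windows (default 100 bp, non-overlapping).  Each window in each sample is
scored as the log2 ratio of the window's methylated-call density to the
sample's genome-wide methylated-call density,

E = log2( ((m_w + c)/L_w) / ((M + c)/L) ),

with pseudocount c = 0.5 keeping E finite for empty windows.  "Density"
here is methylated *calls* (reads) per bp; the alternative — methylated
positions per covered position — was rejected because the statistic divides
by an overall per-sample density, which is naturally a call density.
Because E is a within-sample ratio it is robust to sequencing-depth
differences between samples.

**Filters and test.** Cytosines enter with coverage ≥ 5 reads (applied in
the reader).  Windows with fewer than 20 methylated cytosines are
discarded; for the all-context analysis the unit is distinct positions with
at least one methylated call in the union across samples.  For per-context
calling the unit is the per-sample-summed count instead: a 100-bp window in
a ~38%-GC genome holds only ~7 CpG positions, so a union threshold of 20
would structurally empty the CpG and CHG sets, while the per-sample sum
preserves the filter's intent (sufficient methylation evidence in the
window) at any context density.  Both units are exposed
(`filter_windows(count_mode=...)`).

Replicate-level E values are compared across conditions with a one-way
fixed-effects ANOVA (replicates are the experimental unit; 3 per
condition), BH-adjusted across the surviving windows.  A window is a DMR
when q < 0.01 **and** the largest pairwise difference of condition-mean E
exceeds 3 log2 units ("any pair" of conditions, not only vs baseline).
Zero-variance windows get p = 1; perfect separation reports the smallest
positive float.  Windows where some sample has no qualifying cytosines keep
their pseudocount-derived E rather than being dropped.

Direction is reported per condition-vs-baseline contrast: hyper if the
condition's mean E exceeds the baseline's, hypo otherwise; hyper and hypo
therefore partition the DMR set within each contrast.

**Window stepping.** Overlapping windows (step < width) are supported but
not default: overlapping tests are strongly dependent and would undermine
the BH step-up's assumptions, and non-overlapping tiles make counts
interpretable as region counts.

**Profiles.** DMR condition-mean profiles can be ranked by variance (ties
broken lexicographically by window id for determinism) and clustered with
k-means (profiles z-scored per item; fixed seed and `n_init=10`, so
clustering is deterministic).  Default k = 16 for DMR subclusters and
k = 10 for co-expression subclusters.

## Differential expression

**Normalisation.** Trimmed mean of M-values: per sample against a reference
(the sample whose upper-quartile CPM is closest to the mean upper
quartile), gene-wise log ratios M and abundances A over genes expressed in
both samples are doubly trimmed (30% per tail on M, 5% per tail on A) and
combined as a precision-weighted mean with binomial delta-method weights;
the factor is 2^(that mean), and factors are rescaled to geometric mean 1.
The factors are exactly depth-invariant in their M-values; a mild (~1%)
library-size dependence remains through the precision weights, as in the
published procedure.

**Test.** Per gene, a negative-binomial likelihood-ratio test compares a
one-mean null with a mean-per-group alternative, with effective library
sizes (library size × TMM factor, scaled to geometric mean 1) as offsets.
The group-mean MLE solves Σ(y−μ)/(1+αμ) = 0 by damped Newton on the log
mean; the LRT statistic is referred to χ²(1).  Dispersion α is a pooled
method-of-moments estimate (Var = μ + αμ², residuals inflated by n/(n−p)
for the fitted means); a per-gene `tagwise-moments` mode is available.
This NB-LRT engine is the package's own documented implementation; its
contract is calibration — null type-I error and planted-effect recovery,
both measured by the acceptance checks — not numeric identity with any
external differential-expression tool.

log2 fold changes come from group means of normalised counts with a
pseudocount of 0.5, i.e. before any shrinkage; calls are up/down at
q < 0.01 and |log2FC| ≥ 1, else ns.  BH adjustment is applied within each
contrast separately, matching per-contrast DEG reporting.

**PCA.** Samples are decomposed by SVD of the gene-centred log2(CPM+1)
matrix (CPM uses effective library sizes).  Variance explained is reported
in percent of total and sums to ≤ 100.

**Utilities.** FPKM_gj = counts·10⁹/(effective library size × gene length);
qPCR relative expression 2^−ΔCt; chilling hours as the count of hourly
temperatures strictly below 7.2 °C; the chilling requirement is the first
condition whose bud-break fraction reaches 0.5.

## Integration

DMRs link to every gene whose span extended by ±2,000 bp they intersect
(1-based inclusive intervals; upstream/downstream assigned relative to gene
strand, distance 0 when overlapping the gene body).  Quadrant tables cross
DMR direction with the DEG call per contrast; genes linked to DMRs of
conflicting direction are counted once per direction and flagged; genes
absent from the DEG table go to a `no_test` tally rather than being
dropped, so cells + no_test always account for every assignment.

Cross-genotype conservation selects genes occupying the same quadrant class
(default hyper∩down and hypo∩up) in at least one contrast of each genotype;
the contrast indices need not match because the two genotypes' chilling
timelines differ.

Methylation–expression correlation is Pearson's r between per-condition
*mean* profiles (condition means, not replicate pairs: the two assays share
conditions, not samples), requiring ≥ 3 condition points; links with a
zero-variance profile are excluded with a warning.  Links with r ≤ −0.5
are retained.  A gene with several linked DMRs yields one record per DMR by
default; `closest_only` keeps the nearest DMR per gene.

Term enrichment is a hypergeometric upper tail per term over a
user-supplied gene→term map, BH-adjusted across terms (q < 0.01); no
ontology-graph propagation is attempted.

## Synthetic experiments

The generator emulates the experimental design the pipeline targets: two
genotypes with different chilling timelines (0/173/348/516 CH and
0/443/1295/1637 CH), three replicates, per-context methylation baselines
CpG 0.60 / CHG 0.35 / CHH 0.10 (typical plant per-context rates), NB(mean
20, size 5) coverage, log-normal baseline expression with NB dispersion
0.1, and a random 38%-GC genome whose cytosine contexts are classified
from the actual simulated sequence.

**Planted-effect geometry.** The enrichment statistic with its 3-log2-unit
gate detects only order-of-magnitude changes in methylated-call density:
a +0.4 shift on the genome-average background (≈0.21 pooled methylation)
changes density ~3-fold (1.6 log2 units) and is invisible to it.  Planted
DMRs therefore model de-novo-RdDM-like events: the planted locus has a
locus-specific low baseline (0.05) and gains the planted effect (default
+0.5) from the onset condition onward — an 11-fold density change (~3.5
log2 units) — with hypo DMRs as the mirror image (0.55 falling by the
effect).  Ordinary planted DMRs switch on as a step at the second condition
(methylation changes concentrate between the first two sampling points in
this system); DMRs paired with genes ramp monotonically while their
partner gene's expression ramps oppositely by 2.5 log2 units, so the pair
is anti-correlated across conditions.  Planted loci and directions are
shared between genotypes (that is what makes cross-genotype conservation
testable); noise realisations are genotype-specific.

All randomness flows from one seed through named `SeedSequence` substreams,
so experiments are byte-identical across reruns.  The desk-scale preset
(1 × 200 kb chromosome → 2,000 windows, 500 genes, 40 planted DMRs, 50
planted DEGs, 10 pairs) generates in a few seconds.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level artefacts (mapping bias, incomplete
bisulfite conversion, clonal reads), spatial autocorrelation of methylation
beyond the planted loci, genotype sequence divergence (both genotypes share
one genome), gene-length/GC expression biases, isoform structure, and
effect sizes smaller than the enrichment statistic can detect.  Recovery
results are statements about the procedure's behaviour under its own
stated detection regime, not about sensitivity to subtle real-world
methylation shifts.

## Pipeline

`run_pipeline` executes simulate → DMR (all-context and per-context) → DEG
(every condition vs 0 CH) → integration, writing TSV outputs plus a
manifest recording parameters and SHA-256 hashes of every output (paths
relative to the run directory).  Reruns with the same config skip stages
whose recorded hashes still match; outputs are byte-identical across
reruns, run directories and `--threads` settings (the flag is accepted for
interface compatibility; all computation is vectorised and single-
threaded).  Exit codes: 0 success, 2 config validation error, 3 stage
failure.

## Numerical choices and limitations

- BH step-up is computed by sorted cumulative minima, capped at 1; inputs
  outside [0, 1] are rejected.
- ANOVA zero-variance handling: p = 1 when the total variance is ~0
  (relative tolerance 1e-12), smallest positive float when only the
  within-group variance vanishes.
- Newton iterations for NB means are damped (step clipped to ±2 in log
  space, 60 iterations, tolerance 1e-12); all-zero genes get mean 0 and a
  zero LRT.
- k-means depends on sklearn's seeded initialisation; different k or seed
  give different (equally valid) partitions.
- The common-dispersion NB test shares one α across genes; with strongly
  gene-specific dispersion the tagwise mode is more appropriate but noisier
  at n = 3.
- The ANOVA on log-enrichment values treats them as approximately normal;
  at very low coverage the log transform is granular and the test loses
  calibration — the coverage ≥ 5 and ≥ 20-methylated-cytosine filters are
  what keep it in its working regime.
- Region percent methylation is read-weighted (Σ meth calls / Σ calls), not
  cytosine-averaged; the two differ when coverage varies across cytosines.
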