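# Methods

## Model and assumptions

evikit treats translation as a two-stage process per gene: initiation,
whose relative efficiency is the translation ratio TR = C/M (the fraction
of a gene's transcripts engaged by ribosomes), and elongation, whose
relative speed is the elongation velocity index EVI = C²/(M·F).  The link
is the ribosome density D = F/C = TR/EVI: at fixed initiation, slower
elongation accumulates footprints on the translated mRNA pool.  The model
assumes (i) all three layers are measured on the same cells and expressed
in rpkM, so the ratios are length- and depth-free; (ii) initiation is
rate-limiting, so TR reflects initiation and D-variation beyond TR
reflects elongation; (iii) premature termination, drop-off and
frameshifting are negligible at the gene level.  EVI is a relative
quantity — only ratios and ranks of EVI are meaningful, never an absolute
codons/s speed.

All geometry and statistics downstream of the metric derivation operate
on log₁₀(TR) and log₁₀(EVI): both quantities span several log units on
realistic translatomes and are approximately log-normal, so the bivariate
normal prediction ellipse is fitted in log space.  Outlier clustering also
runs on the log coordinates (raw coordinates would be dominated by the
handful of largest values); a z-scoring flag exists but is off by default
since the ellipse statistic is already affine-invariant.

## Outlier detection

The (1−α) Hotelling T² *prediction* ellipse for a future observation uses
the threshold [2(n+1)(n−1)/(n(n−2))]·F₂,ₙ₋₂(1−α) on the squared
Mahalanobis distance from the sample mean under the unbiased covariance.
α defaults to 0.01 (a 99% ellipse) and is configurable (0.05 is the other
conventional choice).  Outliers are split by agglomerative clustering
(Euclidean distance, Ward linkage, tree cut at k=2); the cluster with the
lower log-EVI centroid is the low-EVI class and the other the high-TR
class.  If a single cluster both minimizes EVI and maximizes TR, the tie
is resolved by which centroid deviates more from the ellipse center in
marginal-SD units along its own axis; with fewer than two outliers each
point is labeled by its dominant axis deviation.  The grey-quadrant test
(top-q TR and bottom-q EVI simultaneously, q = 0.01) uses empirical
quantiles with linear interpolation; genes exactly at a threshold count as
extreme.  No multiple-testing correction is applied anywhere; all reported
p-values are raw.

## Codon statistics

Counts are tallied over the 61 sense codons of the standard nuclear code;
stop codons and codons containing N are skipped and tallied.  RSCU divides
a codon's count by its family's equal-usage expectation.  The preference
score PS = log₂(RSCU_group/RSCU_all) adds a pseudocount of 0.5 to every
raw count before the RSCU step so the log ratio is defined at zero counts
without distorting large counts; PS(group, group) is identically zero and
PS is antisymmetric under swapping group and background.  Per-codon group
tests are two-tailed chi-square on the 2×2 table {group, background} ×
{codon, other synonymous codons}, without continuity correction.

CAI uses geometric-mean relative adaptiveness with weights from a
reference count set (default: the pooled counts of all quantified genes —
a genome-wide reference; an external highly-expressed reference can be
supplied).  Zero reference counts are floored at 0.5 before
normalization; single-codon amino acids (Met, Trp) are excluded from L.
CBI = (N_pfr − N_ran)/(N_tot − N_ran) over the amino acids with a declared
preferred codon; the default preferred set is the argmax-RSCU codon of
every multi-codon amino acid (all 18 — the classical "17 amino acids"
variant is reproducible by passing an explicit preferred map).  Nc uses
Wright's homozygosity estimator F̂ = (nΣp²−1)/(n−1) per amino acid with
n ≥ 2 observations, class means over degeneracies {2:9, 3:1, 4:5, 6:3},
the mean-of-F2-and-F4 fallback for an entirely missing 3-fold class, F = 1
for an entirely unobserved class, and clamping to [20, 61].  tAI weights
follow the anticodon-copy-number formulation with one Watson-Crick and one
wobble anticodon per codon and default wobble penalties s(G:U) = 0.41,
s(I:C) = 0.28, s(I:A) = 0.9999, s(U:G) = 0.68; no organism's tGCN table is
bundled — copy numbers are user input.  PCAA is the K+R+H fraction of the
translated CDS (internal stops are an error by default, truncation is
opt-in).

Group-level analysis pools counts per gene group (counts are sufficient
statistics, so pooling equals concatenation), builds an RSCU matrix with
rows = groups, runs column-centered PCA, keeps the fewest leading
components whose cumulative explained variance exceeds 80%, and clusters
the groups by UPGMA on standardized Euclidean distances (each retained
dimension scaled by its across-row SD; zero-variance dimensions dropped).
Group-pooled rows (typically low-EVI, high-TR, all genes, and a seeded
random inlier subset of the low-EVI group's size) are the default
observation unit; a per-gene mode is possible by passing per-gene groups.

## Pause calling and metagene

The pause candidate is the argmax of CDS depth (leftmost on ties); the
fold is peak depth over the mean CDS depth with the peak included — the
conservative reading of "average" — and the denominator spans the CDS,
not the full transcript.  A call is a pause when fold > 10.  The 240-nt
co-translational-folding boundary is evaluated as offset ≥ 240 from the
first nucleotide of the start codon.  Offset histograms use 40-nt bins by
default with everything ≥ 400 nt collected in the final bin; group
comparisons use the two-sided two-sample KS test on uncapped offsets.
The metagene profile averages per-gene windows (−20..+200 nt around the
start) normalized by each gene's own window mean, over genes with ≥ 200
total footprint reads; its post-start maximum is the standard check for
elongation-inhibitor artifacts (values near 1 mean no start-codon
pile-up).  Coverage is raw depth; P-site offsetting and read-length
stratification are deliberate non-features of this version.

## Synthetic data

The generator is the package's validation instrument.  Defaults define
the study conditions: 5,000 genes; CDS lengths log-normal in codons
(ln-mean 5.6, ln-SD 0.35; median ≈ 270 codons) plus fixed 60/120-nt UTRs;
uniform background codon usage; five designated slow codons enriched 4×
(then renormalized) in 1% planted low-EVI genes, with a disjoint 1%
high-TR set; (log₁₀TR, log₁₀EVI) bivariate normal with SDs 0.35 and 1.0
and target Spearman 0.62 (converted to the Pearson parameter by
2·sin(πρ/6)); planted displacements of 4 marginal SDs (down in log EVI,
up in log TR); M log-normal with log₁₀ mean 1 and SD 0.8 (≈ 4 log units of
dynamic range); independent multiplicative log-normal measurement noise
of log₁₀-SD 0.1 per layer; Poisson coverage at mean depth 10 with planted
20× peaks, after 240 nt for low-EVI genes and before 240 nt for high-TR
genes.  C and F are constructed by exact inversion (C = TR·M,
F = C·TR/EVI), so at zero noise the derived metrics reproduce the truth
to floating-point precision — the generator's correctness oracle.  An
optional mode scales each slow gene's EVI displacement by its realized
slow-codon excess, coupling the codon and expression layers.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: read-level sampling noise and its
count-dependence, positional/ligation bias in footprints, uORFs and
overlapping transcripts, isoform mixtures, non-normal tails of the
(TR, EVI) cloud, and any mechanistic codon-to-EVI link beyond the optional
imposed coupling.  All generator outputs are pure functions of
(parameters, seed); one RNG stream per generator call.

## Numerical choices

rpkM uses the 1e9 scale constant with merged-transcript lengths in nt;
after splice-variant merging (counts summed, gene length = longest
transcript) rpkM is recomputed from merged counts, never averaged.
Footprint abundance F is normalized over the full transcript length by
default, mirroring M and C; a CDS-only flag exists.  Genes absent from
any layer are dropped with a logged count, and the quantification floor
defaults to 0.1 rpkM in every layer.  Quantiles interpolate linearly
between order statistics.  Coordinates are 0-based half-open everywhere.
Collinear point sets make the ellipse covariance singular and raise a
linear-algebra error rather than silently regularizing.  Validation used
these problem sizes: 10,000 draws for ellipse coverage and identity
checks; 20 seeds × 5,000 genes for outlier and preference-score recovery;
20 seeds × 800 genes (median ≈ 150 codons) for the UPGMA singleton check;
200 genes for pause-caller error rates.

## Known limitations

EVI inherits any bias shared by the three libraries only partially; layer-
specific length or composition biases propagate into it.  The ellipse
assumes approximate bivariate log-normality; heavy tails inflate the
outlier count symmetrically.  Ward-cut-at-2 is a heuristic for the
polarized-outlier geometry and is not guaranteed to minimize the k=2 Ward
objective on adversarial configurations.  Nc is undefined on very short
sequences and falls back as described.  tAI quality is bounded by the
supplied anticodon copy numbers, which are a proxy for tRNA abundance.
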