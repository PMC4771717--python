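# evikit

Genome-wide, per-gene analysis of **translation elongation speed** from three
matched RNA-seq layers of the same cells:

* **mRNA-seq** — total mRNA abundance *M*,
* **RNC-seq** — ribosome-nascent-chain-bound (actively translated) mRNA
  abundance *C*,
* **Ribo-seq** — ribosome footprint (RFP) abundance *F*,

all in rpkM so they are length- and depth-normalized and comparable across
genes.

## The model

For each gene the package derives

```
TR  = C / M            translation ratio: relative initiation efficiency
EVI = C² / (M · F)     elongation velocity index: relative elongation speed
D   = F / C = TR / EVI ribosome density on translated mRNA
```

A slowly elongating gene accumulates footprints per unit of translated
mRNA (high D), so at a given initiation efficiency its EVI is low.  EVI is
a *relative* measure — it ranks genes within and between conditions but is
not an absolute speed in codons/s.

On the (log₁₀ TR, log₁₀ EVI) plane, evikit fits a bivariate **Hotelling
T² prediction ellipse**: with sample mean Z̄, unbiased covariance S and n
genes, the (1−α) ellipse is

```
(Z − Z̄)′ S⁻¹ (Z − Z̄) = [2(n+1)(n−1) / (n(n−2))] · F₂,ₙ₋₂(1−α)
```

Genes outside the ellipse are outliers; Ward/Euclidean clustering at k=2
splits them into the **low-EVI** (slow elongation) and **high-TR**
(initiation-efficient) classes.  The "grey quadrant" test asks whether any
gene is simultaneously in the top 1% of TR and the bottom 1% of EVI.

Around this core the package provides:

* codon-preference statistics of gene groups — RSCU, preference score
  PS = log₂(RSCU_group / RSCU_all), per-codon chi-square tests, CAI, CBI,
  effective number of codons Nc, tAI (from user-supplied anticodon gene
  copy numbers), and the fraction of positively charged amino acids;
* PCA on group RSCU vectors with 80%-variance component selection and
  UPGMA clustering on standardized Euclidean distances;
* translational **pause-site calling** from footprint coverage (highest
  CDS peak > 10× the mean CDS depth), the 240-nt start-distance
  classification, peak-offset histograms with KS group comparisons, and a
  start-codon metagene profile;
* between-condition (relative) TR/EVI fold changes with ±10-fold gene
  lists;
* a fully seeded **synthetic-data generator** that plants slow-codon
  enriched low-EVI genes, high-TR genes and pause peaks, so the whole
  pipeline is validated against known ground truth without any download.

## Worked example

```
$ evikit simulate --out sim --seed 7 --n-genes 400
simulated 400 genes -> sim
$ evikit run --mrna sim/mrna.tsv --rnc sim/rnc.tsv --rfp sim/rfp.tsv \
    --cds sim/cds.fasta --gene-models sim/gene_models.tsv \
    --coverage sim/coverage.bedgraph --out run
analysis of 379 genes -> run
```

`run/summary.json` then contains (abridged):

```json
{
 "n_genes": 379,
 "ellipse_threshold": 9.373,
 "n_low_evi": 4,
 "n_high_tr": 4,
 "grey_quadrant_genes": [],
 "tr_evi_spearman": {"spearman_r": 0.607},
 "pca_n_selected": 1,
 "low_evi_singleton_at_2cut": true,
 "pause_comparison": {"ks_statistic": 1.0, "p_value": 0.0286},
 "metagene_post_start_max": 1.049
}
```

Reading: 379 of 400 simulated genes were quantifiable in all three layers;
log TR and log EVI correlate with Spearman R ≈ 0.61; the 99% prediction
ellipse (squared-Mahalanobis threshold 9.37) flags 4 low-EVI and 4 high-TR
outliers; no gene occupies the grey quadrant; in codon space the low-EVI
group clusters apart from all other gene groups; the planted low-EVI pause
peaks sit after 240 nt while the high-TR peaks sit before it (KS statistic
1.0); and the metagene start profile peaks at ≈ 1.05, i.e. no artificial
footprint pile-up at start codons.  Full per-gene tables
(`metrics.tsv`, `classifications.tsv`, `pause_calls.tsv`,
`gene_scores.tsv`, `ps_low_EVI.tsv`, …) are written next to the summary.

`evikit compare runA runB --out cmp` reports per-gene log₂ fold changes of
TR and EVI between two runs and the gene lists beyond ±10-fold EVI change.

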