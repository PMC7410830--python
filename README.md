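# devdecomp

Desk-scale pipeline for structuring a multi-tissue developmental
transcriptome and decomposing whole-tissue epigenomic state maps into
**cell-type-resolved candidate cis-regulatory elements (cCREs)** using
single-cell RNA-seq marker genes.

Whole-embryo ENCODE-style assays (RNA-seq, histone ChIP-seq, DNase,
chromatin-state segmentations) are measured on bulk tissue and therefore
blind to cell type. This package implements the bespoke analysis chain that
restores cell-type resolution:

1. **Bulk transcriptome structure** — genes are split into *dynamic*
   (max/min FPKM ≥ 10, minimum floored at the 0.1 pseudocount) versus
   *ubiquitous*; PCA over log2(FPKM + 0.1) summarizes the tissue × stage
   sample space (z-scored PC scores, unit-norm loadings); dynamic genes are
   clustered (1 − Pearson r, average linkage) and major clades (≥ 30 genes)
   extracted; canonical correlation analysis links the top 20 PCs to Boolean
   tissue/stage/sex/batch metadata, with gene-level canonical loadings
   **L**·**a** (PCA loadings times PC-side canonical coefficients); embryo
   sex is called from *Xist* (female) and *Ddx3y* (male).
2. **Single-cell features and markers** — QC for plate (FPKM) and droplet
   (UMI) platforms; per-cell normalization ln(10⁴·x/Σx + 1); dispersion
   (variance/mean) ranking; *tight-cluster* feature selection (genes in
   dendrogram clusters of > 2 members after cutting at distance 0.8), which
   keeps co-expressed programs and discards sporadic high-dispersion genes;
   one-vs-rest Wilcoxon markers (min.pct 0.25, detection-difference 0.2/0.4,
   Bonferroni) cross-intersected into **exclusive** cell-type/lineage
   markers.
3. **Signal significance tracks** — raw binned signal x is converted to
   −log10 P(X ≥ x) under a negative binomial background (method of moments
   on the bottom 99% of bins; Poisson fallback when v ≤ m), with the mean
   adjusted per position by 20-kb rolling signal/input ratios normalized to
   genome mean 1, capped at 16. Promoter windows (4 kb around the TSS) of
   log2(signal/input) quantify the *de-repression* signature: falling
   repressive histone signal with rising RNA.
4. **cCRE assignment** — DHS peaks merged across samples; peaks kept only
   where they overlap whitelisted chromatin states (active 14, 19, 20, 21,
   23, 24, 25, 27, 28, 30–32; poised 8, 13; bivalent 26, 29); each element
   assigned to the closest expressed TSS (bulk FPKM > 0.1 or detected in
   > 4 cells) and stratified as proximal (≤ 200 bp), middle (201–2,000 bp)
   or distal (> 2,000 bp); elements of exclusive-marker genes become
   cell-type cCREs.
5. **Promoter motifs** — upstream 500-bp promoter pools scanned with PWMs
   (log-odds, null threshold from shuffled sequences); one-sided Fisher
   enrichment, Bonferroni-corrected, required to pass **in both** gene
   annotation variants; significant (motif, cluster) pairs form a bipartite
   graph with shared/unique motif nodes.

All of it runs on seeded synthetic data with planted ground truth (the
`synthetic_data` module), so every step is scored by recovery of what was
planted — no external downloads.

## Worked example

The numbered scripts under `analysis/` run the whole study on synthetic
data and narrate what they find:

```text
$ python analysis/02_bulk_transcriptome.py --seed 1
2000 genes -> 50 removed by the read prefilter, 286 dynamic, 1664 ubiquitous
partition agrees with planted truth on 100.0% of genes
top 3 PCs explain 49.5% of variance
7 major co-expression clades (>= 30 genes): {1: 40, 2: 40, 3: 43, 4: 40, 5: 40, 6: 40, 7: 43}
metadata axes: sex canonical r = 1.000, batch canonical r = 0.999
Xist/Ddx3y sex inference matches planted sex for 100.0% of samples

$ python analysis/05_celltype_elements.py --seed 1
20 exclusive markers from single-cell data
50 whitelisted elements; 50 attributed to cell types; 20/20 marker genes
(100.0%) have at least one affiliated element
against planted truth: recall 1.00, precision 1.00
```

The seven clades are the six planted tissue-specific programs plus the
globally decaying cell-cycle-like block (two clades absorb the sex-linked
genes, hence 43); recall/precision 1.00 means every planted enhancer was
recovered with the right gene, distance stratum and state class, and every
decoy peak on a non-whitelisted state was rejected. The same functionality
is exposed as a CLI (`devdecomp synth|bulk|sc|epi|cre|motif`), whose
outputs are byte-identical across re-runs at a fixed seed.

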