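# Methods

This note records the models, parameter choices and numerical conventions
behind each stage of the pipeline, what the synthetic data emulate (and do
not), and the design decisions taken where the procedure was genuinely
open.

## Coordinates and formats

All genomic coordinates are 0-based half-open, asserted at every reader
boundary. The TSS-to-element distance is computed in the same convention:
for a peak `[start, end)` and a TSS `t`, the distance is `start − t` when
the TSS is left of the peak, `t − end` when right of it, and 0 inside. The
distance strata (proximal ≤ 200 bp, middle 201–2,000 bp, distal > 2,000 bp)
apply to this metric with inclusive upper boundaries. PWM columns off unit
sum by at most 1e-3 are renormalized (published matrices are rounded);
larger deviations are treated as corrupt input.

## Bulk transcriptome

* **Prefilter.** Genes with fewer than 10 mapped reads in every sample, and
  tRNA-biotype genes, are removed before anything else; this requires the
  read-count companion table and fails loudly without it.
* **Dynamic/ubiquitous partition.** A gene is dynamic when max/min FPKM
  ≥ 10 across samples, boundary inclusive, with the minimum floored at the
  0.1 log pseudocount so genes absent from some samples get a finite, large
  ratio rather than infinity. The floor choice keeps the partition
  consistent with the log2(FPKM + 0.1) transform used everywhere else.
* **PCA.** Samples are observations, genes variables, gene-centred and
  unscaled (abundant dynamic genes are supposed to dominate). Loadings are
  unit-norm; reported scores are z-scored per PC (sd with ddof = 1). Sign
  is fixed by making the gene with the largest |loading| positive, ties by
  lexicographic gene id — determinism across linear-algebra backends.
* **Clustering and major clades.** Distance 1 − Pearson r, average linkage.
  Genes are sorted by id before clustering so results cannot depend on
  input order; constant genes get distance 1 to everything with a warning.
  The original clade extraction was a manual walk of the dendrogram guided
  by dominant tissues and GO terms; no algorithm exists for that, so we
  automate it as: traverse from the root, split a clade while both children
  hold ≥ 30 leaves, and report clades that can no longer be split. "30
  nodes" is read as 30 leaves. This reproduces the planted block structure
  exactly and is the package's own, testable stand-in for the manual step.
* **CCA.** Metadata are one-hot Boolean columns (tissue, stage, sex,
  batch); collinear columns (including the implicit intercept of full
  one-hot blocks) are dropped greedily on centred columns. The canonical
  system is solved classically via QR of each centred block and SVD of
  QxᵀQy; coefficients are scaled so variates have unit variance, with signs
  fixed on the metadata side. We implemented this directly because the
  statsmodels solver rejects single-variable sets (it squeezes them to
  1-D), which we need for per-axis questions ("how well does the PC space
  encode sex?"); statsmodels' CanCorr is kept as an independent cross-check
  in the tests on the multi-column case. Gene-level canonical loadings are
  the product of the PCA loading matrix and the PC-side coefficients.
* **Sex inference.** Female iff Xist detected and Ddx3y not, male iff the
  converse, mixed iff both, unknown iff neither. "Detected" defaults to
  FPKM ≥ 1.0 (configurable); no threshold is canonical, and the planted
  effects are far from it.
* **Ubiquitous strata.** Among ubiquitous genes with mean log2(FPKM + 0.1)
  strictly above 2, the n = 3,000 (scaled down to 300 on the synthetic
  data) lowest-variance genes are ranked by mean linear FPKM and split into
  equal high/medium/low thirds.

## Single-cell features and markers

* **QC.** Full-length (plate) data: cells need ≥ 100,000 transcriptome
  reads and ≥ 4,000 genes above 10 FPKM; genes need detection in ≥ 5 cells,
  ≥ 10 FPKM somewhere, and (when a read table is given) ≥ 100 reads
  somewhere. Droplet data: cells need 1,000–8,000 genes detected and ≤ 20%
  mitochondrial counts; genes need detection in ≥ 0.1% of remaining cells.
  All boundaries inclusive of the stated minima. Microscopy-driven plate
  exclusions (doublet chambers, biased chips) are an input mask, not
  computed.
* **Normalization.** Droplet counts per cell: x → ln(10⁴·x/Σx + 1). The
  natural log is a convention choice (only the scale changes); it is
  recorded here and in the matrix metadata.
* **Dispersion and tight clusters.** Dispersion = sample variance
  (ddof = 1) / mean on normalized values (the open choice between raw and
  normalized values is resolved to normalized, matching the rest of the
  chain); zero-mean genes are excluded, ties break by gene id. The top-N
  high-dispersion genes are clustered (1 − Pearson, average linkage), the
  dendrogram is cut at height 0.8, and genes in clusters with more than two
  members are kept. The rationale: truly co-regulated programs survive,
  sporadic bursty genes (high dispersion, no partners) land in singletons
  and are dropped.
* **Markers.** One-vs-rest two-sided Wilcoxon rank-sum (normal
  approximation with tie correction, as in scipy's asymptotic
  Mann-Whitney), tested only where the detection fraction reaches 0.25 in
  either group and the detection difference reaches the 0.2 or 0.4 cutoff.
  P values are Bonferroni-corrected over all genes in the matrix
  (conservative, reproducible). Log2 fold changes compare de-logged group
  means with pseudocount 1. Exclusive markers consider positively enriched
  calls only — the two-sided test also flags depletion, which must not make
  a gene a "marker" of a foreign cluster. A gene is an exclusive marker of
  a type when it is a marker there and nowhere else, or of a declared
  lineage group when its marker set equals the group exactly; duplicate
  group definitions are rejected as ambiguous.

## Signal tracks

* **Background.** Method of moments on bins at or below the empirical 99%
  quantile (linear-interpolation quantile): r = m²/(v−m), p = m/v; Poisson
  when v ≤ m. Trimming the top 1% deliberately removes enriched regions and
  therefore biases both moments low — for heavy NB tails the variance by
  roughly 15–20% — which is the intended behaviour of a *background*
  estimator, not an unbiased one; the tests pin both facts.
* **Local adjustment.** 20-kb centred rolling means of signal and input
  (truncated at chromosome ends; 100 bins at the default 200-bp bin width),
  ratio set to 1 where the input mean is 0 (no information → no
  adjustment), ratios rescaled to genome-wide mean 1, then multiplied onto
  the fitted mean. Only the mean moves; the per-bin variance keeps the
  fitted variance/mean ratio.
* **P-value track.** Inclusive upper tail P(X ≥ x) per bin at the adjusted
  mean, −log10, capped at 16. Non-integer signal is floored with a warning.
  Implementation uses log-survival functions; tests compare against direct
  pmf summation to 1e-8 and check monotonicity and the Poisson limit.
* **De-repression.** Promoter score = mean log2((s+1)/(i+1)) over the 4-kb
  TSS-centred window (strand-independent, truncated at ends with warning);
  fold decrease = earliest − latest time point; clusters ranked by mean
  member fold decrease, paired with the mean least-squares slope of member
  RNA across stages.

## Element assignment

Peak merging coalesces overlapping *and bookended* intervals (standard
merge semantics). A peak qualifies as an element when it overlaps ≥ 1 bp of
a whitelisted-class state interval in *any* sample (the segmentations pool
developmental time points); when classes conflict the single label follows
the precedence active > bivalent > poised — a deterministic choice where no
rule is documented. Expression gating: bulk max FPKM strictly above 0.1, or
detection in strictly more than 4 cells. Nearest-TSS ties break by gene id.
Elements of non-marker genes stay in the full table but not the cell-type
table.

## Motif enrichment

Promoters are the upstream 500 bp on the gene's strand. Scanning is
log-odds against a uniform background over both strands; a sequence is a
hit when its best window reaches the 0.999 quantile of max scores on
mononucleotide-shuffled copies of the input pool (seeded). Enrichment is a
one-sided Fisher exact test of foreground hits versus the non-foreground
remainder of the background pool, Bonferroni-corrected by the motif library
size, and a motif is significant only when corrected P < 0.01 under **both**
annotation variants (two TSS tables; the synthetic variants shift TSSs by
up to ±50 bp). This thresholded-hit Fisher statistic is a deliberate,
fully specified substitute for AME's internal scoring, which is neither
documented in the source procedure nor reproducible here; it is exactly
oracle-testable against the hypergeometric tail.

## Synthetic data: what it emulates, and not

One seed fans out to independent child streams per generator
(`default_rng([seed, stream])`), so datasets are reproducible jointly and
separately.

* **Bulk** (6 tissues × 5 stages × 2 replicates, 2,000 genes): six 40-gene
  tissue-specific blocks (50-fold on/off), a 40-gene globally decaying
  cell-cycle-like block (30-fold first-to-last stage), three female and
  three male sex-linked genes (on/off by planted embryo sex, all three sex
  classes forced to occur), 100 batch-responsive genes (×1.5 in batch 2),
  flat ubiquitous genes, 30 low-count genes and 20 tRNA genes destined for
  the prefilter. Multiplicative noise is *bounded* (uniform ±0.25 in log2),
  so planted dynamic genes are ≥ 10-fold and ubiquitous ones < 10-fold with
  certainty — truth-table recovery is a deterministic contract, not a
  probabilistic one.
* **Single cell** (5 types × 200 cells, 400 genes): 4 exclusive Boolean
  markers per type (detection 0.9 in-type vs 0.05 out, 4-fold rate), a
  10-gene co-activated module (the same 30% of cells burst for every
  member — marginally indistinguishable from noise genes, jointly
  correlated), 50 independent bursty noise genes, 10 mitochondria-tagged
  genes, housekeeping background, log-normal library sizes, and planted
  QC-failure cells (near-empty and saturated). Because the matrix is
  400 genes, drivers and tests pass scaled QC thresholds (min 100 / max 380
  genes, 0.5% gene detection) and tight-cluster top-N 100 (≈ the same
  fraction as 4,000 of a ~16k-gene transcriptome); library defaults remain
  the full-scale values.
* **Epigenome** (2 chromosomes, 2 Mb, 200-bp bins): TSS slots every 35 kb;
  50 enhancers planted at 100 bp / 1 kb / 10 kb from marker-gene TSSs
  (cycling side and state class, state ids drawn from the matching
  whitelist), each covered by exactly one whitelisted state interval split
  across two segmentation samples (so pooling is required); 20 decoy peaks
  on non-whitelisted states; peak calls from two samples with far-side
  extensions (so merging is exercised without moving distances); NB(5, 20)
  signal with 8-fold elevated means over elements and a flat NB input.
* **Not emulated:** realistic sequence composition, read-level noise,
  mappability artifacts, doublets, ambient RNA, batch-by-tissue
  interactions, overlapping genes, and continuous (non-block) expression
  programs. Passing tests therefore demonstrate correctness of the
  *procedures* under controlled conditions, not robustness to every
  pathology of real data.

## Problem sizes

The synthetic dimensions above were chosen once so the full suite and the
acceptance script each complete in seconds while keeping every statistical
test comfortably powered (e.g. 200 cells/type gives Wilcoxon z-scores far
beyond the Bonferroni threshold for the planted effect sizes).

## Known limitations

* Major-clade extraction is a size-based automation of a manual step; on
  real dendrograms the clade boundaries will not always match what an
  annotator guided by GO terms would draw.
* The motif statistic is not AME; absolute P values are not comparable to
  the original tool, only the planted/decoy contrast is.
* The NB background assumes a common variance/mean ratio genome-wide;
  copy-number variation or GC waves beyond the 20-kb window scale are not
  modelled.
* CCA with 20 PCs on 60 samples overfits the full metadata design (all
  canonical correlations near 1); per-axis single-column CCAs are the
  meaningful readout at this sample size.
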