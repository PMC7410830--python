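"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its configuration (one global
seed fans out to independent per-generator streams) and returns, next
to the data, a truth table sufficient to score the downstream analysis
without any external resource.

The bulk generator emulates a tissue-by-stage developmental
transcriptome: tissue-specific dynamic blocks, flat ubiquitous genes,
a globally decaying cell-cycle-like block, X/Y sex-marker genes and an
additive (on the log scale) batch covariate. Effect sizes are chosen
so the planted labels are unambiguous by construction: dynamic blocks
span at least a 30-fold range while ubiquitous genes stay within
3-fold even after noise and batch shifts, comfortably on either side
of the 10-fold partition boundary.

The single-cell generator emulates droplet UMI data with cell-type
structure: exclusive Boolean markers with configured detection
fractions in and out of their type, a co-expressed module driven by a
shared latent activity (for tight-cluster feature selection),
independent high-dispersion noise genes (which tight-cluster selection
must reject), mitochondria-tagged genes and planted QC-failure cells.

The epigenome generator lays out a small two-chromosome genome with
TSS slots, plants enhancer elements at controlled distances from
marker-gene TSSs inside whitelisted chromatin-state intervals, plants
decoy peaks on non-whitelisted states, and draws negative-binomial
signal tracks with elevated means over the planted elements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bulk_structure import ExpressionMatrix
from .cre_assign import (
    ACTIVE_STATES,
    BIVALENT_STATES,
    POISED_STATES,
    StateSegmentation,
    categorize_distance,
)
from .io_formats import PWM, GenomicInterval, SignalTrack, TssTable
from .sc_features import CellMatrix

CELL_TYPE_NAMES = ["Muscle1", "Muscle2", "Chondrocyte", "Perichondrium", "Macrophage"]
FEMALE_GENES = ["Xist", "Kdm6a", "Eif2s3x"]
MALE_GENES = ["Ddx3y", "Uty", "Kdm5d"]


@dataclass
class SynthConfig:
    """Study conditions for the synthetic datasets (desk scale)."""

    seed: int = 0

    # bulk transcriptome
    n_tissues: int = 6
    n_stages: int = 5
    n_replicates: int = 2
    n_genes: int = 2000
    genes_per_tissue_block: int = 40
    n_cell_cycle_genes: int = 40
    n_batch_genes: int = 100
    n_low_count_genes: int = 30
    n_trna_genes: int = 20
    dynamic_fold: float = 50.0  # planted tissue on/off ratio
    cell_cycle_fold: float = 30.0  # first-to-last stage decay
    batch_effect: float = 1.5  # multiplicative FPKM shift in batch 2
    sex_effect_fpkm: float = 30.0
    bulk_noise_log2: float = 0.25  # uniform +-, bounds the fold wobble

    # single cell
    n_celltypes: int = 5
    n_cells_per_type: int = 200
    n_sc_genes: int = 400
    n_markers_per_type: int = 4
    n_module_genes: int = 10
    n_noise_genes: int = 50
    n_mito_genes: int = 10
    marker_fold: float = 4.0
    marker_pct_in: float = 0.9
    marker_pct_out: float = 0.05
    marker_base_rate: float = 2.0
    n_qc_fail_cells: int = 10

    # epigenome
    genome_length: int = 2_000_000
    n_chromosomes: int = 2
    bin_width: int = 200
    gene_spacing: int = 35_000
    n_enhancers: int = 50
    n_decoys: int = 20
    element_width: int = 400
    element_distances: tuple[int, ...] = (100, 1000, 10_000)
    nb_mean: float = 5.0
    nb_variance: float = 20.0
    enhancer_fold: float = 8.0

    def __post_init__(self) -> None:
        for name in (
            "n_tissues", "n_stages", "n_replicates", "n_genes", "n_celltypes",
            "n_cells_per_type", "n_sc_genes", "genome_length", "n_enhancers",
            "bin_width",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.nb_mean <= 0 or self.nb_variance <= 0:
            raise ValueError("negative binomial parameters must be positive")

    def rng(self, stream: int) -> np.random.Generator:
        """Independent child stream ``stream`` of the global seed."""
        return np.random.default_rng([self.seed, stream])


@dataclass
class TruthTables:
    """Ground truth planted by the generators, for scoring."""

    # bulk
    planted_dynamic: dict[str, bool] | None = None
    planted_removed: set[str] | None = None
    planted_sex: dict[str, str] | None = None
    tissue_blocks: dict[str, list[str]] | None = None
    batch_genes: list[str] | None = None
    # single cell
    planted_markers: dict[str, str] | None = None
    planted_module_genes: set[str] | None = None
    noise_genes: set[str] | None = None
    qc_fail_cells: set[str] | None = None
    cell_labels: pd.Series | None = None
    # epigenome
    planted_elements: list[dict] | None = None
    decoy_peaks: list[GenomicInterval] | None = None
    # de-repression / motifs
    planted_derepressed_cluster: int | None = None
    planted_motif_genes: set[str] | None = None


# ---------------------------------------------------------------------------
# Bulk


def generate_bulk_matrix(config: SynthConfig) -> tuple[ExpressionMatrix, TruthTables]:
    rng = config.rng(1)
    tissues = [f"Tissue{t + 1}" for t in range(config.n_tissues)]
    stages = [f"S{s + 1}" for s in range(config.n_stages)]
    samples, meta_rows = [], []
    sexes = []
    # guarantee all three sex classes occur so the X/Y markers span
    # their full on/off range
    forced = ["female", "male", "mixed"]
    for t in tissues:
        for s in stages:
            for r in range(1, config.n_replicates + 1):
                sid = f"{t}_{s}_R{r}"
                sex = forced[len(samples)] if len(samples) < 3 else rng.choice(
                    ["female", "male", "mixed"]
                )
                samples.append(sid)
                sexes.append(str(sex))
                meta_rows.append(
                    {
                        "sample": sid,
                        "tissue": t,
                        "stage": s,
                        "sex": str(sex),
                        "batch": f"B{r}",
                        "replicate": r,
                    }
                )
    meta = pd.DataFrame(meta_rows).set_index("sample")
    n_samples = len(samples)

    gene_ids: list[str] = []
    biotype: list[str] = []
    base = np.zeros((0, n_samples))
    truth_dynamic: dict[str, bool] = {}
    tissue_blocks: dict[str, list[str]] = {t: [] for t in tissues}

    tissue_idx = meta["tissue"].values
    stage_idx = meta["stage"].map({s: i for i, s in enumerate(stages)}).values
    batch2 = (meta["batch"] == "B2").values
    sex_arr = meta["sex"].values

    rows = []
    # tissue-specific dynamic blocks
    for t in tissues:
        for i in range(config.genes_per_tissue_block):
            g = f"DYN_{t}_{i + 1}"
            high = rng.uniform(20, 80)
            v = np.where(tissue_idx == t, high, high / config.dynamic_fold)
            rows.append(v)
            gene_ids.append(g)
            biotype.append("protein_coding")
            truth_dynamic[g] = True
            tissue_blocks[t].append(g)
    # globally decaying cell-cycle-like block
    decay = config.cell_cycle_fold ** (1.0 / (config.n_stages - 1))
    for i in range(config.n_cell_cycle_genes):
        g = f"CC_{i + 1}"
        high = rng.uniform(20, 60)
        rows.append(high / decay**stage_idx)
        gene_ids.append(g)
        biotype.append("protein_coding")
        truth_dynamic[g] = True
    # sex markers: on in the matching sex and in mixed pools, off otherwise
    for g in FEMALE_GENES:
        on = np.isin(sex_arr, ["female", "mixed"])
        rows.append(np.where(on, config.sex_effect_fpkm * rng.uniform(0.7, 1.3), 0.0))
        gene_ids.append(g)
        biotype.append("protein_coding")
        truth_dynamic[g] = True
    for g in MALE_GENES:
        on = np.isin(sex_arr, ["male", "mixed"])
        rows.append(np.where(on, config.sex_effect_fpkm * rng.uniform(0.7, 1.3), 0.0))
        gene_ids.append(g)
        biotype.append("protein_coding")
        truth_dynamic[g] = True
    # batch-responsive ubiquitous genes
    batch_genes = []
    for i in range(config.n_batch_genes):
        g = f"BATCH_{i + 1}"
        b = rng.uniform(5, 40)
        rows.append(np.where(batch2, b * config.batch_effect, b))
        gene_ids.append(g)
        biotype.append("protein_coding")
        truth_dynamic[g] = False
        batch_genes.append(g)
    # plain ubiquitous genes fill the rest
    n_special = len(gene_ids) + config.n_low_count_genes + config.n_trna_genes
    n_ubi = config.n_genes - n_special
    if n_ubi <= 0:
        raise ValueError("n_genes too small for the configured blocks")
    for i in range(n_ubi):
        g = f"UBI_{i + 1}"
        rows.append(np.full(n_samples, rng.uniform(2, 60)))
        gene_ids.append(g)
        biotype.append("protein_coding")
        truth_dynamic[g] = False
    # genes destined for removal by the read-count prefilter
    removed: set[str] = set()
    for i in range(config.n_low_count_genes):
        g = f"LOW_{i + 1}"
        rows.append(np.full(n_samples, 0.2))
        gene_ids.append(g)
        biotype.append("protein_coding")
        removed.add(g)
    for i in range(config.n_trna_genes):
        g = f"n-Tr{i + 1}"
        rows.append(np.full(n_samples, rng.uniform(5, 20)))
        gene_ids.append(g)
        biotype.append("tRNA")
        removed.add(g)

    base = np.vstack(rows)
    # bounded multiplicative noise keeps planted fold ranges on the
    # right side of the 10x boundary with certainty
    noise = np.exp2(rng.uniform(-config.bulk_noise_log2, config.bulk_noise_log2, base.shape))
    values = pd.DataFrame(base * noise, index=pd.Index(gene_ids, name="gene_id"), columns=samples)

    counts = np.rint(values.values * 20).astype(int)
    low_mask = values.index.str.startswith("LOW_")
    counts[low_mask] = rng.integers(0, 10, size=(low_mask.sum(), n_samples))
    read_counts = pd.DataFrame(counts, index=values.index, columns=samples)

    matrix = ExpressionMatrix(
        values=values,
        sample_meta=meta,
        gene_biotype=pd.Series(biotype, index=values.index, name="biotype"),
        read_counts=read_counts,
    )
    truth = TruthTables(
        planted_dynamic={g: d for g, d in truth_dynamic.items()},
        planted_removed=removed,
        planted_sex=dict(zip(samples, sexes)),
        tissue_blocks=tissue_blocks,
        batch_genes=batch_genes,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Single cell


def _celltype_names(n: int) -> list[str]:
    if n <= len(CELL_TYPE_NAMES):
        return CELL_TYPE_NAMES[:n]
    return CELL_TYPE_NAMES + [f"Type{i + 1}" for i in range(n - len(CELL_TYPE_NAMES))]


def _sc_gene_layout(config: SynthConfig) -> tuple[list[str], dict[str, str], list[str], list[str], list[str], list[str]]:
    types = _celltype_names(config.n_celltypes)
    markers: dict[str, str] = {}
    for t in types:
        for i in range(config.n_markers_per_type):
            markers[f"MK_{t}_{i + 1}"] = t
    module = [f"MOD{i + 1}" for i in range(config.n_module_genes)]
    noise = [f"NOISE{i + 1}" for i in range(config.n_noise_genes)]
    mito = [f"mt-G{i + 1}" for i in range(config.n_mito_genes)]
    n_hk = config.n_sc_genes - len(markers) - len(module) - len(noise) - len(mito)
    if n_hk <= 0:
        raise ValueError("n_sc_genes too small for the configured gene blocks")
    hk = [f"HK{i + 1}" for i in range(n_hk)]
    genes = list(markers) + module + noise + mito + hk
    return genes, markers, module, noise, mito, hk


def _sc_rate_matrix(
    config: SynthConfig, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series, dict[str, str], list[str], list[str]]:
    """Per-cell per-gene Poisson rates for the planted populations."""
    types = _celltype_names(config.n_celltypes)
    genes, markers, module, noise, mito, hk = _sc_gene_layout(config)
    cells, labels = [], []
    for t in types:
        for i in range(config.n_cells_per_type):
            cells.append(f"{t}_c{i + 1}")
            labels.append(t)
    n_cells, n_genes = len(cells), len(genes)
    rates = np.zeros((n_cells, n_genes))
    gidx = {g: j for j, g in enumerate(genes)}
    lab = np.array(labels)

    for g, t in markers.items():
        j = gidx[g]
        in_mask = lab == t
        on_in = rng.random(n_cells) < config.marker_pct_in
        on_out = rng.random(n_cells) < config.marker_pct_out
        on = np.where(in_mask, on_in, on_out)
        rate = np.where(in_mask, config.marker_base_rate * config.marker_fold,
                        config.marker_base_rate)
        rates[:, j] = np.where(on, rate, 0.0)
    # the module is a co-activated program: the same cells burst for
    # every member gene, so each member looks marginally like a noise
    # gene (high dispersion) but the bursts co-occur
    module_on = rng.random(n_cells) < 0.3
    for g in module:
        rates[:, gidx[g]] = np.where(module_on, 12.0, 0.0)
    for g in noise:
        on = rng.random(n_cells) < 0.1  # sporadic bursts, independent per gene
        rates[:, gidx[g]] = np.where(on, 15.0, 0.0)
    for g in mito:
        rates[:, gidx[g]] = rng.uniform(2, 4)
    for g in hk:
        rates[:, gidx[g]] = rng.uniform(0.5, 3.0)

    return (
        pd.DataFrame(rates, index=pd.Index(cells, name="cell"), columns=genes),
        pd.Series(labels, index=cells, name="cell_type"),
        markers,
        module,
        noise,
    )


def generate_sc_counts(config: SynthConfig) -> tuple[CellMatrix, TruthTables]:
    """Droplet-style UMI count matrix with planted structure."""
    rng = config.rng(2)
    rates, labels, markers, module, noise = _sc_rate_matrix(config, rng)
    lib = np.exp(rng.normal(0.0, 0.3, len(rates)))  # library size factors
    counts = rng.poisson(rates.values * lib[:, None]).astype(float)

    # planted QC failures: half nearly-empty cells, half saturated cells
    qc_fail: list[str] = []
    fail_rows = []
    n_half = config.n_qc_fail_cells // 2
    for i in range(config.n_qc_fail_cells):
        cid = f"QCFAIL_{'low' if i < n_half else 'high'}_{i + 1}"
        qc_fail.append(cid)
        if i < n_half:
            fail_rows.append(rng.poisson(rates.values.mean(axis=0) * 0.02))
        else:
            fail_rows.append(rng.poisson(np.full(rates.shape[1], 8.0)))
    values = pd.DataFrame(
        np.vstack([counts] + [np.asarray(fail_rows, dtype=float)])
        if fail_rows
        else counts,
        index=pd.Index(list(rates.index) + qc_fail, name="cell"),
        columns=rates.columns,
    )
    all_labels = pd.concat(
        [labels, pd.Series(_celltype_names(config.n_celltypes)[0], index=qc_fail)]
    )
    matrix = CellMatrix(values=values, platform="tag")
    truth = TruthTables(
        planted_markers=markers,
        planted_module_genes=set(module),
        noise_genes=set(noise),
        qc_fail_cells=set(qc_fail),
        cell_labels=all_labels.rename("cell_type"),
    )
    return matrix, truth


def generate_sc_fpkm(config: SynthConfig) -> tuple[CellMatrix, TruthTables]:
    """Full-length plate-style FPKM matrix with a mapped-read companion.

    Reuses the droplet gene layout; FPKM is the per-cell rate scaled to
    abundance units plus bounded noise. A handful of cells are planted
    below the read-depth QC threshold.
    """
    rng = config.rng(3)
    rates, labels, markers, module, noise = _sc_rate_matrix(config, rng)
    fpkm = rates.values * 8.0 * np.exp2(rng.uniform(-0.3, 0.3, rates.shape))
    total = rng.integers(300_000, 900_000, len(rates)).astype(float)
    n_shallow = min(5, len(total))
    shallow = rng.choice(len(total), size=n_shallow, replace=False)
    total[shallow] = rng.integers(10_000, 99_000, n_shallow)
    values = pd.DataFrame(fpkm, index=rates.index, columns=rates.columns)
    matrix = CellMatrix(
        values=values,
        platform="full_length",
        total_mapped=pd.Series(total, index=rates.index),
    )
    truth = TruthTables(
        planted_markers=markers,
        planted_module_genes=set(module),
        noise_genes=set(noise),
        qc_fail_cells={rates.index[i] for i in shallow},
        cell_labels=labels,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Epigenome


NON_WHITELISTED_STATES = tuple(
    s for s in range(0, 13) if s not in POISED_STATES | ACTIVE_STATES | BIVALENT_STATES
)


def generate_epigenome(
    config: SynthConfig, marker_genes: dict[str, str] | None = None
) -> dict:
    """A toy genome with planted enhancer elements and decoy peaks.

    ``marker_genes`` maps exclusive-marker gene id -> cell type; by
    default the layout of ``generate_sc_counts`` is used so the
    epigenome is consistent with the single-cell truth. Returns a dict
    with genome, tss_table, peak BEDs per sample, segmentations, signal
    and input tracks, a matching bulk expression table, and truth.
    """
    rng = config.rng(4)
    if marker_genes is None:
        # default to the single-cell layout so epigenome and single-cell
        # truths are mutually consistent
        marker_genes = _sc_gene_layout(config)[1]
    marker_list = sorted(marker_genes)

    chrom_len = config.genome_length // config.n_chromosomes
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {
        c: "".join(rng.choice(list("ACGT"), size=chrom_len)) for c in chroms
    }

    # TSS slots on a regular grid, away from chromosome edges
    slots: list[tuple[str, int]] = []
    for c in chroms:
        pos = 20_000
        while pos < chrom_len - 20_000:
            slots.append((c, pos))
            pos += config.gene_spacing
    if len(slots) < len(marker_list) + 8:
        raise ValueError("genome too small for the gene layout")
    order = rng.permutation(len(slots))
    tss_rows = []
    n_nonexpressed = 6
    other_i = 0
    for k, si in enumerate(order):
        chrom, pos = slots[si]
        strand = "+" if k % 2 == 0 else "-"
        if k < len(marker_list):
            gene = marker_list[k]
            expressed = True
        elif k < len(order) - n_nonexpressed:
            other_i += 1
            gene = f"EXP_{other_i}"
            expressed = True
        else:
            gene = f"NX_{k}"
            expressed = False
        tss_rows.append(
            {"gene_id": gene, "chrom": chrom, "tss": pos, "strand": strand,
             "expressed": expressed}
        )
    tss_table = TssTable(pd.DataFrame(tss_rows))
    tss_of = {r["gene_id"]: (r["chrom"], r["tss"]) for r in tss_rows}

    # planted elements at controlled distances from marker TSSs
    planted: list[dict] = []
    class_cycle = [
        ("active", sorted(ACTIVE_STATES)),
        ("poised", sorted(POISED_STATES)),
        ("bivalent", sorted(BIVALENT_STATES)),
    ]
    w = config.element_width
    peaks_a: list[GenomicInterval] = []
    peaks_b: list[GenomicInterval] = []
    seg_a: list[GenomicInterval] = []
    seg_b: list[GenomicInterval] = []
    for i in range(config.n_enhancers):
        gene = marker_list[i % len(marker_list)]
        chrom, tss = tss_of[gene]
        d = config.element_distances[i % len(config.element_distances)]
        right = ((i // len(marker_list)) % 2) == 0
        if right:
            start, end = tss + d, tss + d + w
            ext = GenomicInterval(chrom, start, end + 100)  # far-side jitter
            merged = (start, end + 100)
        else:
            start, end = tss - d - w, tss - d
            ext = GenomicInterval(chrom, start - 100, end)
            merged = (start - 100, end)
        cls, state_pool = class_cycle[i % 3]
        state = int(state_pool[int(rng.integers(len(state_pool)))])
        iv = GenomicInterval(chrom, start, end)
        peaks_a.append(iv)
        peaks_b.append(ext)
        seg_iv = GenomicInterval(chrom, min(start, merged[0]) - 100,
                                 max(end, merged[1]) + 100, state=state)
        (seg_a if i % 2 == 0 else seg_b).append(seg_iv)
        planted.append(
            {
                "chrom": chrom,
                "start": merged[0],
                "end": merged[1],
                "gene": gene,
                "distance": d,
                "category": categorize_distance(d),
                "state_class": cls,
                "cell_type": marker_genes[gene],
            }
        )

    # decoy peaks midway between gene slots, covered only by
    # non-whitelisted states
    decoys: list[GenomicInterval] = []
    if config.n_decoys > len(slots):
        raise ValueError("more decoys than TSS slots")
    for i in range(config.n_decoys):
        # slot midpoints are at least several kb from any planted
        # element, so decoys can only overlap their own decoy state
        chrom, pos = slots[i]
        p = pos + config.gene_spacing // 2
        iv = GenomicInterval(chrom, p, p + 300)
        decoys.append(iv)
        state = int(NON_WHITELISTED_STATES[int(rng.integers(len(NON_WHITELISTED_STATES)))])
        cover = GenomicInterval(chrom, p - 100, p + 400, state=state)
        seg_a.append(cover)
        seg_b.append(cover)
        (peaks_a if i % 2 == 0 else peaks_b).append(iv)

    segmentation_a = StateSegmentation(intervals=sorted(seg_a, key=lambda v: (v.chrom, v.start)), sample_id="segA")
    segmentation_b = StateSegmentation(intervals=sorted(seg_b, key=lambda v: (v.chrom, v.start)), sample_id="segB")

    # NB-noised signal over fixed bins, elevated over planted elements
    m, v = config.nb_mean, config.nb_variance
    r, p_nb = m**2 / (v - m), m / v
    n_bins = {c: chrom_len // config.bin_width for c in chroms}
    signal = {c: rng.negative_binomial(r, p_nb, n_bins[c]).astype(float) for c in chroms}
    m2 = m * config.enhancer_fold
    v2 = v * config.enhancer_fold  # keep the variance/mean ratio
    r2, p2 = m2**2 / (v2 - m2), m2 / v2
    for el in planted:
        b0 = el["start"] // config.bin_width
        b1 = -(-el["end"] // config.bin_width)
        signal[el["chrom"]][b0:b1] = rng.negative_binomial(r2, p2, b1 - b0)
    input_values = {c: rng.negative_binomial(r, p_nb, n_bins[c]).astype(float) for c in chroms}

    signal_track = SignalTrack(values=signal, bin_width=config.bin_width,
                               sample_id="synthetic", mark="H3K27ac", role="signal")
    input_track = SignalTrack(values=input_values, bin_width=config.bin_width,
                              sample_id="synthetic", mark="input", role="input")

    # a matching bulk expression table so the expressed-gene filter can
    # be computed rather than trusted
    genes = [r["gene_id"] for r in tss_rows]
    expr = np.array(
        [rng.uniform(1, 50) if r["expressed"] else 0.01 for r in tss_rows]
    )
    bulk_values = pd.DataFrame(
        {f"limb_S{i + 1}": expr * rng.uniform(0.8, 1.2, len(expr)) for i in range(3)},
        index=pd.Index(genes, name="gene_id"),
    )
    bulk = ExpressionMatrix(
        values=bulk_values,
        sample_meta=pd.DataFrame(
            {"tissue": "limb", "stage": [f"S{i + 1}" for i in range(3)]},
            index=bulk_values.columns,
        ),
    )

    truth = TruthTables(
        planted_elements=planted,
        decoy_peaks=decoys,
        planted_markers=dict(marker_genes),
    )
    return {
        "genome": genome,
        "tss_table": tss_table,
        "peak_sets": {"sampleA": peaks_a, "sampleB": peaks_b},
        "segmentations": [segmentation_a, segmentation_b],
        "signal": signal_track,
        "input": input_track,
        "bulk_expression": bulk,
        "truth": truth,
    }


# ---------------------------------------------------------------------------
# De-repression tracks


def generate_derepression(config: SynthConfig, n_clusters: int = 10,
                          genes_per_cluster: int = 10) -> dict:
    """Per-timepoint promoter fold-change tracks with one planted
    de-repressed cluster (falling repressive signal, rising RNA)."""
    rng = config.rng(5)
    timepoints = ["T0", "T1", "T2", "T3"]
    spacing = 5000
    n_genes = n_clusters * genes_per_cluster
    chrom = "chrD"
    chrom_len = (n_genes + 2) * spacing
    bw = config.bin_width
    rows, clusters = [], {}
    for c in range(n_clusters):
        members = []
        for i in range(genes_per_cluster):
            g = f"DR{c}_{i + 1}"
            idx = c * genes_per_cluster + i
            rows.append({"gene_id": g, "chrom": chrom, "tss": spacing * (idx + 1),
                         "strand": "+", "expressed": True})
            members.append(g)
        clusters[c] = members
    tss_table = TssTable(pd.DataFrame(rows))
    n_bins = chrom_len // bw
    derepressed_levels = [2.0, 1.4, 0.8, 0.2]
    flat_level = 0.8
    tracks: dict[str, SignalTrack] = {}
    for tp_i, tp in enumerate(timepoints):
        v = rng.normal(0.0, 0.1, n_bins)
        for c, members in clusters.items():
            level = derepressed_levels[tp_i] if c == 0 else flat_level
            for g in members:
                tss = tss_table.table.loc[tss_table.table["gene_id"] == g, "tss"].iloc[0]
                b0, b1 = (tss - 2000) // bw, (tss + 2000) // bw
                v[b0:b1] += level
        tracks[tp] = SignalTrack(values={chrom: v}, bin_width=bw, mark="H3K27me3",
                                 role="log2fc", sample_id=tp)
    expr = {}
    for c, members in clusters.items():
        base = [1, 2, 4, 8] if c == 0 else [3, 3, 3, 3]
        for g in members:
            expr[g] = np.array(base, dtype=float) * rng.uniform(0.9, 1.1, 4)
    expression = pd.DataFrame(expr, index=timepoints).T
    return {
        "tracks": tracks,
        "tss_table": tss_table,
        "clusters": clusters,
        "expression": expression,
        "truth": TruthTables(planted_derepressed_cluster=0),
    }


# ---------------------------------------------------------------------------
# Motif planting


def synthetic_pwm(consensus: str, motif_id: str = "SYN_MOTIF", p: float = 0.94) -> PWM:
    """A near-deterministic PWM around a consensus sequence."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = len(consensus)
    mat = np.full((4, L), (1.0 - p) / 3.0)
    for j, b in enumerate(consensus):
        mat[idx[b], j] = p
    return PWM(motif_id=motif_id, matrix=mat)


def plant_motif_in_promoters(
    genome: dict[str, str],
    tss_table: TssTable,
    genes: list[str],
    consensus: str,
    fraction: float,
    rng: np.random.Generator,
    upstream: int = 500,
    margin: int = 60,
) -> tuple[dict[str, str], set[str]]:
    """Embed a consensus site in the upstream promoter of a fraction of
    the given genes, on the gene's strand.

    The site is kept at least ``margin`` bp away from the window edges
    so it survives small annotation-variant shifts of the TSS. Returns
    the modified genome and the set of genes that received a site.
    """
    from .motif_graph import reverse_complement

    L = len(consensus)
    seqs = {c: list(s) for c, s in genome.items()}
    n_plant = int(round(fraction * len(genes)))
    chosen = set(rng.choice(sorted(genes), size=n_plant, replace=False))
    t = tss_table.table.set_index("gene_id")
    for g in sorted(chosen):
        row = t.loc[g]
        offset = int(rng.integers(margin, upstream - margin - L))
        if row.strand == "+":
            pos = row.tss - upstream + offset
            seqs[row.chrom][pos : pos + L] = list(consensus)
        else:
            pos = row.tss + upstream - offset - L
            seqs[row.chrom][pos : pos + L] = list(reverse_complement(consensus))
    return {c: "".join(s) for c, s in seqs.items()}, chosen


def perturb_tss(tss_table: TssTable, max_shift: int, rng: np.random.Generator) -> TssTable:
    """An alternative annotation variant: every TSS shifted by up to
    ``max_shift`` bp in either direction."""
    t = tss_table.table.copy()
    t["tss"] = t["tss"] + rng.integers(-max_shift, max_shift + 1, len(t))
    t["tss"] = t["tss"].clip(lower=0)
    return TssTable(t)
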