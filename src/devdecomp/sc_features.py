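"""Single-cell QC, normalization, feature selection and marker calling.

Two platforms are handled: full-length plate data (FPKM per cell, with
a mapped-read companion) and droplet tag data (UMI counts). Feature
selection ranks genes by dispersion (variance over mean) and then keeps
only genes falling in "tight" co-expression clusters, which removes
sporadic high-dispersion genes that are not co-expressed with anything.
Markers are one-vs-rest Wilcoxon rank-sum calls with detection-fraction
filters, and exclusive markers are derived by cross-intersecting marker
sets across cell types and declared lineage groups.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd
from scipy import stats

MITO_PREFIX = "mt-"


@dataclass
class CellMatrix:
    """Cells x genes matrix with per-cell QC fields.

    ``values``: DataFrame, cells in rows, genes in columns; UMI counts
    for ``platform='tag'`` (10x-style) or FPKM for
    ``platform='full_length'`` (C1/SMART-seq-style).
    ``total_mapped``: reads mapped to the transcriptome per cell (for
    full-length data this comes from the aligner; for tag data it
    defaults to the UMI sum). ``n_genes_detected`` and
    ``mito_fraction`` are derived from ``values`` when not given.
    """

    values: pd.DataFrame
    platform: str = "tag"
    total_mapped: pd.Series | None = None
    n_genes_detected: pd.Series | None = None
    mito_fraction: pd.Series | None = None
    gene_biotype: pd.Series | None = None
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.platform not in {"tag", "full_length"}:
            raise ValueError(f"unknown platform {self.platform!r}")
        if (self.values.values < 0).any():
            raise ValueError("cell matrix values must be non-negative")
        if self.total_mapped is None:
            self.total_mapped = self.values.sum(axis=1)
        if self.n_genes_detected is None:
            self.n_genes_detected = (self.values > 0).sum(axis=1)
        if self.mito_fraction is None:
            mito = [g for g in self.values.columns if str(g).startswith(MITO_PREFIX)]
            tot = self.values.sum(axis=1)
            tot[tot == 0] = 1.0
            self.mito_fraction = self.values[mito].sum(axis=1) / tot

    @property
    def cells(self) -> pd.Index:
        return self.values.index

    @property
    def genes(self) -> pd.Index:
        return self.values.columns

    def subset(self, cells=None, genes=None) -> "CellMatrix":
        v = self.values
        if cells is not None:
            v = v.loc[cells]
        if genes is not None:
            v = v[genes]
        sel = lambda s: None if s is None else s.loc[v.index]
        return CellMatrix(
            values=v,
            platform=self.platform,
            total_mapped=sel(self.total_mapped),
            n_genes_detected=None,  # recomputed on the subset
            mito_fraction=None,
            gene_biotype=None if self.gene_biotype is None else self.gene_biotype.reindex(v.columns),
            normalized=self.normalized,
        )


@dataclass
class FeatureGeneSet:
    """High-dispersion genes that survive tight-cluster selection."""

    dispersion: pd.Series  # gene -> variance/mean, for the candidate set
    tight_cluster_id: pd.Series  # retained gene -> cluster id

    @property
    def genes(self) -> list[str]:
        return list(self.tight_cluster_id.index)


@dataclass
class MarkerTable:
    table: pd.DataFrame  # cluster, gene, p_value, p_adjusted, log2_fold_change, pct_in, pct_out
    min_pct: float
    min_diff_pct: float

    def markers_of(self, cluster: str, alpha: float = 0.05) -> set[str]:
        """Positively enriched markers of one cluster (the two-sided
        test also flags depletion, which is not a marker)."""
        t = self.table
        return set(
            t.loc[
                (t["cluster"] == cluster)
                & (t["p_adjusted"] < alpha)
                & (t["log2_fold_change"] > 0),
                "gene",
            ]
        )

    def significant(self, alpha: float = 0.05) -> pd.DataFrame:
        return self.table[self.table["p_adjusted"] < alpha]


# ---------------------------------------------------------------------------
# QC


def qc_filter_full_length(
    matrix: CellMatrix,
    min_reads: int = 100_000,
    min_genes: int = 4000,
    fpkm_cut: float = 10.0,
    min_cells: int = 5,
    min_gene_reads: int = 100,
    gene_read_counts: pd.DataFrame | None = None,
) -> CellMatrix:
    """QC for full-length (plate) single-cell FPKM data.

    Cells are removed when fewer than ``min_reads`` reads mapped to the
    transcriptome or fewer than ``min_genes`` genes exceed ``fpkm_cut``
    FPKM (boundaries inclusive of the stated minima: a cell at exactly
    100,000 reads or 4,000 genes is kept). Genes are then removed when
    expressed (> 0) in fewer than ``min_cells`` cells, or below
    ``fpkm_cut`` FPKM in all cells, or — when a per-gene read-count
    table is supplied — covered by fewer than ``min_gene_reads`` reads
    in all cells.
    """
    if matrix.platform != "full_length":
        raise ValueError("qc_filter_full_length expects full_length platform")
    v = matrix.values
    genes_above = (v >= fpkm_cut).sum(axis=1)
    keep_cells = (matrix.total_mapped >= min_reads) & (genes_above >= min_genes)
    v = v.loc[keep_cells]
    if v.empty:
        raise ValueError("no cells survive QC")
    expressed_in = (v > 0).sum(axis=0)
    keep_genes = (expressed_in >= min_cells) & (v.max(axis=0) >= fpkm_cut)
    if gene_read_counts is not None:
        keep_genes &= gene_read_counts.loc[v.index].max(axis=0) >= min_gene_reads
    out = matrix.subset(cells=v.index, genes=v.columns[keep_genes])
    if out.values.empty:
        raise ValueError("no genes survive QC")
    return out


def qc_filter_tag(
    matrix: CellMatrix,
    min_genes: int = 1000,
    min_cell_frac: float = 0.001,
    max_mito: float = 0.20,
    max_genes: int = 8000,
) -> CellMatrix:
    """QC for droplet (UMI) single-cell data.

    Cells with fewer than ``min_genes`` genes detected, more than
    ``max_genes`` genes detected, or more than ``max_mito`` fraction of
    mitochondrial counts are removed; genes detected in less than
    ``min_cell_frac`` of the remaining cells are then removed.
    """
    if matrix.platform != "tag":
        raise ValueError("qc_filter_tag expects tag platform")
    keep_cells = (
        (matrix.n_genes_detected >= min_genes)
        & (matrix.n_genes_detected <= max_genes)
        & (matrix.mito_fraction <= max_mito)
    )
    v = matrix.values.loc[keep_cells]
    if v.empty:
        raise ValueError("no cells survive QC")
    frac = (v > 0).sum(axis=0) / len(v)
    keep_genes = frac >= min_cell_frac
    out = matrix.subset(cells=v.index, genes=v.columns[keep_genes])
    if out.values.empty:
        raise ValueError("no genes survive QC")
    return out


def normalize_tag(matrix: CellMatrix, scale: float = 10_000.0) -> CellMatrix:
    """Library-size normalization for UMI counts: per cell, counts are
    divided by the cell sum, multiplied by ``scale``, incremented by 1
    and natural-log transformed."""
    sums = matrix.values.sum(axis=1)
    if (sums == 0).any():
        raise ValueError("zero-sum cell encountered; QC should have removed it")
    normed = np.log1p(matrix.values.div(sums, axis=0) * scale)
    out = matrix.subset()
    out.values = normed
    out.normalized = True
    return out


# ---------------------------------------------------------------------------
# Feature selection


def dispersion_rank(matrix: CellMatrix, top_n: int | None = None) -> pd.Series:
    """Genes ranked by dispersion = sample variance / sample mean
    (descending); zero-mean genes are excluded. Ties break by gene id."""
    v = matrix.values
    mean = v.mean(axis=0)
    var = v.var(axis=0, ddof=1)
    nz = mean > 0
    disp = (var[nz] / mean[nz]).rename("dispersion")
    df = disp.to_frame().assign(gene=disp.index.astype(str))
    ranked = df.sort_values(["dispersion", "gene"], ascending=[False, True])["dispersion"]
    if top_n is not None:
        if top_n > len(ranked):
            warnings.warn(
                f"top_n={top_n} exceeds {len(ranked)} genes with non-zero mean; using all",
                stacklevel=2,
            )
            top_n = len(ranked)
        ranked = ranked.head(top_n)
    return ranked


def select_tight_cluster_features(
    matrix: CellMatrix,
    top_n: int = 4000,
    cut: float = 0.8,
    min_members: int = 3,
) -> FeatureGeneSet:
    """Keep high-dispersion genes that fall in tight co-expression
    clusters.

    The ``top_n`` genes by dispersion are clustered (1 - Pearson over
    cells, average linkage); the dendrogram is cut at height ``cut``
    and genes in clusters with more than two members (>= ``min_members``)
    are retained. Sporadic genes that are highly dispersed but not
    co-expressed with anything fall in singleton clusters and are
    dropped.
    """
    disp = dispersion_rank(matrix, top_n=top_n)
    genes = sorted(disp.index, key=str)
    if len(genes) < min_members:
        warnings.warn("fewer genes than min_members; empty feature set", stacklevel=2)
        return FeatureGeneSet(dispersion=disp, tight_cluster_id=pd.Series(dtype=int))
    X = matrix.values[genes].T.values.astype(float)  # genes x cells
    sd = X.std(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = np.clip(1.0 - corr, 0.0, 2.0)
    np.fill_diagonal(dist, 0.0)
    Z = sch.linkage(ssd.squareform(dist, checks=False), method="average")
    labels = sch.fcluster(Z, t=cut, criterion="distance")
    counts = pd.Series(labels).value_counts()
    tight = set(counts.index[counts >= min_members])
    keep = pd.Series(labels, index=pd.Index(genes)).loc[
        lambda s: s.isin(tight)
    ]
    return FeatureGeneSet(dispersion=disp, tight_cluster_id=keep.astype(int))


# ---------------------------------------------------------------------------
# Marker calling


def find_markers(
    matrix: CellMatrix,
    labels: pd.Series,
    min_pct: float = 0.25,
    min_diff_pct: float = 0.2,
    pseudocount: float = 1.0,
) -> MarkerTable:
    """One-vs-rest marker genes per cluster by Wilcoxon rank-sum.

    ``matrix`` must be normalized (natural-log) tag data or log FPKM.
    A gene is tested for a cluster only if its detection fraction is at
    least ``min_pct`` in the cluster or in the rest, and the absolute
    difference of detection fractions is at least ``min_diff_pct``.
    P values come from the two-sided normal approximation with tie
    correction and are Bonferroni-adjusted over all genes in the
    matrix (per cluster). The log2 fold change compares de-logged group
    means with a pseudocount.
    """
    labels = labels.reindex(matrix.cells)
    if labels.isna().any():
        missing = list(labels.index[labels.isna()])[:5]
        raise ValueError(f"cells without a cluster label: {missing}")
    clusters = sorted(map(str, labels.unique()))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    counts = labels.astype(str).value_counts()
    small = counts[counts < 3]
    if len(small):
        raise ValueError(f"clusters with fewer than 3 cells: {list(small.index)}")
    V = matrix.values
    n_genes_total = V.shape[1]
    delog = np.expm1(V) if matrix.normalized else V
    rows = []
    lab = labels.astype(str).values
    for cl in clusters:
        in_mask = lab == cl
        X_in = V.values[in_mask]
        X_out = V.values[~in_mask]
        pct_in = (X_in > 0).mean(axis=0)
        pct_out = (X_out > 0).mean(axis=0)
        testable = (
            ((pct_in >= min_pct) | (pct_out >= min_pct))
            & (np.abs(pct_in - pct_out) >= min_diff_pct)
        )
        idx = np.flatnonzero(testable)
        if len(idx) == 0:
            continue
        stat, p = stats.mannwhitneyu(
            X_in[:, idx], X_out[:, idx], alternative="two-sided", method="asymptotic"
        )
        mean_in = delog.values[in_mask][:, idx].mean(axis=0)
        mean_out = delog.values[~in_mask][:, idx].mean(axis=0)
        lfc = np.log2((mean_in + pseudocount) / (mean_out + pseudocount))
        p_adj = np.minimum(1.0, p * n_genes_total)
        for j, gi in enumerate(idx):
            rows.append(
                {
                    "cluster": cl,
                    "gene": str(V.columns[gi]),
                    "p_value": p[j],
                    "p_adjusted": p_adj[j],
                    "log2_fold_change": lfc[j],
                    "pct_in": pct_in[gi],
                    "pct_out": pct_out[gi],
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "cluster", "gene", "p_value", "p_adjusted",
            "log2_fold_change", "pct_in", "pct_out",
        ],
    ).sort_values(["cluster", "p_adjusted", "gene"]).reset_index(drop=True)
    return MarkerTable(table=table, min_pct=min_pct, min_diff_pct=min_diff_pct)


def derive_exclusive_markers(
    marker_sets: dict[str, set[str]],
    groups: dict[str, frozenset] | None = None,
) -> dict[str, str]:
    """Cross-intersect per-cluster marker sets into exclusive markers.

    A gene is an exclusive marker of a cell type when it is a marker
    there and nowhere else; a gene that is a marker in exactly the
    member types of a declared lineage group (e.g. "Muscle1+Muscle2")
    and in no other type is an exclusive marker of that group. Genes
    whose marker pattern matches neither are dropped.

    Returns gene -> cell type or group name. Raises if two declared
    groups share the same member set (the assignment would be
    ambiguous).
    """
    groups = groups or {}
    seen: dict[frozenset, str] = {}
    for name, members in groups.items():
        members = frozenset(members)
        if members in seen:
            raise ValueError(
                f"ambiguous group definitions: {seen[members]!r} and {name!r} "
                "have identical members"
            )
        if len(members) < 2:
            raise ValueError(f"group {name!r} must have at least two members")
        unknown = members - set(marker_sets)
        if unknown:
            raise ValueError(f"group {name!r} references unknown types: {sorted(unknown)}")
        seen[members] = name
    gene_pattern: dict[str, set[str]] = {}
    for cl, genes in marker_sets.items():
        for g in genes:
            gene_pattern.setdefault(g, set()).add(cl)
    out: dict[str, str] = {}
    for gene, pattern in gene_pattern.items():
        if len(pattern) == 1:
            out[gene] = next(iter(pattern))
        else:
            name = seen.get(frozenset(pattern))
            if name is not None:
                out[gene] = name
    return out
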