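"""Structure of the bulk tissue-by-stage developmental transcriptome.

The whole-tissue RNA-seq side of the pipeline: partition genes into
dynamic versus ubiquitous by fold range, interpret the sample space by
PCA, cluster dynamic genes into co-expression clades, relate the PC
space to sample metadata by canonical correlation analysis (CCA), infer
embryo sex from Xist/Ddx3y, and stratify ubiquitous genes by abundance.

All expression values enter as linear FPKM (or TPM); log transforms use
log2 with a 0.1 pseudocount throughout so that lowly expressed genes
remain visible without masking zeros.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
import scipy.spatial.distance as ssd

DEFAULT_PSEUDOCOUNT = 0.1
DYNAMIC_FOLD = 10.0


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance matrix with sample metadata.

    ``values``: DataFrame, genes in rows, samples in columns, linear
    FPKM/TPM. ``sample_meta``: DataFrame indexed by sample id with
    columns tissue, stage, sex, batch, replicate. ``gene_biotype``:
    Series per gene (e.g. protein_coding, tRNA). ``read_counts``:
    optional genes x samples mapped-read counts used by the prefilter.
    """

    values: pd.DataFrame
    sample_meta: pd.DataFrame
    gene_biotype: pd.Series | None = None
    read_counts: pd.DataFrame | None = None
    units: str = "FPKM"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("expression values must be non-negative")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids")
        if not self.values.columns.equals(pd.Index(self.sample_meta.index)):
            # allow same set in same order only
            if set(self.values.columns) != set(self.sample_meta.index):
                raise ValueError("sample metadata does not match matrix columns")
            self.sample_meta = self.sample_meta.loc[self.values.columns]
        required = {"tissue", "stage"}
        missing = required - set(self.sample_meta.columns)
        if missing:
            raise ValueError(f"sample_meta missing columns: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def subset_genes(self, genes) -> "ExpressionMatrix":
        return ExpressionMatrix(
            values=self.values.loc[genes],
            sample_meta=self.sample_meta,
            gene_biotype=None if self.gene_biotype is None else self.gene_biotype.loc[genes],
            read_counts=None if self.read_counts is None else self.read_counts.loc[genes],
            units=self.units,
        )


@dataclass
class GenePartition:
    """Dynamic / ubiquitous / removed label per gene with its fold range."""

    labels: pd.Series  # gene -> {dynamic, ubiquitous, removed}
    fold_ratio: pd.Series  # gene -> max/min ratio (NaN for removed)

    def genes_with(self, label: str) -> list[str]:
        return list(self.labels.index[self.labels == label])


@dataclass
class PCAResult:
    loadings: pd.DataFrame  # genes x PCs, unit-norm columns
    scores: pd.DataFrame  # samples x PCs, z-scored per PC
    raw_scores: pd.DataFrame  # samples x PCs, centred projections
    var_explained: pd.Series  # per PC, fraction of total variance


@dataclass
class CCAResult:
    correlations: np.ndarray  # canonical correlations, non-increasing
    x_coef: pd.DataFrame  # PC-side coefficients (PCs x variates)
    y_coef: pd.DataFrame  # metadata-side coefficients (columns x variates)
    x_variates: pd.DataFrame  # samples x variates, standardized
    y_variates: pd.DataFrame
    gene_loadings: pd.DataFrame  # genes x variates = PCA loadings @ x_coef


@dataclass
class ClusterSet:
    linkage: np.ndarray  # scipy linkage matrix over the clustered genes
    genes: list[str]  # leaf order corresponds to linkage input order
    major_clusters: list[tuple[int, list[str]]]  # (cluster id, members)

    def membership(self) -> pd.Series:
        rows = {}
        for cid, members in self.major_clusters:
            for g in members:
                rows[g] = cid
        return pd.Series(rows, name="cluster")


# ---------------------------------------------------------------------------


def log_transform(values: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """log2(x + pseudocount), elementwise; rejects negative input."""
    if (values.values < 0).any():
        raise ValueError("log_transform requires non-negative values")
    return np.log2(values + pseudocount)


def prefilter_genes(
    matrix: ExpressionMatrix, min_reads: int = 10
) -> tuple[ExpressionMatrix, list[str]]:
    """Drop genes covered by fewer than ``min_reads`` reads in every
    sample, and tRNA-biotype genes.

    Returns the filtered matrix and the list of removed gene ids.
    Requires the mapped-read-count companion table.
    """
    if matrix.read_counts is None:
        raise ValueError("prefilter_genes requires the read-count companion table")
    max_reads = matrix.read_counts.max(axis=1)
    keep = max_reads >= min_reads
    if matrix.gene_biotype is not None:
        keep &= matrix.gene_biotype.reindex(matrix.genes).fillna("unknown") != "tRNA"
    removed = list(matrix.genes[~keep])
    return matrix.subset_genes(matrix.genes[keep]), removed


def partition_dynamic_genes(
    matrix: ExpressionMatrix,
    fold: float = DYNAMIC_FOLD,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    removed: list[str] | None = None,
) -> GenePartition:
    """Label each gene dynamic (max/min FPKM ratio >= ``fold``, boundary
    inclusive) or ubiquitous.

    Operates on linear units. The minimum is floored at the log-
    transform pseudocount so genes absent from some samples get a
    finite ratio. Previously removed genes can be appended with the
    ``removed`` label for a complete partition of the original gene set.
    """
    if matrix.values.shape[1] < 2:
        raise ValueError("fold-range partition needs at least two samples")
    v = matrix.values
    ratio = v.max(axis=1) / v.min(axis=1).clip(lower=pseudocount)
    labels = pd.Series(
        np.where(ratio >= fold, "dynamic", "ubiquitous"), index=v.index
    )
    if removed:
        labels = pd.concat([labels, pd.Series("removed", index=pd.Index(removed))])
        ratio = pd.concat([ratio, pd.Series(np.nan, index=pd.Index(removed))])
    return GenePartition(labels=labels, fold_ratio=ratio)


def run_pca(matrix_log: pd.DataFrame, n_pcs: int = 20) -> PCAResult:
    """PCA of the log-transformed matrix with samples as observations.

    Genes are centred but not scaled, so abundant dynamic genes drive
    the leading components. Loadings are unit-norm eigenvectors; the
    reported scores are z-scored projections (mean 0, sd 1 per PC over
    samples). The sign of each component is fixed so the gene with the
    largest absolute loading is positive.
    """
    genes = matrix_log.index
    samples = matrix_log.columns
    X = matrix_log.T.values.astype(float)  # samples x genes
    n, p = X.shape
    if n_pcs > min(n, p):
        raise ValueError(f"n_pcs={n_pcs} exceeds min(samples, genes)={min(n, p)}")
    Xc = X - X.mean(axis=0, keepdims=True)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[:n_pcs].T  # genes x n_pcs
    # deterministic sign: largest-|loading| gene positive; among equal
    # |loading| the lexicographically smallest gene id decides
    for k in range(n_pcs):
        col = load[:, k]
        best = np.abs(col).max()
        cands = np.flatnonzero(np.isclose(np.abs(col), best))
        idx = min(cands, key=lambda i: str(genes[i]))
        if col[idx] < 0:
            load[:, k] = -col
            U[:, k] = -U[:, k]
    raw = U[:, :n_pcs] * S[:n_pcs]
    sd = raw.std(axis=0, ddof=1)
    sd[sd == 0] = 1.0
    z = (raw - raw.mean(axis=0)) / sd
    pcs = [f"PC{i + 1}" for i in range(n_pcs)]
    total_var = (S**2).sum()
    return PCAResult(
        loadings=pd.DataFrame(load, index=genes, columns=pcs),
        scores=pd.DataFrame(z, index=samples, columns=pcs),
        raw_scores=pd.DataFrame(raw, index=samples, columns=pcs),
        var_explained=pd.Series(S[:n_pcs] ** 2 / total_var, index=pcs),
    )


def top_loading_genes(
    pca: PCAResult, pc: str | int, k: int = 100
) -> tuple[list[str], list[str]]:
    """The k genes with the highest positive and the k with the lowest
    negative loadings on one PC; ties broken by gene id."""
    if isinstance(pc, int):
        pc = f"PC{pc}"
    col = pca.loadings[pc]
    if k > len(col):
        raise ValueError(f"k={k} exceeds number of genes {len(col)}")
    df = pd.DataFrame({"loading": col, "gene": col.index.astype(str)})
    pos = df.sort_values(["loading", "gene"], ascending=[False, True]).head(k)
    neg = df.sort_values(["loading", "gene"], ascending=[True, True]).head(k)
    return list(pos["gene"]), list(neg["gene"])


def _correlation_distance(matrix_log: pd.DataFrame) -> np.ndarray:
    """Condensed 1 - Pearson distance over genes (rows); constant genes
    sit at distance 1 from everything, with a warning."""
    X = matrix_log.values.astype(float)
    sd = X.std(axis=1)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{const.sum()} constant gene(s): correlation undefined, "
            "assigned distance 1 to all",
            stacklevel=3,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr[np.isnan(corr)] = 0.0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip(dist, 0.0, 2.0)
    return ssd.squareform(dist, checks=False)


def cluster_genes(
    matrix_log: pd.DataFrame, min_clade: int = 30
) -> ClusterSet:
    """Average-linkage hierarchical clustering of genes with 1 - Pearson
    distance, then major-clade extraction.

    Genes are sorted by id before clustering so the result does not
    depend on input order. Major clusters are found by traversing from
    the root towards the leaves: a clade is split while both of its
    children hold at least ``min_clade`` leaves; clades that can no
    longer be split (and have >= min_clade leaves) are the major
    clusters.
    """
    matrix_log = matrix_log.loc[sorted(matrix_log.index, key=str)]
    genes = list(matrix_log.index)
    if len(genes) < 2:
        raise ValueError("need at least two genes to cluster")
    d = _correlation_distance(matrix_log)
    Z = sch.linkage(d, method="average")
    root = sch.to_tree(Z)

    clusters: list[list[str]] = []

    def visit(node) -> None:
        if node.get_count() < min_clade:
            return
        left, right = node.get_left(), node.get_right()
        if (
            left is not None
            and right is not None
            and left.get_count() >= min_clade
            and right.get_count() >= min_clade
        ):
            visit(left)
            visit(right)
        else:
            clusters.append([genes[i] for i in node.pre_order()])

    visit(root)
    major = [(i + 1, sorted(members)) for i, members in enumerate(clusters)]
    return ClusterSet(linkage=Z, genes=genes, major_clusters=major)


def encode_metadata(
    sample_meta: pd.DataFrame,
    columns: tuple[str, ...] = ("tissue", "stage", "sex", "batch"),
) -> pd.DataFrame:
    """One-hot Boolean design matrix from categorical sample metadata."""
    cols = [c for c in columns if c in sample_meta.columns]
    design = pd.get_dummies(sample_meta[cols].astype(str), dtype=float)
    return design


def _drop_collinear(design: pd.DataFrame, tol: float = 1e-8) -> pd.DataFrame:
    """Greedily drop columns that are linear combinations of earlier
    ones. Columns are centred first (CCA works on centred variables, so
    a full one-hot block is collinear with the implicit intercept)."""
    X = design.values.astype(float)
    X = X - X.mean(axis=0, keepdims=True)
    keep: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, keep + [j]]
        if np.linalg.matrix_rank(cand, tol=tol * max(1.0, np.abs(cand).max())) > len(keep):
            keep.append(j)
    return design.iloc[:, keep]


def run_cca(
    pca: PCAResult,
    design: pd.DataFrame,
    n_pcs: int = 20,
) -> CCAResult:
    """Canonical correlation analysis between the top PC scores and a
    Boolean metadata design matrix.

    Collinear design columns are dropped first. Gene-level canonical
    loadings are the product of the PCA gene-loading matrix and the
    PC-side canonical coefficients, which places each canonical axis
    back in gene space.
    """
    scores = pca.scores.iloc[:, :n_pcs]
    design = _drop_collinear(design)
    n = scores.shape[0]
    rank = np.linalg.matrix_rank(design.values - design.values.mean(axis=0))
    if n <= rank:
        raise ValueError(
            f"{n} samples cannot support a metadata design of rank {rank}"
        )
    # classical CCA via QR + SVD of the cross-product of orthonormal bases
    Xc = scores.values - scores.values.mean(axis=0)
    Yc = design.values.astype(float) - design.values.mean(axis=0)
    Qx, Rx = np.linalg.qr(Xc)
    Qy, Ry = np.linalg.qr(Yc)
    U, s, Vt = np.linalg.svd(Qx.T @ Qy)
    k = min(Xc.shape[1], np.linalg.matrix_rank(Ry))
    corrs = s[:k]
    a = np.linalg.solve(Rx, U[:, :k]) * np.sqrt(n - 1)
    b = np.linalg.lstsq(Ry, Vt.T[:, :k], rcond=None)[0] * np.sqrt(n - 1)
    # deterministic sign: largest-|coefficient| metadata column positive
    for j in range(k):
        i = int(np.argmax(np.abs(b[:, j])))
        if b[i, j] < 0:
            b[:, j] = -b[:, j]
            a[:, j] = -a[:, j]
    x_coef = pd.DataFrame(
        a, index=scores.columns, columns=[f"CC{i + 1}" for i in range(k)]
    )
    y_coef = pd.DataFrame(b, index=design.columns, columns=x_coef.columns)
    xv = scores.values @ x_coef.values
    yv = design.values @ y_coef.values

    def standardize(a: np.ndarray) -> np.ndarray:
        sd = a.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        return (a - a.mean(axis=0)) / sd

    gene_loadings = pca.loadings.iloc[:, :n_pcs].values @ x_coef.values
    return CCAResult(
        correlations=np.clip(corrs, 0.0, 1.0),
        x_coef=x_coef,
        y_coef=y_coef,
        x_variates=pd.DataFrame(standardize(xv), index=scores.index, columns=x_coef.columns),
        y_variates=pd.DataFrame(standardize(yv), index=scores.index, columns=x_coef.columns),
        gene_loadings=pd.DataFrame(
            gene_loadings, index=pca.loadings.index, columns=x_coef.columns
        ),
    )


def infer_sex(
    matrix: ExpressionMatrix,
    xist_id: str = "Xist",
    ddx3y_id: str = "Ddx3y",
    detect_threshold: float = 1.0,
) -> pd.Series:
    """Per-sample sex call from the female marker Xist and the male
    marker Ddx3y: female if only Xist is detected, male if only Ddx3y,
    mixed if both (pooled embryos of both sexes), unknown if neither.

    A marker counts as detected at FPKM >= ``detect_threshold``.
    """
    for g in (xist_id, ddx3y_id):
        if g not in matrix.genes:
            raise ValueError(f"sex marker gene {g!r} absent from matrix")
    xist = matrix.values.loc[xist_id] >= detect_threshold
    ddx3y = matrix.values.loc[ddx3y_id] >= detect_threshold
    out = pd.Series("unknown", index=matrix.samples, name="sex")
    out[xist & ~ddx3y] = "female"
    out[~xist & ddx3y] = "male"
    out[xist & ddx3y] = "mixed"
    return out


def stratify_ubiquitous(
    matrix_log: pd.DataFrame,
    ubiquitous_genes: list[str],
    n: int = 3000,
    min_log2: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, list[str]]:
    """Split the ``n`` least-variable well-expressed ubiquitous genes
    into equal high / medium / low abundance groups.

    Genes whose mean log2(FPKM + 0.1) is no higher than ``min_log2``
    are removed first (boundary exclusive: a gene exactly at the cut is
    dropped). The ``n`` genes with smallest sample variance of the log
    values are ranked by mean linear FPKM and split into three equal
    groups.
    """
    sub = matrix_log.loc[[g for g in ubiquitous_genes if g in matrix_log.index]]
    eligible = sub[sub.mean(axis=1) > min_log2]
    if len(eligible) < n:
        warnings.warn(
            f"only {len(eligible)} eligible ubiquitous genes (< {n}); using all",
            stacklevel=2,
        )
        n = len(eligible)
    var = eligible.var(axis=1, ddof=1)
    ranked = var.to_frame("var").assign(gene=var.index.astype(str))
    chosen = ranked.sort_values(["var", "gene"]).head(n).index
    mean_fpkm = (np.power(2.0, eligible.loc[chosen]) - pseudocount).mean(axis=1)
    df = mean_fpkm.to_frame("mean").assign(gene=mean_fpkm.index.astype(str))
    ordered = df.sort_values(["mean", "gene"], ascending=[False, True]).index
    thirds = np.array_split(np.arange(len(ordered)), 3)
    return {
        "high": list(ordered[thirds[0]]),
        "medium": list(ordered[thirds[1]]),
        "low": list(ordered[thirds[2]]),
    }
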