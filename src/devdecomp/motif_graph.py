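"""Promoter motif enrichment and the motif-cluster bipartite graph.

Upstream promoter sequences of each co-expression cluster (or cell
type's marker genes) are pooled and scanned with position weight
matrices; per-motif enrichment of the foreground pool against a
background pool is scored by a one-sided Fisher exact test on
thresholded hits, Bonferroni-corrected over the motif library. Because
promoter coordinates depend on the gene annotation, the analysis is run
under two annotation variants and a motif counts as significant only
when its corrected P value clears the cutoff in both. Significant
(motif, cluster) pairs form a bipartite graph whose motif nodes are
flagged as shared (enriched in more than one cluster) or unique.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import PWM, TssTable

COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
PROMOTER_UPSTREAM = 500
HIT_QUANTILE = 0.999
ALPHA = 0.01


def reverse_complement(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def extract_promoters(
    tss: TssTable, genome: dict[str, str], upstream: int = PROMOTER_UPSTREAM
) -> dict[str, str]:
    """Upstream promoter sequence per gene, read on the gene's strand.

    Plus-strand genes take ``[tss - upstream, tss)``; minus-strand
    genes take the reverse complement of ``[tss, tss + upstream)``.
    Windows running off a chromosome end are truncated with a warning;
    a TSS outside the chromosome raises.
    """
    import warnings

    out: dict[str, str] = {}
    truncated = 0
    for row in tss.table.itertuples(index=False):
        if row.chrom not in genome:
            raise ValueError(f"chromosome {row.chrom!r} absent from genome")
        seq = genome[row.chrom]
        if not (0 <= row.tss <= len(seq)):
            raise ValueError(f"TSS of {row.gene_id} outside chromosome {row.chrom}")
        if row.strand == "+":
            lo, hi = row.tss - upstream, row.tss
            if lo < 0:
                truncated += 1
                lo = 0
            out[str(row.gene_id)] = seq[lo:hi]
        else:
            lo, hi = row.tss, row.tss + upstream
            if hi > len(seq):
                truncated += 1
                hi = len(seq)
            out[str(row.gene_id)] = reverse_complement(seq[lo:hi])
    if truncated:
        warnings.warn(f"{truncated} promoter(s) truncated at chromosome ends", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# PWM scanning


def _log_odds(pwm: PWM, background: float = 0.25, eps: float = 1e-9) -> np.ndarray:
    return np.log2((pwm.matrix + eps) / background)


_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}


def _max_score(seq: str, lo: np.ndarray) -> float:
    """Best log-odds window score over both strands; -inf when the
    sequence is shorter than the motif or every window contains N."""
    L = lo.shape[1]
    best = -np.inf
    cols = np.arange(L)
    for s in (seq, reverse_complement(seq)):
        n = len(s)
        if n < L:
            continue
        idx = np.frombuffer(s.encode("ascii"), dtype=np.uint8)
        code = np.full(256, -1, dtype=np.int64)
        for b, i in _BASE_INDEX.items():
            code[ord(b)] = i
        enc = code[idx]
        windows = np.lib.stride_tricks.sliding_window_view(enc, L)
        ok = (windows >= 0).all(axis=1)
        if not ok.any():
            continue
        scores = lo[windows[ok], cols].sum(axis=1)
        best = max(best, float(scores.max()))
    return best


def _shuffle(seq: str, rng: np.random.Generator) -> str:
    chars = np.array(list(seq))
    rng.shuffle(chars)
    return "".join(chars)


def scan_pwm_hits(
    sequences: dict[str, str],
    pwm: PWM,
    hit_threshold_quantile: float = HIT_QUANTILE,
    seed: int = 0,
    n_shuffles: int = 2,
) -> pd.Series:
    """Boolean hit per sequence: best log-odds window score (both
    strands, uniform background) at or above the null threshold.

    The threshold is the ``hit_threshold_quantile`` quantile of max
    scores on mononucleotide-shuffled copies of the input sequences
    (seeded, hence reproducible).
    """
    lo = _log_odds(pwm)
    rng = np.random.default_rng(seed)
    null_scores = []
    for seq in sequences.values():
        for _ in range(n_shuffles):
            s = _max_score(_shuffle(seq, rng), lo)
            if np.isfinite(s):
                null_scores.append(s)
    if not null_scores:
        return pd.Series({name: False for name in sequences})
    threshold = float(np.quantile(null_scores, hit_threshold_quantile))
    return pd.Series(
        {name: _max_score(seq, lo) >= threshold for name, seq in sequences.items()}
    )


# ---------------------------------------------------------------------------
# Enrichment


@dataclass
class EnrichmentResult:
    """Per (motif, variant): raw and Bonferroni-corrected Fisher P;
    a motif is significant only if corrected P < alpha in every
    annotation variant."""

    table: pd.DataFrame  # motif, variant, fg_hits, fg_total, bg_hits, bg_total, p_raw, p_corrected
    alpha: float = ALPHA

    def significant_motifs(self) -> list[str]:
        t = self.table
        ok = t.groupby("motif")["p_corrected"].max() < self.alpha
        return sorted(ok.index[ok])

    def corrected_p(self, motif: str) -> float:
        """Worst (largest) corrected P across variants for a motif."""
        return float(self.table.loc[self.table["motif"] == motif, "p_corrected"].max())


def fisher_enrichment(
    fg_hits: int, fg_total: int, bg_hits: int, bg_total: int
) -> float:
    """One-sided Fisher exact P that the foreground hit fraction
    exceeds the non-foreground background's. The foreground must be a
    subset of the background pool."""
    if not (0 <= fg_hits <= fg_total and 0 <= bg_hits <= bg_total):
        raise ValueError("invalid hit counts")
    if fg_total > bg_total or fg_hits > bg_hits:
        raise ValueError("foreground must be a subset of the background pool")
    rest_hits = bg_hits - fg_hits
    rest_total = bg_total - fg_total
    table = [[fg_hits, fg_total - fg_hits], [rest_hits, rest_total - rest_hits]]
    return float(stats.fisher_exact(table, alternative="greater")[1])


def enrich_motifs(
    foregrounds: dict[str, dict[str, str]],
    backgrounds: dict[str, dict[str, str]],
    motifs: list[PWM],
    alpha: float = ALPHA,
    hit_threshold_quantile: float = HIT_QUANTILE,
    seed: int = 0,
) -> EnrichmentResult:
    """Motif enrichment of a foreground promoter pool against a
    background pool, run once per annotation variant.

    ``foregrounds`` and ``backgrounds`` map variant name -> {gene:
    sequence}; each foreground gene set must be contained in the
    matching background after de-duplication. Raw one-sided Fisher P
    values are Bonferroni-corrected by the motif library size.
    """
    if set(foregrounds) != set(backgrounds):
        raise ValueError("foreground and background variants differ")
    n_motifs = len(motifs)
    rows = []
    for variant in sorted(foregrounds):
        fg, bg = foregrounds[variant], backgrounds[variant]
        if not set(fg) <= set(bg):
            raise ValueError(
                f"variant {variant!r}: foreground genes not a subset of background"
            )
        for k, pwm in enumerate(motifs):
            hits = scan_pwm_hits(
                bg, pwm, hit_threshold_quantile, seed=seed * 100_003 + k
            )
            fg_hits = int(hits[list(fg)].sum())
            bg_hits = int(hits.sum())
            p = fisher_enrichment(fg_hits, len(fg), bg_hits, len(bg))
            rows.append(
                {
                    "motif": pwm.motif_id,
                    "variant": variant,
                    "fg_hits": fg_hits,
                    "fg_total": len(fg),
                    "bg_hits": bg_hits,
                    "bg_total": len(bg),
                    "p_raw": p,
                    "p_corrected": min(1.0, p * n_motifs),
                }
            )
    return EnrichmentResult(table=pd.DataFrame(rows), alpha=alpha)


# ---------------------------------------------------------------------------
# Bipartite graph


def build_bipartite_graph(
    cluster_results: dict[str, EnrichmentResult],
    cluster_sizes: dict[str, int] | None = None,
) -> nx.Graph:
    """Bipartite motif-cluster graph of significant enrichments.

    One edge per (motif, cluster) significant in both annotation
    variants, weighted by -log10 of the worse corrected P (floored at
    1e-300). Motif nodes get ``kind='motif'`` and ``shared`` True when
    enriched in more than one cluster; cluster nodes get
    ``kind='cluster'`` and their gene count as ``size``.
    """
    g = nx.Graph()
    cluster_sizes = cluster_sizes or {}
    for cluster, res in cluster_results.items():
        g.add_node(f"cluster:{cluster}", kind="cluster", label=str(cluster),
                   size=cluster_sizes.get(cluster, 0))
        for motif in res.significant_motifs():
            node = f"motif:{motif}"
            if node not in g:
                g.add_node(node, kind="motif", label=motif)
            p = max(res.corrected_p(motif), 1e-300)
            g.add_edge(node, f"cluster:{cluster}", weight=float(-np.log10(p)))
    for node, data in g.nodes(data=True):
        if data["kind"] == "motif":
            data["shared"] = g.degree(node) > 1
    return g


def graph_to_json(g: nx.Graph) -> str:
    payload = {
        "nodes": [
            {"id": n, **{k: (bool(v) if isinstance(v, np.bool_) else v) for k, v in d.items()}}
            for n, d in sorted(g.nodes(data=True))
        ],
        "edges": [
            {"source": u, "target": v, "weight": d["weight"]}
            for u, v, d in sorted(g.edges(data=True))
        ],
    }
    return json.dumps(payload, indent=2, sort_keys=True)


def graph_to_dot(g: nx.Graph) -> str:
    lines = ["graph motif_clusters {"]
    for n, d in sorted(g.nodes(data=True)):
        if d["kind"] == "cluster":
            attrs = f'shape=box,label="{d["label"]}"'
        else:
            color = "grey" if d.get("shared") else "yellow"
            attrs = f'shape=ellipse,style=filled,fillcolor={color},label="{d["label"]}"'
        lines.append(f'  "{n}" [{attrs}];')
    for u, v, d in sorted(g.edges(data=True)):
        lines.append(f'  "{u}" -- "{v}" [penwidth={d["weight"]:.2f}];')
    lines.append("}")
    return "\n".join(lines)
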