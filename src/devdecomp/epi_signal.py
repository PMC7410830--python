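"""Negative-binomial significance tracks and promoter-window statistics.

Raw epigenomic signal (ChIP-seq, ATAC, DNase) over fixed genome bins is
converted to capped -log10 P values under a negative binomial
background whose mean and variance are estimated from the bottom 99%
of the data; the mean is adjusted per position by the ratio of 20-kb
rolling means of signal and sequencing input, so that local coverage
biases do not masquerade as enrichment. The same module computes
promoter-window fold-change summaries used to detect developmental
de-repression (falling repressive histone signal with rising RNA) and
the hypergeometric overlap test for target-set enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import SignalTrack, TssTable

PVAL_CAP = 16.0
BACKGROUND_QUANTILE = 0.99
LOCAL_WINDOW = 20_000


@dataclass
class NBParams:
    """Method-of-moments negative binomial background.

    ``mean`` and ``variance`` are estimated from values at or below the
    ``fit_quantile`` empirical quantile. When variance <= mean the
    negative binomial degenerates and a Poisson background is used
    instead (``poisson_fallback``).
    """

    mean: float
    variance: float
    poisson_fallback: bool
    fit_quantile: float = BACKGROUND_QUANTILE

    def __post_init__(self) -> None:
        if self.mean <= 0:
            raise ValueError("background mean must be positive")
        if self.variance <= 0:
            raise ValueError("background variance must be positive")
        assert self.poisson_fallback == (self.variance <= self.mean)


def fit_nb_background(track: SignalTrack, fit_quantile: float = BACKGROUND_QUANTILE) -> NBParams:
    """Estimate the background mean/variance from the bottom of the
    signal distribution (values <= the ``fit_quantile`` quantile), so
    enriched regions do not inflate the background."""
    values = track.concatenated()
    if len(values) < 2:
        raise ValueError("track too short to fit a background")
    if not values.any():
        raise ValueError("all-zero track: no background to fit")
    q = np.quantile(values, fit_quantile)
    sub = values[values <= q]
    m = float(sub.mean())
    v = float(sub.var(ddof=1))
    if m <= 0:
        raise ValueError("background mean is zero after quantile trimming")
    if v <= 0:
        raise ValueError("degenerate (constant) background: variance is zero")
    return NBParams(mean=m, variance=v, poisson_fallback=v <= m, fit_quantile=fit_quantile)


def local_mean_adjust(
    signal: SignalTrack,
    input_track: SignalTrack,
    params: NBParams,
    window: int = LOCAL_WINDOW,
) -> dict[str, np.ndarray]:
    """Per-bin adjusted background means from local signal/input ratios.

    Rolling means of signal and input are taken in a ``window``-bp
    window centred on each bin (truncated at chromosome ends); their
    ratio (1 where the input rolling mean is zero) is rescaled to
    genome-wide mean 1 and multiplied onto the fitted background mean.
    The genome-average adjusted mean therefore equals the fitted mean.
    """
    if signal.bin_width != input_track.bin_width:
        raise ValueError("signal and input bin widths differ")
    if set(signal.values) != set(input_track.values):
        raise ValueError("signal and input cover different chromosomes")
    for c in signal.values:
        if len(signal.values[c]) != len(input_track.values[c]):
            raise ValueError(f"signal and input bin counts differ on {c}")
    w_bins = max(1, window // signal.bin_width)
    ratios: dict[str, np.ndarray] = {}
    for c in sorted(signal.values):
        rs = (
            pd.Series(signal.values[c])
            .rolling(w_bins, center=True, min_periods=1)
            .mean()
            .values
        )
        ri = (
            pd.Series(input_track.values[c])
            .rolling(w_bins, center=True, min_periods=1)
            .mean()
            .values
        )
        r = np.ones_like(rs)
        nz = ri > 0
        r[nz] = rs[nz] / ri[nz]
        ratios[c] = r
    grand = np.concatenate([ratios[c] for c in sorted(ratios)]).mean()
    if grand == 0:
        raise ValueError("all local ratios are zero; cannot normalize")
    return {c: params.mean * (r / grand) for c, r in ratios.items()}


def _neglog10_sf(x: np.ndarray, mean: np.ndarray, params: NBParams, cap: float) -> np.ndarray:
    """-log10 of the inclusive upper tail P(X >= x) at per-bin means,
    with the variance-to-mean ratio of the fitted background."""
    x = np.asarray(x, dtype=float)
    mean = np.broadcast_to(np.asarray(mean, dtype=float), x.shape)
    if not np.all(x == np.floor(x)):
        warnings.warn("non-integer signal values floored before tail test", stacklevel=3)
        x = np.floor(x)
    out = np.zeros_like(x)
    pos = x >= 1
    if params.poisson_fallback:
        logsf = stats.poisson.logsf(x[pos] - 1, mean[pos])
    else:
        phi = params.variance / params.mean  # > 1, preserved per bin
        r = mean[pos] / (phi - 1.0)
        p = 1.0 / phi
        logsf = stats.nbinom.logsf(x[pos] - 1, r, p)
    out[pos] = -logsf / np.log(10.0)
    return np.clip(out, 0.0, cap)


def signal_to_neglog10p(
    track: SignalTrack,
    params: NBParams,
    adjusted_means: dict[str, np.ndarray] | None = None,
    cap: float = PVAL_CAP,
) -> SignalTrack:
    """Convert a raw signal track to capped -log10 P values under the
    (locally adjusted) negative binomial or Poisson background.

    The per-bin variance scales with the adjusted mean so the
    variance/mean ratio of the fitted background is preserved.
    """
    values: dict[str, np.ndarray] = {}
    for c in sorted(track.values):
        x = track.values[c]
        m = adjusted_means[c] if adjusted_means is not None else np.full(len(x), params.mean)
        if len(m) != len(x):
            raise ValueError(f"adjusted means and track disagree on {c}")
        values[c] = _neglog10_sf(x, m, params, cap)
    return SignalTrack(
        values=values,
        bin_width=track.bin_width,
        sample_id=track.sample_id,
        mark=track.mark,
        role="pvalue",
    )


def log2_ratio_track(
    signal: SignalTrack, input_track: SignalTrack, pseudocount: float = 1.0
) -> SignalTrack:
    """Per-bin log2((signal + pc) / (input + pc)) fold-change track."""
    if signal.bin_width != input_track.bin_width:
        raise ValueError("signal and input bin widths differ")
    values = {}
    for c in signal.values:
        s, i = signal.values[c], input_track.values[c]
        if len(s) != len(i):
            raise ValueError(f"bin counts differ on {c}")
        values[c] = np.log2((s + pseudocount) / (i + pseudocount))
    return SignalTrack(
        values=values,
        bin_width=signal.bin_width,
        sample_id=signal.sample_id,
        mark=signal.mark,
        role="log2fc",
    )


def promoter_window_signal(
    fc_track: SignalTrack, tss_table: TssTable, window: int = 4000
) -> pd.Series:
    """Mean fold change in a ``window``-bp window enclosing each TSS at
    its centre (strand-independent); windows are truncated at
    chromosome ends with a warning."""
    bw = fc_track.bin_width
    half = window // 2
    out = {}
    truncated = 0
    for row in tss_table.table.itertuples(index=False):
        if row.chrom not in fc_track.values:
            raise ValueError(f"TSS chromosome {row.chrom!r} absent from track")
        v = fc_track.values[row.chrom]
        lo = (row.tss - half) // bw
        hi = -(-(row.tss + half) // bw)  # ceil
        if lo < 0 or hi > len(v):
            truncated += 1
        lo = max(lo, 0)
        hi = min(hi, len(v))
        if hi <= lo:
            out[row.gene_id] = np.nan
            continue
        out[row.gene_id] = float(v[lo:hi].mean())
    if truncated:
        warnings.warn(
            f"{truncated} promoter window(s) truncated at chromosome ends",
            stacklevel=2,
        )
    return pd.Series(out, name="promoter_fc")


def promoter_score_table(
    fc_tracks: dict[str, SignalTrack], tss_table: TssTable, window: int = 4000
) -> pd.DataFrame:
    """Per-gene promoter fold change at each time point plus the fold
    decrease between the earliest and latest time point.

    ``fc_tracks`` maps time point label -> log2 fold-change track; time
    points are taken in the given (insertion) order, earliest first.
    """
    cols = {tp: promoter_window_signal(tr, tss_table, window) for tp, tr in fc_tracks.items()}
    table = pd.DataFrame(cols)
    tps = list(fc_tracks)
    table["fold_decrease"] = table[tps[0]] - table[tps[-1]]
    return table


def cluster_derepression_score(
    score_table: pd.DataFrame,
    clusters: dict[int | str, list[str]],
    expression: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Rank gene clusters by mean promoter fold decrease.

    ``score_table`` must carry a ``fold_decrease`` column (see
    ``promoter_score_table``). When an expression matrix (genes x
    ordered stages) is given, each cluster also gets the mean per-gene
    linear-trend slope of expression, so de-repression candidates
    (falling repressive signal, rising RNA) can be read off directly.
    Result is sorted by fold decrease, largest first.
    """
    if "fold_decrease" not in score_table.columns:
        raise ValueError("score_table lacks a fold_decrease column")
    rows = []
    for cid, genes in clusters.items():
        missing = [g for g in genes if g not in score_table.index]
        if missing:
            raise ValueError(f"cluster {cid}: genes absent from score table: {missing[:5]}")
        fd = score_table.loc[genes, "fold_decrease"].mean()
        row = {"cluster": cid, "mean_fold_decrease": fd, "n_genes": len(genes)}
        if expression is not None:
            t = np.arange(expression.shape[1], dtype=float)
            sub = expression.loc[genes].values
            # least-squares slope per gene against stage index
            tc = t - t.mean()
            slopes = (sub - sub.mean(axis=1, keepdims=True)) @ tc / (tc @ tc)
            row["mean_expression_slope"] = float(slopes.mean())
        rows.append(row)
    return (
        pd.DataFrame(rows)
        .sort_values(["mean_fold_decrease", "cluster"], ascending=[False, True])
        .reset_index(drop=True)
    )


def hypergeom_overlap(set_a: set, set_b: set, universe: set) -> float:
    """Upper-tail hypergeometric P value for the overlap of two gene
    sets drawn from a common universe."""
    set_a, set_b, universe = set(set_a), set(set_b), set(universe)
    if not set_a <= universe or not set_b <= universe:
        raise ValueError("sets must be subsets of the universe")
    k = len(set_a & set_b)
    return float(stats.hypergeom.sf(k - 1, len(universe), len(set_a), len(set_b)))
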