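"""Cell-type candidate cis-regulatory element (cCRE) assignment.

Open-chromatin (DHS) peaks from all samples are merged; merged peaks
are kept only where they overlap chromatin-segmentation states of the
active, poised or bivalent classes; surviving elements are assigned to
the closest transcription start site of an expressed gene, stratified
by TSS distance into proximal / middle / distal, and finally attributed
to cell types through the exclusive single-cell marker map of the
assigned gene.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import pandas as pd

from .bulk_structure import ExpressionMatrix
from .io_formats import GenomicInterval, TssTable
from .sc_features import CellMatrix

# Chromatin-state classes of the 32-state whole-tissue segmentation.
ACTIVE_STATES = frozenset({14, 19, 20, 21, 23, 24, 25, 27, 28, 30, 31, 32})
POISED_STATES = frozenset({8, 13})
BIVALENT_STATES = frozenset({26, 29})

# the segmentation model has states 0..32; everything not on the
# active/poised/bivalent whitelists is "other"
DEFAULT_STATE_CLASSES: dict[int, str] = {
    s: (
        "active"
        if s in ACTIVE_STATES
        else "poised"
        if s in POISED_STATES
        else "bivalent"
        if s in BIVALENT_STATES
        else "other"
    )
    for s in range(33)
}

WHITELIST_CLASSES = ("active", "poised", "bivalent")
# deterministic single label when a peak overlaps several classes
CLASS_PRECEDENCE = ("active", "bivalent", "poised")

PROXIMAL_MAX = 200
MIDDLE_MAX = 2000


@dataclass
class StateSegmentation:
    """Chromatin-state intervals (integer state labels) for one sample."""

    intervals: list[GenomicInterval]
    state_classes: dict[int, str] = field(default_factory=lambda: dict(DEFAULT_STATE_CLASSES))
    sample_id: str = ""

    def __post_init__(self) -> None:
        by_chrom: dict[str, list[GenomicInterval]] = {}
        for iv in self.intervals:
            if iv.state is None:
                raise ValueError(f"segmentation interval without state label: {iv}")
            by_chrom.setdefault(iv.chrom, []).append(iv)
        for chrom, ivs in by_chrom.items():
            ivs = sorted(ivs, key=lambda x: x.start)
            for a, b in zip(ivs, ivs[1:]):
                if b.start < a.end:
                    raise ValueError(f"overlapping segmentation intervals on {chrom}")

    def class_of(self, state: int) -> str:
        try:
            return self.state_classes[state]
        except KeyError:
            raise ValueError(f"state {state} has no class assignment") from None


@dataclass
class CandidateElement:
    interval: GenomicInterval
    gene: str
    distance: int
    category: str  # proximal | middle | distal
    state_class: str  # active | poised | bivalent
    cell_types: frozenset = frozenset()

    def as_row(self) -> dict:
        return {
            "chrom": self.interval.chrom,
            "start": self.interval.start,
            "end": self.interval.end,
            "gene": self.gene,
            "distance": self.distance,
            "category": self.category,
            "state_class": self.state_class,
            "cell_types": ",".join(sorted(self.cell_types)),
        }


# ---------------------------------------------------------------------------


def merge_peaks(
    *peak_sets: list[GenomicInterval], known_chroms: set[str] | None = None
) -> list[GenomicInterval]:
    """Union of peak calls across samples: overlapping or bookended
    intervals coalesce; output sorted by (chrom, start)."""
    peaks = [iv for ps in peak_sets for iv in ps]
    if known_chroms is not None:
        bad = {iv.chrom for iv in peaks} - set(known_chroms)
        if bad:
            raise ValueError(f"peaks on unknown chromosomes: {sorted(bad)}")
    merged: list[GenomicInterval] = []
    for chrom in sorted({iv.chrom for iv in peaks}):
        ivs = sorted(
            (iv for iv in peaks if iv.chrom == chrom), key=lambda x: (x.start, x.end)
        )
        cur_start, cur_end = ivs[0].start, ivs[0].end
        for iv in ivs[1:]:
            if iv.start <= cur_end:  # overlap or bookended
                cur_end = max(cur_end, iv.end)
            else:
                merged.append(GenomicInterval(chrom, cur_start, cur_end))
                cur_start, cur_end = iv.start, iv.end
        merged.append(GenomicInterval(chrom, cur_start, cur_end))
    return merged


def classify_states(
    segmentation: StateSegmentation,
) -> list[tuple[GenomicInterval, str]]:
    """Class (active/poised/bivalent/other) per segmentation interval."""
    return [(iv, segmentation.class_of(iv.state)) for iv in segmentation.intervals]


def filter_peaks_by_state(
    peaks: list[GenomicInterval],
    segmentations: list[StateSegmentation],
) -> list[tuple[GenomicInterval, str]]:
    """Keep peaks with >= 1 bp overlap with a whitelisted-class state
    interval in at least one sample; each kept peak gets a single class
    label by the precedence active > bivalent > poised.

    Segmentations from multiple samples (e.g. developmental time
    points) are pooled: whitelisting in any one sample qualifies.
    """
    whitelisted: dict[str, list[tuple[int, int, str]]] = {}
    for seg in segmentations:
        for iv, cls in classify_states(seg):
            if cls in WHITELIST_CLASSES:
                whitelisted.setdefault(iv.chrom, []).append((iv.start, iv.end, cls))
    rank = {c: i for i, c in enumerate(CLASS_PRECEDENCE)}
    out: list[tuple[GenomicInterval, str]] = []
    for peak in peaks:
        hits = [
            cls
            for (s, e, cls) in whitelisted.get(peak.chrom, [])
            if s < peak.end and peak.start < e
        ]
        if hits:
            out.append((peak, min(hits, key=rank.__getitem__)))
    return out


def expressed_gene_filter(
    bulk: ExpressionMatrix | None,
    sc: CellMatrix | None,
    fpkm_threshold: float = 0.1,
    min_cells_detected: int = 4,
) -> set[str]:
    """Genes regarded as expressed: bulk maximum FPKM above
    ``fpkm_threshold`` in at least one sample (strict), or detected in
    more than ``min_cells_detected`` cells of the single-cell data
    (strict)."""
    if bulk is None and sc is None:
        raise ValueError("need at least one of bulk or single-cell data")
    expressed: set[str] = set()
    if bulk is not None:
        m = bulk.values.max(axis=1)
        expressed |= set(m.index[m > fpkm_threshold].astype(str))
    if sc is not None:
        det = (sc.values > 0).sum(axis=0)
        expressed |= set(det.index[det > min_cells_detected].astype(str))
    return expressed


def _interval_tss_distance(iv: GenomicInterval, tss: int) -> int:
    """Distance from a TSS to the nearest edge of a half-open interval
    (0 when the TSS lies inside): the size of the gap between the TSS
    and the interval boundary coordinate."""
    if tss < iv.start:
        return iv.start - tss
    if tss >= iv.end:
        return tss - iv.end
    return 0


def assign_nearest_tss(
    peaks: list[GenomicInterval],
    tss: TssTable,
) -> list[tuple[GenomicInterval, str, int]]:
    """Assign each peak to the closest expressed-gene TSS on its
    chromosome (edge distance; ties broken by gene id).

    Peaks on chromosomes without any expressed TSS are left unassigned
    with a warning.
    """
    table = tss.expressed_only().table
    by_chrom: dict[str, list[tuple[int, str]]] = {}
    for row in table.itertuples(index=False):
        by_chrom.setdefault(row.chrom, []).append((row.tss, str(row.gene_id)))
    out: list[tuple[GenomicInterval, str, int]] = []
    unassigned = 0
    for peak in peaks:
        cands = by_chrom.get(peak.chrom)
        if not cands:
            unassigned += 1
            continue
        best = min(
            ((_interval_tss_distance(peak, t), g) for t, g in cands),
            key=lambda dg: (dg[0], dg[1]),
        )
        out.append((peak, best[1], best[0]))
    if unassigned:
        warnings.warn(
            f"{unassigned} peak(s) on chromosomes without expressed TSS left unassigned",
            stacklevel=2,
        )
    return out


def categorize_distance(distance: int) -> str:
    """Distance stratum of an element relative to its assigned TSS:
    proximal (<= 200 bp), middle (201-2,000 bp), distal (> 2,000 bp)."""
    if distance < 0:
        raise ValueError("distance must be non-negative")
    if distance <= PROXIMAL_MAX:
        return "proximal"
    if distance <= MIDDLE_MAX:
        return "middle"
    return "distal"


def derive_celltype_elements(
    classified_peaks: list[tuple[GenomicInterval, str]],
    tss: TssTable,
    exclusive_markers: dict[str, str] | None = None,
    group_members: dict[str, frozenset] | None = None,
) -> tuple[list[CandidateElement], list[CandidateElement]]:
    """Build the full cCRE table and the cell-type-restricted table.

    Each whitelisted peak is assigned to its nearest expressed TSS and
    distance-categorized. When an exclusive-marker map is given,
    elements whose assigned gene is an exclusive marker inherit that
    cell type (or the member types of a lineage group, via
    ``group_members``); elements assigned to non-marker genes appear
    only in the full table.

    Returns (all_elements, celltype_elements), both sorted by
    coordinate.
    """
    peaks = [p for p, _ in classified_peaks]
    classes = {id(p): cls for p, cls in classified_peaks}
    assignments = assign_nearest_tss(peaks, tss)
    group_members = group_members or {}
    all_elements: list[CandidateElement] = []
    celltype_elements: list[CandidateElement] = []
    for peak, gene, dist in assignments:
        elem = CandidateElement(
            interval=peak,
            gene=gene,
            distance=dist,
            category=categorize_distance(dist),
            state_class=classes[id(peak)],
        )
        all_elements.append(elem)
        if exclusive_markers and gene in exclusive_markers:
            owner = exclusive_markers[gene]
            types = group_members.get(owner, frozenset({owner}))
            celltype_elements.append(
                CandidateElement(
                    interval=peak,
                    gene=gene,
                    distance=dist,
                    category=elem.category,
                    state_class=elem.state_class,
                    cell_types=frozenset(types),
                )
            )
    key = lambda e: (e.interval.chrom, e.interval.start, e.interval.end)
    return sorted(all_elements, key=key), sorted(celltype_elements, key=key)


def coverage_stats(
    celltype_elements: list[CandidateElement],
    marker_genes: set[str],
) -> dict:
    """How many exclusive marker genes have at least one affiliated
    element, and how many elements there are in total."""
    covered = {e.gene for e in celltype_elements} & set(marker_genes)
    n = len(marker_genes)
    return {
        "n_marker_genes": n,
        "n_with_element": len(covered),
        "fraction": len(covered) / n if n else 0.0,
        "n_elements": len(celltype_elements),
    }


def elements_to_frame(elements: list[CandidateElement]) -> pd.DataFrame:
    cols = ["chrom", "start", "end", "gene", "distance", "category", "state_class", "cell_types"]
    return pd.DataFrame([e.as_row() for e in elements], columns=cols)


def run_cre_pipeline(
    peak_sets: list[list[GenomicInterval]],
    segmentations: list[StateSegmentation],
    tss: TssTable,
    bulk: ExpressionMatrix | None = None,
    sc: CellMatrix | None = None,
    exclusive_markers: dict[str, str] | None = None,
    group_members: dict[str, frozenset] | None = None,
) -> dict:
    """The full element pipeline: merge peaks, whitelist by chromatin
    state, assign to expressed TSSs, categorize, attribute cell types.

    When bulk/single-cell matrices are given, the expression flags in
    the TSS table are recomputed from them; otherwise the flags in the
    table are trusted.
    """
    merged = merge_peaks(*peak_sets)
    classified = filter_peaks_by_state(merged, segmentations)
    if bulk is not None or sc is not None:
        expressed = expressed_gene_filter(bulk, sc)
        t = tss.table.copy()
        t["expressed"] = t["gene_id"].astype(str).isin(expressed)
        tss = TssTable(t)
    all_elements, celltype_elements = derive_celltype_elements(
        classified, tss, exclusive_markers, group_members
    )
    out = {
        "merged_peaks": merged,
        "elements": all_elements,
        "celltype_elements": celltype_elements,
    }
    if exclusive_markers:
        out["coverage"] = coverage_stats(celltype_elements, set(exclusive_markers))
    return out
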