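"""Peak merging, state whitelisting, TSS assignment, distance strata."""

import numpy as np
import pandas as pd
import pytest

from devdecomp import cre_assign as ca
from devdecomp.bulk_structure import ExpressionMatrix
from devdecomp.io_formats import GenomicInterval, TssTable
from devdecomp.sc_features import CellMatrix


def iv(chrom, start, end, **kw):
    return GenomicInterval(chrom, start, end, **kw)


def tss_table(rows):
    return TssTable(pd.DataFrame(rows))


class TestMergePeaks:
    def test_overlapping_coalesce(self):
        out = ca.merge_peaks([iv("chr1", 100, 200), iv("chr1", 150, 300)])
        assert [(p.start, p.end) for p in out] == [(100, 300)]

    def test_bookended_coalesce(self):
        out = ca.merge_peaks([iv("chr1", 100, 200)], [iv("chr1", 200, 300)])
        assert [(p.start, p.end) for p in out] == [(100, 300)]

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            ca.merge_peaks([iv("chrZ", 0, 10)], known_chroms={"chr1"})

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_quadratic_union_oracle(self, seed):
        rng = np.random.default_rng(seed)
        peaks = [
            iv(f"chr{rng.integers(1, 3)}", int(s), int(s + rng.integers(1, 200)))
            for s in rng.integers(0, 5000, 500)
        ]
        merged = ca.merge_peaks(peaks)
        # oracle: per-bp membership (union with bookended coalescing)
        for chrom in {"chr1", "chr2"}:
            covered = np.zeros(6000, dtype=bool)
            for p in peaks:
                if p.chrom == chrom:
                    covered[p.start : p.end] = True
            runs = []
            in_run = False
            for pos in range(len(covered)):
                if covered[pos] and not in_run:
                    start, in_run = pos, True
                if not covered[pos] and in_run:
                    runs.append((start, pos))
                    in_run = False
            if in_run:
                runs.append((start, len(covered)))
            got = [(p.start, p.end) for p in merged if p.chrom == chrom]
            assert got == runs


class TestClassifyStates:
    @pytest.mark.parametrize(
        "state,expected",
        [(14, "active"), (19, "active"), (32, "active"), (8, "poised"),
         (13, "poised"), (26, "bivalent"), (29, "bivalent"), (1, "other"),
         (0, "other"), (22, "other")],
    )
    def test_default_class_map(self, state, expected):
        seg = ca.StateSegmentation(intervals=[iv("chr1", 0, 100, state=state)])
        assert seg.class_of(state) == expected

    def test_unknown_state_id_rejected(self):
        seg = ca.StateSegmentation(intervals=[iv("chr1", 0, 100, state=1)])
        with pytest.raises(ValueError, match="no class"):
            seg.class_of(99)

    def test_overlapping_intervals_rejected(self):
        with pytest.raises(ValueError, match="overlapping"):
            ca.StateSegmentation(
                intervals=[iv("chr1", 0, 100, state=1), iv("chr1", 50, 150, state=2)]
            )


class TestFilterPeaksByState:
    def _seg(self, *ivs):
        return ca.StateSegmentation(intervals=list(ivs))

    def test_active_peak_kept(self):
        out = ca.filter_peaks_by_state(
            [iv("chr1", 10, 50)], [self._seg(iv("chr1", 0, 100, state=14))]
        )
        assert out == [(out[0][0], "active")]

    def test_other_state_peak_dropped(self):
        out = ca.filter_peaks_by_state(
            [iv("chr1", 10, 50)], [self._seg(iv("chr1", 0, 100, state=1))]
        )
        assert out == []

    def test_precedence_active_over_poised(self):
        out = ca.filter_peaks_by_state(
            [iv("chr1", 10, 90)],
            [self._seg(iv("chr1", 0, 50, state=8), iv("chr1", 50, 100, state=14))],
        )
        assert out[0][1] == "active"

    def test_any_sample_qualifies(self):
        peak = iv("chr1", 10, 50)
        seg_bad = self._seg(iv("chr1", 0, 100, state=1))
        seg_good = self._seg(iv("chr1", 0, 100, state=26))
        assert ca.filter_peaks_by_state([peak], [seg_bad, seg_good])[0][1] == "bivalent"

    def test_matches_intersection_oracle(self):
        rng = np.random.default_rng(3)
        peaks = [iv("chr1", int(s), int(s) + 50) for s in rng.integers(0, 10_000, 200)]
        states = []
        pos = 0
        while pos < 11_000:
            w = int(rng.integers(100, 400))
            states.append(iv("chr1", pos, pos + w, state=int(rng.integers(0, 33))))
            pos += w
        seg = self._seg(*states)
        got = {(p.start, p.end): cls for p, cls in ca.filter_peaks_by_state(peaks, [seg])}
        rank = {"active": 0, "bivalent": 1, "poised": 2}
        for p in peaks:
            classes = {
                seg.class_of(s.state)
                for s in states
                if s.start < p.end and p.start < s.end
            } - {"other"}
            if classes:
                assert got[(p.start, p.end)] == min(classes, key=rank.__getitem__)
            else:
                assert (p.start, p.end) not in got


class TestExpressedGeneFilter:
    def _bulk(self, values):
        v = pd.DataFrame(values).T
        v.index = [f"g{i}" for i in range(len(v))]
        v.columns = [f"s{j}" for j in range(v.shape[1])]
        meta = pd.DataFrame({"tissue": "T", "stage": list(v.columns)}, index=v.columns)
        return ExpressionMatrix(values=v, sample_meta=meta)

    def _sc(self, detected_cells, n_cells=10):
        v = pd.DataFrame(0.0, index=[f"c{i}" for i in range(n_cells)], columns=["g0"])
        v.iloc[:detected_cells, 0] = 1.0
        return CellMatrix(values=v, platform="tag")

    def test_sc_detection_strictly_more_than_four(self):
        bulk = self._bulk({"g0": [0.05, 0.05]})
        assert ca.expressed_gene_filter(bulk, self._sc(5)) == {"g0"}
        assert ca.expressed_gene_filter(bulk, self._sc(4)) == set()

    def test_bulk_threshold_strict(self):
        assert ca.expressed_gene_filter(self._bulk({"g0": [0.1, 0.1]}), None) == set()
        assert ca.expressed_gene_filter(self._bulk({"g0": [0.11, 0.0]}), None) == {"g0"}

    def test_requires_some_input(self):
        with pytest.raises(ValueError):
            ca.expressed_gene_filter(None, None)

    def test_matches_bruteforce(self):
        rng = np.random.default_rng(4)
        vals = {f"g{i}": rng.uniform(0, 0.3, 3) for i in range(30)}
        bulk = self._bulk(vals)
        got = ca.expressed_gene_filter(bulk, None)
        expected = {g for g, v in vals.items() if max(v) > 0.1}
        assert got == expected


class TestAssignNearestTss:
    def _tss(self, entries):
        return tss_table(
            [
                {"gene_id": g, "chrom": c, "tss": t, "strand": "+", "expressed": e}
                for g, c, t, e in entries
            ]
        )

    def test_edge_distance(self):
        t = self._tss([("gA", "chr1", 10_000, True)])
        ((peak, gene, dist),) = ca.assign_nearest_tss([iv("chr1", 9_900, 9_950)], t)
        assert gene == "gA" and dist == 50

    def test_tss_inside_peak_distance_zero(self):
        t = self._tss([("gA", "chr1", 10_000, True)])
        ((_, _, dist),) = ca.assign_nearest_tss([iv("chr1", 9_900, 10_100)], t)
        assert dist == 0

    def test_only_expressed_genes_eligible(self):
        t = self._tss([("gNear", "chr1", 10_000, False), ("gFar", "chr1", 20_000, True)])
        ((_, gene, _),) = ca.assign_nearest_tss([iv("chr1", 9_900, 9_950)], t)
        assert gene == "gFar"

    def test_ties_lexicographic(self):
        t = self._tss([("gB", "chr1", 900, True), ("gA", "chr1", 1100, True)])
        ((_, gene, dist),) = ca.assign_nearest_tss([iv("chr1", 990, 1010)], t)
        assert gene == "gA" and dist == 90

    def test_chromosome_without_tss_warns(self):
        t = self._tss([("gA", "chr1", 100, True)])
        with pytest.warns(UserWarning, match="unassigned"):
            out = ca.assign_nearest_tss([iv("chr2", 0, 10)], t)
        assert out == []

    def test_matches_pairwise_scan_oracle(self):
        rng = np.random.default_rng(5)
        entries = [
            (f"g{i:03d}", "chr1", int(p), True)
            for i, p in enumerate(rng.integers(0, 100_000, 200))
        ]
        t = self._tss(entries)
        peaks = [iv("chr1", int(s), int(s) + int(rng.integers(1, 500)))
                 for s in rng.integers(0, 100_000, 300)]
        got = ca.assign_nearest_tss(peaks, t)
        for peak, gene, dist in got:
            best = min(
                (
                    (
                        peak.start - p if p < peak.start else p - peak.end if p >= peak.end else 0,
                        g,
                    )
                    for g, _, p, _ in entries
                ),
            )
            assert (gene, dist) == (best[1], best[0])


class TestCategorizeDistance:
    @pytest.mark.parametrize(
        "d,expected",
        [(0, "proximal"), (200, "proximal"), (201, "middle"),
         (2000, "middle"), (2001, "distal"), (50_000, "distal")],
    )
    def test_boundaries(self, d, expected):
        assert ca.categorize_distance(d) == expected

    def test_exhaustive_piecewise_rule(self):
        for d in range(0, 3001):
            expected = "proximal" if d <= 200 else "middle" if d <= 2000 else "distal"
            assert ca.categorize_distance(d) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ca.categorize_distance(-1)


class TestDeriveCelltypeElements:
    def _inputs(self):
        t = tss_table(
            [
                {"gene_id": "gMuscle", "chrom": "chr1", "tss": 1000, "strand": "+",
                 "expressed": True},
                {"gene_id": "gOther", "chrom": "chr1", "tss": 50_000, "strand": "+",
                 "expressed": True},
            ]
        )
        classified = [
            (iv("chr1", 1100, 1300), "active"),  # near gMuscle
            (iv("chr1", 49_000, 49_200), "poised"),  # near gOther
        ]
        return classified, t

    def test_marker_gene_element_inherits_cell_type(self):
        classified, t = self._inputs()
        _, ct = ca.derive_celltype_elements(classified, t, {"gMuscle": "Muscle"})
        assert len(ct) == 1 and ct[0].cell_types == frozenset({"Muscle"})

    def test_non_marker_gene_only_in_full_table(self):
        classified, t = self._inputs()
        full, ct = ca.derive_celltype_elements(classified, t, {"gMuscle": "Muscle"})
        assert len(full) == 2
        assert {e.gene for e in ct} == {"gMuscle"}

    def test_lineage_group_expansion(self):
        classified, t = self._inputs()
        _, ct = ca.derive_celltype_elements(
            classified, t, {"gMuscle": "M1+M2"},
            group_members={"M1+M2": frozenset({"M1", "M2"})},
        )
        assert ct[0].cell_types == frozenset({"M1", "M2"})


class TestCoverageStats:
    def test_half_covered(self):
        elems = [
            ca.CandidateElement(iv("chr1", 0, 10), "gA", 5, "proximal", "active",
                                frozenset({"T"})),
            ca.CandidateElement(iv("chr1", 20, 30), "gB", 5, "proximal", "active",
                                frozenset({"T"})),
        ]
        out = ca.coverage_stats(elems, {"gA", "gB", "gC", "gD"})
        assert out["fraction"] == 0.5 and out["n_elements"] == 2

    def test_no_elements(self):
        out = ca.coverage_stats([], {"gA"})
        assert out["fraction"] == 0.0


class TestEndToEnd:
    def test_planted_elements_recovered_exactly(self, epigenome):
        truth = epigenome["truth"]
        res = ca.run_cre_pipeline(
            list(epigenome["peak_sets"].values()),
            epigenome["segmentations"],
            epigenome["tss_table"],
            bulk=epigenome["bulk_expression"],
            exclusive_markers=truth.planted_markers,
        )
        got = {
            (e.interval.chrom, e.interval.start, e.interval.end, e.gene,
             e.category, e.state_class)
            for e in res["celltype_elements"]
        }
        want = {
            (p["chrom"], p["start"], p["end"], p["gene"], p["category"], p["state_class"])
            for p in truth.planted_elements
        }
        assert got == want  # recall 1.0 and precision 1.0

    def test_decoys_absent(self, epigenome):
        truth = epigenome["truth"]
        res = ca.run_cre_pipeline(
            list(epigenome["peak_sets"].values()),
            epigenome["segmentations"],
            epigenome["tss_table"],
            bulk=epigenome["bulk_expression"],
        )
        decoy_keys = {(d.chrom, d.start, d.end) for d in truth.decoy_peaks}
        got_keys = {(e.interval.chrom, e.interval.start, e.interval.end)
                    for e in res["elements"]}
        assert not decoy_keys & got_keys

    def test_output_invariants(self, epigenome):
        truth = epigenome["truth"]
        res = ca.run_cre_pipeline(
            list(epigenome["peak_sets"].values()),
            epigenome["segmentations"],
            epigenome["tss_table"],
            bulk=epigenome["bulk_expression"],
            exclusive_markers=truth.planted_markers,
        )
        whitelisted = [
            s
            for seg in epigenome["segmentations"]
            for s in seg.intervals
            if seg.state_classes[s.state] != "other"
        ]
        expressed = ca.expressed_gene_filter(epigenome["bulk_expression"], None)
        for e in res["elements"]:
            assert any(
                s.chrom == e.interval.chrom and s.start < e.interval.end
                and e.interval.start < s.end
                for s in whitelisted
            )
            assert e.gene in expressed
            assert e.category == ca.categorize_distance(e.distance)

    def test_input_order_invariance(self, epigenome):
        truth = epigenome["truth"]
        kw = dict(
            segmentations=epigenome["segmentations"],
            tss=epigenome["tss_table"],
            bulk=epigenome["bulk_expression"],
            exclusive_markers=truth.planted_markers,
        )
        a = ca.run_cre_pipeline(list(epigenome["peak_sets"].values()), **kw)
        b = ca.run_cre_pipeline(list(epigenome["peak_sets"].values())[::-1], **kw)
        assert ca.elements_to_frame(a["elements"]).equals(ca.elements_to_frame(b["elements"]))
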