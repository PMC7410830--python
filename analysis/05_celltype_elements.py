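#!/usr/bin/env python
"""Cell-type candidate regulatory elements from DHS peaks, chromatin
states and exclusive markers.

Merges DHS peak calls across samples, keeps peaks overlapping
active/poised/bivalent chromatin states in any sample, assigns each
surviving element to the closest expressed TSS, stratifies by distance
(proximal <= 200 bp, middle 201-2,000, distal > 2,000) and attributes
elements to cell types through the exclusive marker map derived from
the single-cell data. Scores the result against the planted truth.
"""

import argparse
import json
from pathlib import Path

from devdecomp import cre_assign as ca
from devdecomp import sc_features as sf
from devdecomp.synthetic_data import SynthConfig, generate_epigenome, generate_sc_counts

SC_QC = dict(min_genes=100, max_genes=380, max_mito=0.20, min_cell_frac=0.005)


def run(seed: int, out: Path) -> None:
    out.mkdir(parents=True, exist_ok=True)
    cfg = SynthConfig(seed=seed)
    # derive the exclusive marker map from the single-cell data, as the
    # element attribution step requires
    mat, sc_truth = generate_sc_counts(cfg)
    norm = sf.normalize_tag(sf.qc_filter_tag(mat, **SC_QC))
    labels = sc_truth.cell_labels.loc[norm.cells]
    table = sf.find_markers(norm, labels, min_diff_pct=0.4)
    exclusive = sf.derive_exclusive_markers(
        {str(c): table.markers_of(str(c)) for c in sorted(labels.unique())}
    )
    print(f"{len(exclusive)} exclusive markers from single-cell data")

    epi = generate_epigenome(cfg)
    res = ca.run_cre_pipeline(
        list(epi["peak_sets"].values()), epi["segmentations"], epi["tss_table"],
        bulk=epi["bulk_expression"], sc=mat, exclusive_markers=exclusive,
    )
    ca.elements_to_frame(res["elements"]).to_csv(
        out / "elements.tsv", sep="\t", index=False)
    ca.elements_to_frame(res["celltype_elements"]).to_csv(
        out / "celltype_elements.tsv", sep="\t", index=False)
    cov = res["coverage"]
    print(f"{len(res['elements'])} whitelisted elements; "
          f"{cov['n_elements']} attributed to cell types; "
          f"{cov['n_with_element']}/{cov['n_marker_genes']} marker genes "
          f"({cov['fraction']:.1%}) have at least one affiliated element")
    truth = epi["truth"]
    got = {(e.interval.chrom, e.interval.start, e.interval.end, e.gene,
            e.category, e.state_class) for e in res["celltype_elements"]}
    want = {(p["chrom"], p["start"], p["end"], p["gene"], p["category"],
             p["state_class"]) for p in truth.planted_elements}
    recall = len(got & want) / len(want)
    precision = len(got & want) / max(len(got), 1)
    print(f"against planted truth: recall {recall:.2f}, precision {precision:.2f}")
    (out / "coverage.json").write_text(json.dumps(
        {**cov, "recall": recall, "precision": precision}, indent=2))


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/cre"))
    args = ap.parse_args()
    run(args.seed, args.out)
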