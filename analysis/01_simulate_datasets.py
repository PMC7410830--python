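#!/usr/bin/env python
"""Generate the synthetic study datasets and write them to disk.

Produces the bulk tissue-by-stage FPKM matrix (with read counts,
biotypes and sample metadata), the droplet single-cell UMI matrix with
cell labels, and the toy epigenome (genome FASTA, TSS table, DHS peak
calls from two samples, two chromatin-state segmentations, NB-noised
signal and input tracks), plus the truth tables used to score every
later step.
"""

import argparse
from pathlib import Path

from click.testing import CliRunner

from devdecomp.cli import main as cli


def run(seed: int, out: Path) -> None:
    r = CliRunner().invoke(cli, ["synth", "--seed", str(seed), "--out", str(out)],
                           catch_exceptions=False)
    print(r.output.strip())
    print(f"Datasets and truth tables written under {out}/")


if __name__ == "__main__":
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/data"))
    args = ap.parse_args()
    run(args.seed, args.out)
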