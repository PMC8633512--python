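#!/usr/bin/env python
"""Transcription-factor-binding-site gains and losses.

Summarises the per-SNP 11-bp-window motif deltas produced by the pipeline and
the motif content of the deleted sequence, and demonstrates the resistance-
gene-style event where one SNP destroys a TTGATC motif while creating a
W-box.  Tables go to results/.
"""

import os
import sys

import pandas as pd

from promcap.models import Motif
from promcap.tfbs import snp_window_delta

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
OUT = os.path.join(ROOT, "scratch", "analysis")


def main() -> int:
    if not os.path.isdir(OUT):
        sys.exit("run analysis/03_run_pipeline.py first")
    deltas = pd.read_csv(os.path.join(OUT, "tfbs_deltas.tsv"), sep="\t")
    content = pd.read_csv(os.path.join(OUT, "deletion_tfbs.tsv"), sep="\t")

    n = len(deltas)
    gained = deltas.gained.notna() & (deltas.gained != "")
    lost = deltas.lost.notna() & (deltas.lost != "")
    print(f"{n} haplotype SNPs scanned in +/-5 bp windows: "
          f"{gained.sum()} gain and {lost.sum()} lose at least one motif")
    print("motif content of deleted sequences (zero is a valid outcome):")
    print(content.to_string(index=False))

    lib = [Motif("W-box", ("Ta",), "TGAC"), Motif("TTGATC-motif", ("Td",), "TTGATC")]
    d = snp_window_delta("AATGATTGATC", 5, "C", lib)
    print(f"worked example: T>C at the window centre loses {d.lost} and gains {d.gained}")

    deltas.to_csv(os.path.join(ROOT, "results", "06_tfbs_deltas.tsv"), sep="\t", index=False)
    content.to_csv(os.path.join(ROOT, "results", "06_deletion_tfbs.tsv"), sep="\t", index=False)
    return 0


if __name__ == "__main__":
    sys.exit(main())
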