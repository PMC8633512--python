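#!/usr/bin/env python
"""Collect the headline numbers of the whole study into results/.

Combines the pipeline's summary with the trait roll-up of the target table
and prints the figures a reader would quote: subgenome specificity, haplotype
structure, polymorphism rates, deletions and TFBS deltas.
"""

import json
import os
import sys

from promcap import io as pio
from promcap.pipeline import trait_rollup

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
OUT = os.path.join(ROOT, "scratch", "analysis")
PANEL = os.path.join(ROOT, "scratch", "panel")


def main() -> int:
    if not os.path.isdir(OUT):
        sys.exit("run analysis/03_run_pipeline.py first")
    with open(os.path.join(OUT, "summary.json")) as fh:
        summary = json.load(fh)
    targets = pio.read_targets(
        os.path.join(PANEL, "annotation.gff3"), os.path.join(PANEL, "targets.tsv")
    )
    rollup = trait_rollup(targets)
    rollup.to_csv(os.path.join(ROOT, "results", "07_trait_rollup.tsv"), sep="\t", index=False)

    headline = {
        "n_targets": summary["n_targets"],
        "n_accessions": summary["n_accessions"],
        "subgenome_verdicts": summary["subgenome_verdicts"],
        "reference_self_check": summary["reference_self_check"],
        "haplotype_summary": summary["haplotype_summary"],
        "polymorphism_frequency_per_kbp": summary["polymorphism_frequency_per_kbp"],
        "introgression_percent_by_relative": summary["introgression_percent_by_relative"],
        "n_deletions": summary["n_deletions"],
    }
    with open(os.path.join(ROOT, "results", "07_headline.json"), "w") as fh:
        json.dump(headline, fh, indent=2, sort_keys=True)
    print(json.dumps(headline, indent=2, sort_keys=True))
    return 0


if __name__ == "__main__":
    sys.exit(main())
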