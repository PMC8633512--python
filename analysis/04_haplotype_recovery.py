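#!/usr/bin/env python
"""Compare recovered haplotype groups against the planted truth.

Checks that the shared/unique/reference-identical partition, the
introgression recipients and the nullisomic arm flag all come back exactly
from the emitted files, and writes the haplotype headline table to results/.
"""

import os
import sys

import pandas as pd

ROOT = os.path.dirname(os.path.dirname(os.path.abspath(__file__)))
OUT = os.path.join(ROOT, "scratch", "analysis")
PANEL = os.path.join(ROOT, "scratch", "panel")


def main() -> int:
    if not os.path.isdir(OUT):
        sys.exit("run analysis/03_run_pipeline.py first")
    grp = pd.read_csv(os.path.join(OUT, "haplotype_groups.tsv"), sep="\t")
    truth = pd.read_csv(os.path.join(PANEL, "truth", "haplotypes.tsv"), sep="\t")

    exact = 0
    genes = sorted(truth.gene_id.unique())
    for gid in genes:
        want = {
            (r.signature, tuple(sorted(str(r.members).split(","))))
            for r in truth[truth.gene_id == gid].itertuples()
        }
        got = {
            (r.signature, tuple(sorted(str(r.members).split(","))))
            for r in grp[grp.gene_id == gid].itertuples()
        }
        exact += want == got
    print(f"haplotype partitions recovered exactly: {exact}/{len(genes)} genes")

    classes = grp.groupby("class").size()
    ref_only = sum(
        1
        for _gid, sub in grp.groupby("gene_id")
        if len(sub) == 1 and bool(sub.iloc[0].ref_identical)
    )
    print(f"groups: {classes.to_dict()}; genes whose sole haplotype is "
          f"reference-identical: {ref_only}")

    intro = pd.read_csv(os.path.join(OUT, "introgression.tsv"), sep="\t")
    flags = pd.read_csv(os.path.join(OUT, "arm_flags.tsv"), sep="\t")
    print("introgression candidates:")
    print(intro.to_string(index=False))
    print("nullisomic arm flags:")
    print(flags.to_string(index=False))

    summary = grp.groupby("gene_id").agg(
        n_haplotypes=("label", "size"),
        n_shared=("class", lambda s: (s == "shared").sum()),
        n_unique=("class", lambda s: (s == "unique").sum()),
    )
    summary.to_csv(os.path.join(ROOT, "results", "04_haplotypes_per_gene.tsv"), sep="\t")
    return 0 if exact == len(genes) else 1


if __name__ == "__main__":
    sys.exit(main())
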