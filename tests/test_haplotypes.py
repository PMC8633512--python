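"""Haplotype signatures, grouping, gene status and cross-ploidy sharing."""

import pytest

from promcap.haplotypes import (
    Signature,
    build_signature,
    call_gene_status,
    cross_ploidy_sharing,
    detect_missing_arm_clusters,
    group_haplotypes,
    homozygous_filter,
    summarize_haplotypes,
)
from promcap.models import TargetGene, Variant


def target(gene_id="g1", subgenome="B", start=1000, span=1700, chrom="chr1", arm="S"):
    return TargetGene(
        gene_id=gene_id,
        trait_tag="T1",
        homoeo_group_id="HG1",
        subgenome=subgenome,
        chrom=chrom,
        strand="+",
        atg_pos=start + span + 1,
        target_interval=(start, start + span),
        partitions={},
        arm=arm,
    )


def snp(pos, alt="T", chrom="chr1", af=1.0, qual=50.0, depth=40):
    return Variant(chrom, pos, "A", alt, af, qual, depth)


class TestHomozygousFilter:
    def test_kept_and_dropped(self):
        kept = snp(10)
        het = snp(11, af=0.5)
        lowq = snp(12, qual=20)
        lowd = snp(13, depth=5)
        assert homozygous_filter([kept, het, lowq, lowd]) == [kept]

    def test_indel_length_boundary(self):
        ok = Variant("chr1", 5, "A" + "C" * 20, "A", 1.0, 60, 30)   # 20 bp: kept
        big = Variant("chr1", 9, "A" + "C" * 25, "A", 1.0, 60, 30)  # 25 bp: structural route
        assert homozygous_filter([ok, big]) == [ok]


class TestBuildSignature:
    def test_sorted_and_windowed(self):
        t = target(start=1000)
        vs = [snp(2101), snp(1558), snp(50), snp(9999)]  # two inside [1000, 2700)
        sig = build_signature("a1", t, vs, captured_target_bp=1700)
        assert [v.pos for v in sig.variants] == [1558, 2101]
        assert sig.complete

    def test_empty_signature_is_reference_candidate(self):
        sig = build_signature("a1", target(), [], captured_target_bp=1700)
        assert sig.variants == () and sig.complete

    def test_low_capture_flagged_incomplete(self):
        sig = build_signature("a1", target(), [], captured_target_bp=340)  # 20%
        assert not sig.complete


class TestGrouping:
    def _sigs(self, assignment, t):
        out = []
        for acc, positions in assignment.items():
            vs = tuple(snp(p) for p in sorted(positions))
            out.append(Signature(t.gene_id, acc, vs))
        return out

    def test_three_groups_with_classes(self):
        t = target()
        sigs = self._sigs(
            {"a": [], "b": [], "c": [1500], "d": [1500], "e": [1500, 1600]}, t
        )
        groups = group_haplotypes(sigs, t)
        assert [(g.label, len(g.members), g.klass, g.ref_identical) for g in groups] == [
            ("B1", 2, "shared", True),
            ("B2", 2, "shared", False),
            ("B3", 1, "unique", False),
        ]

    def test_all_reference_identical(self):
        t = target()
        groups = group_haplotypes(self._sigs({f"a{i}": [] for i in range(5)}, t), t)
        assert len(groups) == 1 and groups[0].klass == "shared" and groups[0].ref_identical

    def test_partition_property(self):
        t = target()
        sigs = self._sigs(
            {"a": [], "b": [1500], "c": [1500], "d": [1700], "e": [1500, 1600], "f": []}, t
        )
        groups = group_haplotypes(sigs, t)
        assert sum(len(g.members) for g in groups) == len(sigs)
        seen = [m for g in groups for m in g.members]
        assert sorted(seen) == sorted(s.accession_id for s in sigs)
        assert len(groups) == len({s.key() for s in sigs})

    def test_order_invariance_with_labels(self):
        t = target()
        sigs = self._sigs({"a": [1500], "b": [1500], "c": [], "d": [1400]}, t)
        fwd = group_haplotypes(sigs, t)
        rev = group_haplotypes(sigs[::-1], t)
        assert [(g.label, g.signature, g.members) for g in fwd] == [
            (g.label, g.signature, g.members) for g in rev
        ]

    def test_comparison_set_limits_shared(self):
        t = target()
        sigs = self._sigs({"hex1": [1500], "rel1": [1500]}, t)
        groups = group_haplotypes(sigs, t, comparison_set={"hex1"})
        assert groups[0].klass == "unique"  # one hexaploid member only

    def test_incomplete_excluded(self):
        t = target()
        good = Signature(t.gene_id, "a", (snp(1500),), complete=True)
        bad = Signature(t.gene_id, "b", (snp(1500),), complete=False)
        groups = group_haplotypes([good, bad], t)
        assert groups[0].members == ("a",)


class TestGeneStatus:
    @pytest.mark.parametrize(
        "promoter, cds, status",
        [
            (0, 0, "missing_gene"),
            (0, 400, "promoter_absent_cds_present"),
            (1700, 500, "captured"),
        ],
    )
    def test_states(self, promoter, cds, status):
        assert call_gene_status("a", "g", promoter, cds).status == status


class TestArmClusters:
    def _statuses(self, acc, missing, captured):
        out = []
        targets = {}
        for i, gid in enumerate(missing):
            targets[gid] = target(gene_id=gid, arm="S")
            out.append(call_gene_status(acc, gid, 0, 0))
        for gid in captured:
            targets[gid] = target(gene_id=gid, arm="L")
            out.append(call_gene_status(acc, gid, 1700, 400))
        return out, targets

    def test_nullisomic_arm_flagged(self):
        statuses, targets = self._statuses("hob", [f"s{i}" for i in range(6)], ["l1", "l2"])
        flags = detect_missing_arm_clusters(statuses, targets)
        assert len(flags) == 1 and flags[0]["arm"] == "S" and flags[0]["n_missing"] == 6

    def test_one_present_gene_blocks_flag(self):
        statuses, targets = self._statuses("acc", [f"s{i}" for i in range(9)], ["l1"])
        statuses.append(call_gene_status("acc", "s_ok", 1700, 400))
        targets["s_ok"] = target(gene_id="s_ok", arm="S")
        assert detect_missing_arm_clusters(statuses, targets) == []

    def test_small_arm_never_flagged(self):
        statuses, targets = self._statuses("acc", ["s0", "s1"], ["l1"])
        assert detect_missing_arm_clusters(statuses, targets, min_genes=5) == []

    def test_synthetic_nullisomic_recovered(self, sim30):
        from conftest import read_tsv

        flags = read_tsv(sim30["outdir"] / "arm_flags.tsv")
        acc, sub, arm = sim30["truth"].nullisomic
        assert len(flags) == 1
        row = flags.iloc[0]
        assert (row.accession_id, row.chrom, row.arm) == (acc, f"chr{sub}", arm)


class TestCrossPloidySharing:
    def test_planted_recipients_exact(self, sim30):
        from conftest import read_tsv

        intro = read_tsv(sim30["outdir"] / "introgression.tsv")
        for rec in sim30["truth"].introgressions:
            rows = intro[(intro.relative == rec["donor"]) & (intro.gene_id == rec["gene_id"])]
            assert len(rows) == 1
            carriers = set(str(rows.iloc[0].hexaploid_carriers).split(","))
            assert carriers == set(rec["recipients"])

    def test_empty_relative_signature_excluded(self):
        t = target()
        grp = group_haplotypes(
            [Signature("g1", "hex1", ()), Signature("g1", "hex2", ())], t
        )
        rows, pct = cross_ploidy_sharing(
            {"g1": grp}, {"rel": [Signature("g1", "rel", ())]}, {"hex1", "hex2"}
        )
        assert rows == [] and pct["rel"] == 0.0

    def test_unshared_relative_absent_from_table(self):
        t = target()
        hexsigs = [Signature("g1", "hex1", (snp(1500),)), Signature("g1", "hex2", (snp(1500),))]
        grp = group_haplotypes(hexsigs, t)
        rows, _ = cross_ploidy_sharing(
            {"g1": grp}, {"rel": [Signature("g1", "rel", (snp(1600),))]}, {"hex1", "hex2"}
        )
        assert rows == []


class TestSummary:
    def test_counts_and_histogram(self):
        t1, t2 = target("g1"), target("g2")
        g1 = group_haplotypes(
            [
                Signature("g1", "a", ()),
                Signature("g1", "b", ()),
                Signature("g1", "c", (snp(1500),)),
            ],
            t1,
        )
        g2 = group_haplotypes(
            [Signature("g2", "a", ()), Signature("g2", "b", ())], t2
        )
        s = summarize_haplotypes({"g1": g1, "g2": g2})
        assert s["ref_identical_only_genes"] == 1
        assert s["ref_identical_only_percent"] == 50
        assert s["unique_by_accession"] == {"c": 1}
        assert s["snps_per_haplotype_hist"] == {1: 0.5}

    def test_planted_histogram_matches_truth(self, sim30):
        truth = sim30["truth"]
        from conftest import read_tsv

        grp = read_tsv(sim30["outdir"] / "haplotype_groups.tsv")
        want = {}
        for groups in truth.haplotypes.values():
            for sig, _m in groups:
                n = sum(1 for _p, r, a in sig if len(r) == 1 == len(a))
                if sig:
                    want[n] = want.get(n, 0) + 1
        got = {}
        for r in grp.itertuples():
            if r.signature != ".":
                got[r.n_snps] = got.get(r.n_snps, 0) + 1
        assert got == want
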