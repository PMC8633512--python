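"""Bait design: tiling closed form, masking, specificity and filtering."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from promcap.baits import (
    GenomeSeedIndex,
    MaskTrack,
    Probe,
    candidate_count,
    design_baits,
    filter_probes,
    mask_repeats,
    probe_masked_fraction,
    specificity_screen,
    target_coverage,
    tile_candidates,
)
from promcap.models import RepeatEntry, TargetGene, revcomp


def make_target(span=1700, start=0, gene_id="g1", chrom="chr1"):
    return TargetGene(
        gene_id=gene_id,
        trait_tag="T1",
        homoeo_group_id="HG1",
        subgenome="A",
        chrom=chrom,
        strand="+",
        atg_pos=start + span + 1,
        target_interval=(start, start + span),
        partitions={},
    )


class TestTiling:
    @pytest.mark.parametrize("span, expected", [(1700, 27), (120, 1), (854, 13)])
    def test_counts(self, span, expected):
        assert candidate_count(span) == expected

    @given(span=st.integers(120, 5000))
    @settings(max_examples=300, deadline=None)
    def test_closed_form(self, span):
        assert candidate_count(span) == (span - 120) // 60 + 1

    def test_starts_and_sequences(self):
        rng = np.random.default_rng(0)
        genome = {"chr1": "".join(rng.choice(list("ACGT"), 2000))}
        probes = tile_candidates(make_target(1700), genome)
        assert [p.genomic_start for p in probes] == list(range(0, 1561, 60))
        assert all(p.sequence == genome["chr1"][p.genomic_start : p.genomic_start + 120] for p in probes)

    def test_too_short_span(self):
        with pytest.raises(ValueError):
            candidate_count(119)


class TestMasking:
    def _genome_with_element(self, rng, element, where=500, rc=False):
        bg = "".join(rng.choice(list("ACGT"), 2000))
        ins = revcomp(element) if rc else element
        return {"chr1": bg[:where] + ins + bg[where:]}

    def test_exact_element_masked(self):
        rng = np.random.default_rng(1)
        el = "".join(rng.choice(list("ACGT"), 300))
        genome = self._genome_with_element(rng, el)
        tracks = mask_repeats(genome, [RepeatEntry("e1", el)])
        assert (500, 800) in tracks["chr1"].intervals

    def test_revcomp_orientation_masked(self):
        rng = np.random.default_rng(2)
        el = "".join(rng.choice(list("ACGT"), 300))
        genome = self._genome_with_element(rng, el, rc=True)
        tracks = mask_repeats(genome, [RepeatEntry("e1", el)])
        assert (500, 800) in tracks["chr1"].intervals

    def test_short_element_not_masked(self):
        rng = np.random.default_rng(3)
        el = "".join(rng.choice(list("ACGT"), 40))
        genome = self._genome_with_element(rng, el)
        tracks = mask_repeats(genome, [RepeatEntry("e1", el)], min_match_len=60)
        assert tracks["chr1"].intervals == []

    def test_empty_library_warns(self):
        with pytest.warns(UserWarning):
            tracks = mask_repeats({"chr1": "ACGT" * 100}, [])
        assert tracks["chr1"].intervals == []


class TestMaskedFraction:
    def _probe(self, start=100):
        return Probe("p", "g", "chr1", start, "A" * 120)

    def test_quarter(self):
        track = MaskTrack("chr1", [(190, 400)])
        assert probe_masked_fraction(self._probe(100), track) == 0.25

    def test_none_and_full(self):
        assert probe_masked_fraction(self._probe(), MaskTrack("chr1", [])) == 0.0
        assert probe_masked_fraction(self._probe(), MaskTrack("chr1", [(0, 500)])) == 1.0


class TestFiltering:
    def _probe(self, masked, hits):
        p = Probe("p", "g", "chr1", 0, "A" * 120)
        p.masked_fraction, p.hyb_hits = masked, hits
        return p

    @pytest.mark.parametrize(
        "masked, hits, status",
        [
            (0.25, 1, "removed_masked"),   # ">= 25%" boundary removes
            (0.10, 3, "removed_multihit"),
            (0.10, 1, "retained"),
            (0.30, 5, "removed_masked"),   # mask test applied first
            (0.249, 2, "removed_multihit"),
        ],
    )
    def test_status(self, masked, hits, status):
        (p,) = filter_probes([self._probe(masked, hits)])
        assert p.status == status

    def test_idempotent_order_independent(self):
        probes = [self._probe(m, h) for m in (0.0, 0.25, 0.4) for h in (1, 2)]
        once = [p.status for p in filter_probes(probes)]
        twice = [p.status for p in filter_probes(probes)]
        rev = [p.status for p in filter_probes(probes[::-1])][::-1]
        assert once == twice == rev


def brute_force_hyb_hits(probe_seq, genome, seed_len=16, min_identity=0.90, min_aln_len=80):
    """Independent oracle: enumerate every diagonal placement on both strands,
    require a shared exact seed and a window of min_aln_len at min_identity."""
    hits = []
    for strand, q in (("+", probe_seq), ("-", revcomp(probe_seq))):
        qarr = np.frombuffer(q.encode(), dtype=np.uint8)
        for chrom, seq in genome.items():
            garr = np.frombuffer(seq.encode(), dtype=np.uint8)
            for g0 in range(-len(q) + min_aln_len, len(seq) - min_aln_len + 1):
                s, e = max(0, g0), min(len(seq), g0 + len(q))
                if e - s < min_aln_len:
                    continue
                m = garr[s:e] == qarr[s - g0 : e - g0]
                # exact seed anywhere on this diagonal
                run = best = 0
                for x in m:
                    run = run + 1 if x else 0
                    best = max(best, run)
                if best < seed_len:
                    continue
                ok = False
                lo = mism = 0
                for hi in range(len(m)):
                    if not m[hi]:
                        mism += 1
                    while mism > (1 - min_identity) * (hi - lo + 1):
                        if not m[lo]:
                            mism -= 1
                        lo += 1
                    if hi - lo + 1 >= min_aln_len:
                        ok = True
                        break
                if ok:
                    hits.append((strand, chrom, g0))
    loci = []
    for h in sorted(hits):
        if any(h[0] == l0 and h[1] == l1 and abs(h[2] - l2) <= 5 for l0, l1, l2 in loci):
            continue
        loci.append(h)
    return len(loci)


class TestSpecificity:
    def setup_method(self):
        rng = np.random.default_rng(4)
        self.a = "".join(rng.choice(list("ACGT"), 1500))
        self.b = "".join(rng.choice(list("ACGT"), 1500))

    def test_unique_probe_counts_own_locus(self):
        genome = {"chr1": self.a, "chr2": self.b}
        index = GenomeSeedIndex(genome)
        p = Probe("p", "g", "chr1", 200, self.a[200:320])
        assert specificity_screen(p, index) == 1

    def test_verbatim_copy_elsewhere_counts_two(self):
        dup = self.a[200:320]
        genome = {"chr1": self.a, "chr2": self.b[:700] + dup + self.b[700:]}
        index = GenomeSeedIndex(genome)
        p = Probe("p", "g", "chr1", 200, dup)
        assert specificity_screen(p, index) == 2

    def test_matches_exhaustive_oracle_on_synthetic_genome(self):
        """Seeded screen equals the brute-force diagonal enumeration,
        including over homoeologous loci of the divergence-grid genome."""
        from promcap.simulate import PanelSimConfig, build_reference_genome

        ref = build_reference_genome(
            PanelSimConfig(seed=3, n_homoeo_groups=2, spacer=200, flank=300, cds_len=200)
        )
        genome = ref.sequences
        index = GenomeSeedIndex(genome)
        rng = np.random.default_rng(5)
        for t in ref.targets[:3]:
            start = t.target_interval[0] + int(rng.integers(0, t.span - 120))
            p = Probe("p", t.gene_id, t.chrom, start, genome[t.chrom][start : start + 120])
            assert specificity_screen(p, index) == brute_force_hyb_hits(p.sequence, genome)


class TestCoverage:
    def test_disjoint_probes(self):
        t = make_target(1700)
        probes = []
        for k in range(8):
            p = Probe(f"p{k}", "g1", "chr1", k * 200, "A" * 120)
            p.status = "retained"
            probes.append(p)
        covered, pct = target_coverage(probes, t)
        assert (covered, pct) == (960, 56.5)

    def test_full_tiling_and_zero(self):
        # start-anchored tiling of a 1700 bp target covers [0, 1680); adding
        # an end-anchored probe closes the last 20 bp to 100%
        t = make_target(1700)
        probes = []
        for k in range(27):
            p = Probe(f"p{k}", "g1", "chr1", k * 60, "A" * 120)
            p.status = "retained"
            probes.append(p)
        assert target_coverage(probes, t) == (1680, 98.8)
        end_anchored = Probe("p27", "g1", "chr1", 1580, "A" * 120)
        end_anchored.status = "retained"
        assert target_coverage(probes + [end_anchored], t) == (1700, 100.0)
        for p in probes:
            p.status = "removed_masked"
        assert target_coverage(probes, t) == (0, 0.0)


class TestDesignOnSyntheticGenome:
    def test_retained_probes_unique_and_te_probes_masked(self, sim6):
        ref, probes = sim6["ref"], sim6["probes"]
        assert all(p.hyb_hits == 1 for p in probes if p.status == "retained")
        te0, te1 = ref.chimera["interval"]
        inside_te = [
            p
            for p in probes
            if p.chrom == ref.chimera["chrom"] and p.genomic_start >= te0 and p.genomic_start + 120 <= te1
        ]
        assert inside_te and all(p.status == "removed_masked" for p in inside_te)
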