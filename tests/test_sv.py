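"""Cliff-edge deletions, repeat annotation, hairpins and copy counts."""

import numpy as np
import pytest

from promcap.models import DepthProfile, RepeatEntry, Variant, revcomp
from promcap.simulate import build_mite
from promcap.sv import (
    annotate_deletion_repeats,
    catalogue_small_indels,
    detect_cliff_deletions,
    find_hairpin,
    genome_hit_count,
)


def profile(depths, start=0):
    return DepthProfile("a1", "g1", "chr1", (start, start + len(depths)), np.array(depths))


# ---------------------------------------------------------------- oracles

def cliff_oracle(depths, flank=10, floor=0, min_len=21, max_edge=5):
    """Brute-force scan over all maximal low-depth runs with flank checks."""
    events, trunc = [], []
    n = len(depths)
    i = 0
    while i < n:
        if depths[i] <= floor:
            j = i
            while j < n and depths[j] <= floor:
                j += 1
            if j - i >= min_len:
                if i == 0 or j == n:
                    trunc.append((i, j))
                else:
                    left = any(depths[k] >= flank for k in range(max(0, i - max_edge), i))
                    right = any(depths[k] >= flank for k in range(j, min(n, j + max_edge)))
                    if left and right:
                        events.append((i, j))
            i = j
        else:
            i += 1
    return events, trunc


def hairpin_oracle(seq, min_stem=20, max_loop=200, min_stem_identity=0.8):
    """Exhaustive enumeration over every (arm-a end, arm-b start) anchor with
    arms grown outward one base pair at a time."""
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    n = len(seq)
    best = None
    for a_end in range(min_stem, n):
        for b_start in range(a_end, min(n, a_end + max_loop + 1)):
            max_L = min(a_end, n - b_start)
            matches = 0
            for L in range(1, max_L + 1):
                if comp.get(seq[a_end - L]) == seq[b_start + L - 1]:
                    matches += 1
                if L >= min_stem and matches / L >= min_stem_identity:
                    cand = (-(2 * matches - L), a_end - L, -L, b_start - a_end, b_start)
                    if best is None or cand < best:
                        best = cand
    if best is None:
        return None
    score, a, negL, loop, b = -best[0], best[1], best[2], best[3], best[4]
    return (score, a, -negL, loop, b)


# ---------------------------------------------------------------- deletions

class TestCliffDetection:
    def test_below_min_len_ignored(self):
        d = [20, 20] + [0] * 19 + [20, 20]
        events, trunc = detect_cliff_deletions(profile(d))
        assert events == [] and trunc == []

    def test_planted_512_exact(self):
        d = [30] * 40 + [0] * 512 + [30] * 40
        events, _ = detect_cliff_deletions(profile(d, start=1000))
        assert len(events) == 1
        assert events[0].interval == (1040, 1552)
        assert events[0].size == 512 and events[0].klass == "large"

    def test_run_touching_window_end_is_truncated(self):
        d = [30] * 40 + [0] * 60
        events, trunc = detect_cliff_deletions(profile(d))
        assert events == [] and trunc == [(40, 100)]

    def test_soft_edge_rejected(self):
        # depth ramps down slowly: no >=10 flank within 5 bp of the gap
        d = [30] * 30 + [9, 8, 7, 6, 5, 4] + [0] * 40 + [4, 5, 6, 7, 8, 9] + [30] * 30
        events, _ = detect_cliff_deletions(profile(d))
        assert events == []

    def test_matches_bruteforce_on_random_profiles(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            n = int(rng.integers(40, 250))
            d = rng.choice([0, 0, 0, 5, 12, 30], size=n, p=[0.3, 0.1, 0.1, 0.1, 0.2, 0.2])
            p = profile(d)
            events, trunc = detect_cliff_deletions(p)
            want_events, want_trunc = cliff_oracle(d)
            assert [e.interval for e in events] == want_events
            assert trunc == want_trunc

    def test_planted_deletions_recovered_end_to_end(self, sim30):
        from conftest import read_tsv

        dele = read_tsv(sim30["outdir"] / "deletions.tsv")
        (rec,) = sim30["truth"].deletions
        d0, d1 = rec["interval"]
        assert set(dele.accession_id) == set(rec["carriers"])
        assert (dele.start == d0).all() and (dele.end == d1).all()
        assert (dele["class"] == "large").all()


class TestSmallIndelCatalogue:
    def test_counts(self):
        vs = [
            Variant("c", 1, "A", "T", 1.0, 60, 30),
            Variant("c", 5, "A", "G", 1.0, 60, 30),
            Variant("c", 9, "A", "C", 1.0, 60, 30),
            Variant("c", 20, "A" + "G" * 20, "A", 1.0, 60, 30),  # 20 bp boundary: counted
        ]
        assert catalogue_small_indels({"a1": vs, "a2": []}) == {"a1": (3, 1), "a2": (0, 0)}


# ---------------------------------------------------------------- repeats

class TestRepeatAnnotation:
    def test_exact_single_element(self):
        rng = np.random.default_rng(0)
        el = "".join(rng.choice(list("ACGT"), 200))
        hits, chimera = annotate_deletion_repeats(el, [RepeatEntry("e1", el)])
        assert len(hits) == 1
        h = hits[0]
        assert h.query_interval == (0, 200) and h.identity == 1.0 and not h.nested
        assert not chimera

    def test_no_match(self):
        hits, chimera = annotate_deletion_repeats("ACGT" * 30, [RepeatEntry("e1", "TTTTAAAACCCCGGGG" * 8)])
        assert hits == [] and not chimera

    def test_planted_chimera_structure(self, sim6):
        """Outer element split into two arms around a nested inner MITE."""
        chim = sim6["ref"].chimera
        hits, chimera = annotate_deletion_repeats(chim["sequence"], sim6["ref"].repeat_library)
        assert chimera
        inner = [h for h in hits if h.name == chim["inner_name"]]
        outer = [h for h in hits if h.name == chim["outer_name"]]
        assert len(inner) == 1 and inner[0].nested
        i0, i1 = chim["inner_interval"][0] - chim["interval"][0], chim["inner_interval"][1] - chim["interval"][0]
        assert inner[0].query_interval == (i0, i1)
        assert len(outer) >= 2
        spans = [h.query_interval for h in outer]
        assert min(s for s, _ in spans) == 0 and max(e for _, e in spans) == len(chim["sequence"])


# ---------------------------------------------------------------- hairpins

class TestHairpin:
    def test_constructed_mite(self):
        rng = np.random.default_rng(1)
        s = build_mite(rng, stem=25, loop=100)
        hp = find_hairpin(s)
        assert hp is not None
        assert hp.stem_len >= 25 and hp.stem_identity >= 0.9
        assert (hp.arm_a, hp.arm_b) == ((0, hp.stem_len), (150 - hp.stem_len, 150)) or hp.score >= 25

    def test_random_sequence_none(self):
        rng = np.random.default_rng(2)
        s = "".join(rng.choice(list("ACGT"), 200))
        assert find_hairpin(s) is None
        assert hairpin_oracle(s) is None

    def test_degraded_stem_below_identity(self):
        rng = np.random.default_rng(3)
        stem = "".join(rng.choice(list("ACGT"), 25))
        loop = "".join(rng.choice(list("ACGT"), 100))
        arm_b = list(revcomp(stem))
        for i in (1, 5, 9, 13, 17, 21):  # 6 spread mismatches: every >=20-window <0.8
            arm_b[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[arm_b[i]]
        s = stem + loop + "".join(arm_b)
        assert find_hairpin(s) is None

    def test_too_short_sequence(self):
        assert find_hairpin("ACGTACGT") is None

    @pytest.mark.parametrize("length, seed", [(150, 4), (200, 5), (260, 6), (300, 7)])
    def test_agrees_with_exhaustive_oracle(self, length, seed):
        rng = np.random.default_rng(seed)
        if seed % 2:
            s = build_mite(rng, stem=22, loop=60)
            s = s + "".join(rng.choice(list("ACGT"), max(0, length - len(s))))
        else:
            s = "".join(rng.choice(list("ACGT"), length))
        hp = find_hairpin(s)
        want = hairpin_oracle(s)
        if want is None:
            assert hp is None
        else:
            score, a, L, loop, b = want
            assert (hp.score, hp.arm_a[0], hp.stem_len, hp.loop_len, hp.arm_b[0]) == (
                score, a, L, loop, b,
            )


# ---------------------------------------------------------------- copy count

class TestGenomeHitCount:
    def test_planted_mite_copies(self, sim6):
        ref = sim6["ref"]
        inner = next(r.sequence for r in ref.repeat_library if r.name == ref.chimera["inner_name"])
        assert genome_hit_count(inner, ref.sequences) == 3

    def test_chimera_unique_full_length(self, sim6):
        ref = sim6["ref"]
        assert genome_hit_count(ref.chimera["sequence"], ref.sequences) == 1

    def test_absent_sequence(self, sim6):
        rng = np.random.default_rng(9)
        q = "".join(rng.choice(list("ACGT"), 150))
        assert genome_hit_count(q, sim6["ref"].sequences) == 0

    def test_self_slice(self, sim6):
        ref = sim6["ref"]
        q = ref.sequences["chrA"][1000:1500]
        assert genome_hit_count(q, ref.sequences) >= 1
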