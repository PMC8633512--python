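"""Structural variation from coverage: cliff-edge deletion detection, repeat
annotation of deleted sequence (including nested/chimeric decomposition),
MITE-style hairpin prediction and genomic copy counting.

The detection parametrization (flank depth, floor depth, edge sharpness) is an
operationalization of the visually diagnostic 'cliff edges' a deleted element
leaves in per-base capture depth."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import Align

from .models import DepthProfile, RepeatEntry, Variant, revcomp

MIN_DELETION_LEN = 21  # <= 20 bp events are VCF InDels


@dataclass
class DeletionEvent:
    accession_id: str
    gene_id: str
    chrom: str
    interval: tuple[int, int]  # reference, 0-based half-open
    left_edge_bp: int
    right_edge_bp: int

    @property
    def size(self) -> int:
        return self.interval[1] - self.interval[0]

    @property
    def klass(self) -> str:
        return "large" if self.size > 100 else "mid"


@dataclass
class RepeatHit:
    name: str
    query_interval: tuple[int, int]  # within the deletion sequence
    identity: float
    orientation: str  # + | -
    nested: bool = False


@dataclass
class Hairpin:
    stem_len: int
    loop_len: int
    stem_identity: float
    arm_a: tuple[int, int]
    arm_b: tuple[int, int]
    score: int


# ------------------------------------------------------------- deletions

def detect_cliff_deletions(
    profile: DepthProfile,
    flank_depth: int = 10,
    floor_depth: int = 0,
    min_len: int = MIN_DELETION_LEN,
    max_edge: int = 5,
) -> tuple[list[DeletionEvent], list[tuple[int, int]]]:
    """Maximal depth<=floor runs of at least min_len, flanked on both sides by
    depth >= flank_depth reached within max_edge bp.  Runs touching the window
    edges cannot show both cliffs and are returned separately as 'truncated'
    candidates (promoter-absent calls, not deletions)."""
    d = profile.depths
    low = d <= floor_depth
    events: list[DeletionEvent] = []
    truncated: list[tuple[int, int]] = []
    if not low.any():
        return events, truncated
    diff = np.diff(low.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if low[0]:
        starts.insert(0, 0)
    if low[-1]:
        ends.append(len(d))
    off = profile.window[0]
    for s, e in zip(starts, ends):
        if e - s < min_len:
            continue
        if s == 0 or e == len(d):
            truncated.append((s + off, e + off))
            continue
        left = d[max(0, s - max_edge) : s]
        right = d[e : e + max_edge]
        if len(left) and left.max() >= flank_depth and len(right) and right.max() >= flank_depth:
            left_edge = int(s - np.flatnonzero(d[:s] >= flank_depth).max())
            right_edge = int(np.flatnonzero(d[e:] >= flank_depth).min() + 1)
            events.append(
                DeletionEvent(
                    accession_id=profile.accession_id,
                    gene_id=profile.gene_id,
                    chrom=profile.chrom,
                    interval=(s + off, e + off),
                    left_edge_bp=left_edge,
                    right_edge_bp=right_edge,
                )
            )
    return events, truncated


def catalogue_small_indels(filtered_variants_by_acc: dict[str, list[Variant]]) -> dict[str, tuple[int, int]]:
    """(SNP count, small-InDel count) per accession after the homozygous
    filter; 20 bp is inclusive."""
    out: dict[str, tuple[int, int]] = {}
    for acc, variants in filtered_variants_by_acc.items():
        snps = sum(1 for v in variants if v.vtype == "SNP")
        indels = sum(1 for v in variants if v.vtype == "InDel" and v.indel_length <= 20)
        out[acc] = (snps, indels)
    return out


# ------------------------------------------------------------- repeats

def _local_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    return aligner


def _alignment_stats(alignment) -> tuple[int, int, tuple[int, int], float]:
    """(matches, aligned columns, target interval, identity)."""
    t_blocks, q_blocks = alignment.aligned
    matches = 0
    cols = 0
    t = alignment.target
    q = alignment.query
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        cols += te - ts
        matches += sum(1 for a, b in zip(t[ts:te], q[qs:qe]) if a == b)
    # gap columns between blocks
    for i in range(1, len(t_blocks)):
        cols += (t_blocks[i][0] - t_blocks[i - 1][1]) + (q_blocks[i][0] - q_blocks[i - 1][1])
    t_iv = (int(t_blocks[0][0]), int(t_blocks[-1][1]))
    return matches, cols, t_iv, matches / cols if cols else 0.0


def annotate_deletion_repeats(
    deletion_seq: str,
    repeat_library: list[RepeatEntry],
    min_identity: float = 0.8,
    min_len: int = 30,
    max_hits_per_entry: int = 8,
) -> tuple[list[RepeatHit], bool]:
    """Local alignments (Smith-Waterman, unit scores, gap -2) of every library
    element, both orientations, against the deleted reference sequence.

    An element interrupted by an insertion aligns as several local hits, so
    nesting is judged against each repeat's merged span: a hit lying strictly
    inside another repeat's span is marked nested.  The chimera flag is set
    when two or more distinct repeats jointly cover >= 80% of the deletion.
    Returns (hits, chimera_flag)."""
    aligner = _local_aligner()
    hits: list[RepeatHit] = []
    for entry in repeat_library:
        for orient, qseq in (("+", entry.sequence), ("-", revcomp(entry.sequence))):
            work = deletion_seq
            for _ in range(max_hits_per_entry):
                if len(work) == 0:
                    break
                alignment = aligner.align(work, qseq)
                try:
                    best = alignment[0]
                except IndexError:
                    break
                if best.score < min_len * min_identity:
                    break
                matches, cols, t_iv, ident = _alignment_stats(best)
                if cols < min_len or ident < min_identity:
                    break
                hits.append(RepeatHit(entry.name, t_iv, round(ident, 4), orient))
                work = work[: t_iv[0]] + "#" * (t_iv[1] - t_iv[0]) + work[t_iv[1] :]

    # nesting against merged per-repeat spans
    spans: dict[str, tuple[int, int]] = {}
    for h in hits:
        lo, hi = spans.get(h.name, (h.query_interval[0], h.query_interval[1]))
        spans[h.name] = (min(lo, h.query_interval[0]), max(hi, h.query_interval[1]))
    for h in hits:
        for name, (lo, hi) in spans.items():
            if name != h.name and lo < h.query_interval[0] and h.query_interval[1] < hi:
                h.nested = True

    covered = np.zeros(len(deletion_seq), dtype=bool)
    names = set()
    for h in hits:
        covered[h.query_interval[0] : h.query_interval[1]] = True
        names.add(h.name)
    chimera = len(names) >= 2 and covered.mean() >= 0.8 if len(deletion_seq) else False
    hits.sort(key=lambda h: h.query_interval)
    return hits, chimera


# ------------------------------------------------------------- hairpins

_COMP_TABLE = np.full(256, 0, dtype=np.uint8)
for a, b in zip(b"ACGT", b"TGCA"):
    _COMP_TABLE[a] = b


def find_hairpin(
    seq: str,
    min_stem: int = 20,
    max_loop: int = 200,
    min_stem_identity: float = 0.8,
) -> Hairpin | None:
    """Best-scoring pair of reverse-complementary arms (score = matches -
    mismatches), deterministic tie-break: leftmost arm start, then longest
    stem, then smallest loop.

    Arms (a, a+L) and (b, b+L) pair base a+k with base b+L-1-k; all such pairs
    lie on one anti-diagonal p+q = a+b+L-1 of the complement-match matrix, so
    the search walks anti-diagonals with prefix sums."""
    n = len(seq)
    if n < 2 * min_stem:
        return None
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    comp = _COMP_TABLE[arr]
    best: tuple | None = None  # (-score, a, -L, loop, b)

    for diag in range(2 * min_stem - 1, 2 * n - 2):
        p_lo = max(0, diag - n + 1)
        p_hi = (diag - 1) // 2  # p < q
        if p_hi - p_lo + 1 < min_stem:
            continue
        p = np.arange(p_lo, p_hi + 1)
        m = (comp[p] == arr[diag - p]).astype(np.int32)
        pre = np.concatenate(([0], np.cumsum(m)))
        # stem = window [i, e) of p; innermost pair at p=e-1, loop = diag-2e+1
        e_hi = min(p_hi + 1, (diag + 1) // 2)
        e_lo = max(p_lo + min_stem, int(np.ceil((diag + 1 - max_loop) / 2)))
        if e_lo > e_hi:
            continue
        e_vals = np.arange(e_lo, e_hi + 1)
        loops = diag - 2 * e_vals + 1
        keep = (loops >= 0) & (loops <= max_loop)
        e_vals = e_vals[keep]
        if e_vals.size == 0:
            continue
        i_vals = np.arange(p_lo, e_hi - min_stem + 1)
        if i_vals.size == 0:
            continue
        # matches[e, i] via broadcasting of prefix sums
        M = pre[e_vals[:, None] - p_lo] - pre[i_vals[None, :] - p_lo]
        L = e_vals[:, None] - i_vals[None, :]
        valid = L >= min_stem
        with np.errstate(divide="ignore", invalid="ignore"):
            ident = np.where(valid, M / np.maximum(L, 1), 0.0)
        score = 2 * M - L
        valid &= ident >= min_stem_identity
        if not valid.any():
            continue
        score = np.where(valid, score, -(10**9))
        flat = np.argmax(score)  # first occurrence: smallest e then smallest i
        # scan all maxima applying the global tie-break
        mx = score.max()
        for ei, ii in zip(*np.nonzero(score == mx)):
            a = int(i_vals[ii])
            e = int(e_vals[ei])
            Lv = e - a
            loop = diag - 2 * e + 1
            b = diag - e + 1
            cand = (-int(mx), a, -Lv, loop, b)
            if best is None or cand < best:
                best = cand
    if best is None:
        return None
    neg_score, a, neg_L, loop, b = best
    L = -neg_L
    score = -neg_score
    matches = (score + L) // 2
    return Hairpin(
        stem_len=L,
        loop_len=loop,
        stem_identity=round(matches / L, 4),
        arm_a=(a, a + L),
        arm_b=(b, b + L),
        score=score,
    )


# ------------------------------------------------------------- copy count

def genome_hit_count(
    seq: str,
    genome: dict[str, str],
    min_identity: float = 0.9,
    min_cover: float = 0.9,
    seed_len: int = 16,
) -> int:
    """Count genomic loci (both strands) where ``seq`` matches over at least
    ``min_cover`` of its length at ``min_identity`` (seeded ungapped scan)."""
    L = len(seq)
    need = int(np.ceil(min_cover * L))
    hits: list[tuple[str, str, int]] = []
    for strand, q in (("+", seq), ("-", revcomp(seq))):
        qarr = np.frombuffer(q.encode(), dtype=np.uint8)
        seeds = {q[o : o + seed_len]: o for o in range(0, L - seed_len + 1, max(1, seed_len // 2))}
        for chrom, gseq in genome.items():
            garr = np.frombuffer(gseq.encode(), dtype=np.uint8)
            checked: set[int] = set()
            for o in range(0, L - seed_len + 1, max(1, seed_len // 2))          :
                kmer = q[o : o + seed_len]
                start = 0
                while True:
                    j = gseq.find(kmer, start)
                    if j < 0:
                        break
                    start = j + 1
                    g0 = j - o
                    if any(abs(g0 - c) <= 5 for c in checked):
                        continue
                    checked.add(g0)
                    s = max(0, g0)
                    e = min(len(gseq), g0 + L)
                    if e - s < need:
                        continue
                    matches = int((garr[s:e] == qarr[s - g0 : e - g0]).sum())
                    if matches >= need * min_identity and (e - s) >= need:
                        ident = matches / (e - s)
                        if ident >= min_identity:
                            hits.append((strand, chrom, g0))
    # dedupe loci across strands (a palindromic hit counts once)
    loci: list[tuple[str, int]] = []
    for _strand, chrom, g0 in sorted(hits):
        if any(chrom == c and abs(g0 - p) <= 5 for c, p in loci):
            continue
        loci.append((chrom, g0))
    return len(loci)
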