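"""High-stringency capture bait design.

Reproduces the workflow: soft-mask the genome with a repeat library, tile each
target with 120-nt probe candidates every 60 nt (50% overlap), screen every
candidate genome-wide for extra strong hybridization sites, then drop probes
that are >=25% masked or have more than one strong site.

A "strong hybridization site" is defined as a locus that (i) shares at least
one exact ``seed_len``-mer with the probe and (ii) aligns ungapped over at
least ``min_aln_len`` bp at identity >= ``min_identity``.  The exact-seed
requirement models hybridization nucleation: a duplex cannot zip up without a
short perfectly paired core.  All thresholds are configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import (
    RepeatEntry,
    TargetGene,
    intersect_length,
    merge_intervals,
    percent_rounded,
    revcomp,
)

PROBE_LEN = 120
PROBE_STEP = 60
MASK_REMOVE_FRACTION = 0.25  # probes ">= 25% soft-masked" are removed


@dataclass
class Probe:
    probe_id: str
    gene_id: str
    chrom: str
    genomic_start: int  # 0-based
    sequence: str
    masked_fraction: float = 0.0
    hyb_hits: int = 1
    status: str = ""  # retained | removed_masked | removed_multihit

    @property
    def interval(self) -> tuple[int, int]:
        return (self.genomic_start, self.genomic_start + PROBE_LEN)


@dataclass
class MaskTrack:
    chrom: str
    intervals: list[tuple[int, int]] = field(default_factory=list)


# ---------------------------------------------------------------- masking

def _seed_index(sequences: dict[str, str], seed_len: int) -> dict[str, list[tuple[str, int]]]:
    idx: dict[str, list[tuple[str, int]]] = {}
    for name, seq in sequences.items():
        for i in range(len(seq) - seed_len + 1):
            idx.setdefault(seq[i : i + seed_len], []).append((name, i))
    return idx


def _max_window_at_identity(
    matches: np.ndarray, min_len: int, min_identity: float
) -> tuple[int, int] | None:
    """Longest window of a boolean match array with identity >= min_identity
    and length >= min_len (two-pointer scan); returns (start, end) or None."""
    best = None
    mism = 0
    lo = 0
    max_mism_at = lambda L: int((1.0 - min_identity) * L)
    for hi in range(len(matches)):
        if not matches[hi]:
            mism += 1
        while mism > max_mism_at(hi - lo + 1) and lo <= hi:
            if not matches[lo]:
                mism -= 1
            lo += 1
        L = hi - lo + 1
        if L >= min_len and (best is None or L > best[1] - best[0]):
            best = (lo, hi + 1)
    return best


def mask_repeats(
    genome: dict[str, str],
    repeat_library: list[RepeatEntry],
    min_match_len: int = 60,
    max_mismatch_fraction: float = 0.10,
    seed_len: int = 16,
) -> dict[str, MaskTrack]:
    """Soft-mask every genomic interval matching a library element (either
    orientation) over >= min_match_len at mismatch fraction <= the threshold.

    Seeded exact-match extension stands in for cross_match: each shared
    ``seed_len``-mer anchors an ungapped diagonal comparison whose widest
    window within the identity bound is masked.
    """
    tracks = {chrom: MaskTrack(chrom) for chrom in genome}
    if not repeat_library:
        import warnings

        warnings.warn("empty repeat library: nothing masked")
        return tracks

    lib_seqs: dict[str, str] = {}
    for entry in repeat_library:
        lib_seqs[entry.name + "/+"] = entry.sequence.upper()
        lib_seqs[entry.name + "/-"] = revcomp(entry.sequence.upper())
    idx = _seed_index(lib_seqs, seed_len)

    for chrom, seq in genome.items():
        garr = np.frombuffer(seq.encode(), dtype=np.uint8)
        found: list[tuple[int, int]] = []
        seen_diag: set[tuple[str, int]] = set()
        for i in range(len(seq) - seed_len + 1):
            for name, off in idx.get(seq[i : i + seed_len], ()):  # noqa: B905
                g0 = i - off  # genome position of library element start on this diagonal
                key = (name, g0)
                if key in seen_diag:
                    continue
                seen_diag.add(key)
                lseq = lib_seqs[name]
                s = max(0, g0)
                e = min(len(seq), g0 + len(lseq))
                if e - s < min_match_len:
                    continue
                larr = np.frombuffer(lseq.encode(), dtype=np.uint8)[s - g0 : e - g0]
                matches = garr[s:e] == larr
                win = _max_window_at_identity(
                    matches, min_match_len, 1.0 - max_mismatch_fraction
                )
                if win:
                    found.append((s + win[0], s + win[1]))
        tracks[chrom].intervals = merge_intervals(found)
    return tracks


# ---------------------------------------------------------------- tiling

def candidate_count(span: int, probe_len: int = PROBE_LEN, step: int = PROBE_STEP) -> int:
    if span < probe_len:
        raise ValueError(f"target span {span} shorter than probe length {probe_len}")
    return (span - probe_len) // step + 1


def tile_candidates(
    target: TargetGene,
    genome: dict[str, str],
    probe_len: int = PROBE_LEN,
    step: int = PROBE_STEP,
) -> list[Probe]:
    """120-nt candidates every 60 nt, anchored at the target start."""
    start, end = target.target_interval
    n = candidate_count(end - start, probe_len, step)
    seq = genome[target.chrom]
    probes = []
    for k in range(n):
        g0 = start + k * step
        probes.append(
            Probe(
                probe_id=f"{target.gene_id}_p{k:03d}",
                gene_id=target.gene_id,
                chrom=target.chrom,
                genomic_start=g0,
                sequence=seq[g0 : g0 + probe_len],
            )
        )
    return probes


def probe_masked_fraction(probe: Probe, mask: MaskTrack) -> float:
    ov = intersect_length([probe.interval], mask.intervals)
    return ov / len(probe.sequence)


# ---------------------------------------------------------------- specificity

class GenomeSeedIndex:
    """Exact k-mer position index over the genome (forward strand only; probe
    reverse complements are looked up instead of indexing both strands)."""

    def __init__(self, genome: dict[str, str], seed_len: int = 16):
        self.seed_len = seed_len
        self.genome = genome
        self.index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in genome.items():
            for i in range(len(seq) - seed_len + 1):
                self.index.setdefault(seq[i : i + seed_len], []).append((chrom, i))

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def specificity_screen(
    probe: Probe,
    index: GenomeSeedIndex,
    min_identity: float = 0.90,
    min_aln_len: int = 80,
) -> int:
    """Count genomic sites (both strands) where the probe has a strong
    predicted hybridization site; the probe's own locus counts as one."""
    hits: set[tuple[str, str, int]] = set()
    seed_len = index.seed_len
    for strand, pseq in (("+", probe.sequence), ("-", revcomp(probe.sequence))):
        parr = np.frombuffer(pseq.encode(), dtype=np.uint8)
        diags_seen: set[tuple[str, int]] = set()
        for off in range(len(pseq) - seed_len + 1):
            for chrom, gpos in index.lookup(pseq[off : off + seed_len]):
                g0 = gpos - off
                if (chrom, g0) in diags_seen:
                    continue
                diags_seen.add((chrom, g0))
                gseq = index.genome[chrom]
                s = max(0, g0)
                e = min(len(gseq), g0 + len(pseq))
                if e - s < min_aln_len:
                    continue
                garr = np.frombuffer(gseq.encode(), dtype=np.uint8)[s:e]
                matches = garr == parr[s - g0 : e - g0]
                if _max_window_at_identity(matches, min_aln_len, min_identity):
                    hits.add((strand, chrom, g0))
    # collapse near-identical diagonals at the same locus (offset jitter)
    loci: list[tuple[str, str, int]] = []
    for h in sorted(hits):
        if any(h[0] == l0 and h[1] == l1 and abs(h[2] - l2) <= 5 for l0, l1, l2 in loci):
            continue
        loci.append(h)
    return len(loci)


# ---------------------------------------------------------------- filtering

def filter_probes(candidates: list[Probe]) -> list[Probe]:
    """Set status from populated masked_fraction / hyb_hits fields.

    The mask test is applied first when both would remove a probe; filtering
    is idempotent and order-independent."""
    for p in candidates:
        if p.masked_fraction >= MASK_REMOVE_FRACTION:
            p.status = "removed_masked"
        elif p.hyb_hits > 1:
            p.status = "removed_multihit"
        else:
            p.status = "retained"
    return candidates


def target_coverage(probes: list[Probe], target: TargetGene) -> tuple[int, float]:
    """Union of retained probe intervals intersected with the target window;
    percent via the shared rounding convention (1 decimal)."""
    retained = [p.interval for p in probes if p.status == "retained"]
    covered = intersect_length(merge_intervals(retained), [target.target_interval])
    return covered, percent_rounded(covered, target.span, 1)


# ---------------------------------------------------------------- driver

def design_baits(
    genome: dict[str, str],
    targets: list[TargetGene],
    repeat_library: list[RepeatEntry],
    seed_len: int = 16,
    mask_min_len: int = 60,
    mask_max_mismatch: float = 0.10,
    hyb_min_identity: float = 0.90,
    hyb_min_aln_len: int = 80,
) -> tuple[list[Probe], pd.DataFrame]:
    """Full design: mask, tile, screen, filter.  Returns all probes (with
    status) and a per-target coverage table."""
    masks = mask_repeats(genome, repeat_library, mask_min_len, mask_max_mismatch, seed_len)
    index = GenomeSeedIndex(genome, seed_len)
    all_probes: list[Probe] = []
    rows = []
    for tg in targets:
        probes = tile_candidates(tg, genome)
        for p in probes:
            p.masked_fraction = probe_masked_fraction(p, masks[p.chrom])
            if p.masked_fraction >= MASK_REMOVE_FRACTION:
                p.hyb_hits = 1  # masked probes are removed regardless; skip the scan
            else:
                p.hyb_hits = specificity_screen(p, index, hyb_min_identity, hyb_min_aln_len)
        filter_probes(probes)
        covered, pct = target_coverage(probes, tg)
        rows.append(
            {
                "gene_id": tg.gene_id,
                "n_candidates": len(probes),
                "n_retained": sum(p.status == "retained" for p in probes),
                "covered_bp": covered,
                "covered_percent": pct,
            }
        )
        all_probes.extend(probes)
    return all_probes, pd.DataFrame(rows)


def probes_to_frame(probes: list[Probe]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in probes],
            "gene_id": [p.gene_id for p in probes],
            "chrom": [p.chrom for p in probes],
            "start": [p.genomic_start for p in probes],
            "end": [p.genomic_start + len(p.sequence) for p in probes],
            "status": [p.status for p in probes],
            "masked_fraction": [round(p.masked_fraction, 4) for p in probes],
            "hyb_hits": [p.hyb_hits for p in probes],
            "sequence": [p.sequence for p in probes],
        }
    )
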