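"""Shared domain types and reporting conventions.

Coordinate conventions used throughout the package:

* in memory everything is 0-based, half-open ``(start, end)``;
* VCF and GFF3 on disk keep their native 1-based conventions;
* positions reported relative to the translation start are printed in the
  negative-offset style, e.g. ``[-143]`` for 143 bp upstream of the A of ATG.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Optional

import numpy as np

SUBGENOMES = ("A", "B", "D")

#: IUPAC nucleotide codes and the unambiguous bases each one stands for.
IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an upper-case nucleotide string."""
    return seq.translate(_COMPLEMENT)[::-1]


def _as_decimal(x) -> Decimal:
    # accept plain and numpy scalars alike
    if float(x).is_integer():
        return Decimal(int(x))
    return Decimal(repr(float(x)))


def round_half_away(x: float, digits: int = 0) -> float:
    """Round half away from zero, matching printed report values
    (92.506 -> 93, 22.03 -> 22)."""
    q = Decimal(1).scaleb(-digits)
    return float(_as_decimal(x).quantize(q, rounding=ROUND_HALF_UP))


def percent_rounded(numerator: float, denominator: float, digits: int = 0) -> float:
    """``100 * numerator / denominator`` rounded half away from zero.

    Raises ``ValueError`` on a zero denominator.  This is the single rounding
    convention used by every percentage in every report.
    """
    if denominator == 0:
        raise ValueError("percent_rounded: denominator is zero")
    q = Decimal(100) * _as_decimal(numerator) / _as_decimal(denominator)
    return float(q.quantize(Decimal(1).scaleb(-digits), rounding=ROUND_HALF_UP))


def atg_relative(pos0: int, atg_pos0: int, strand: str = "+") -> int:
    """Offset of a 0-based genomic position relative to the A of ATG.

    Upstream positions come out negative, e.g. ``[-143]``."""
    if strand == "+":
        return pos0 - atg_pos0
    return atg_pos0 - pos0


@dataclass
class TargetGene:
    """One homoeo-allele's promoter / 5'UTR capture target.

    ``target_interval`` is the (default 1700 bp) window immediately upstream of
    the annotated start codon; ``partitions`` split it (plus the adjacent gene
    body) into promoter, five_utr, exon and intron sub-intervals.
    """

    gene_id: str
    trait_tag: str
    homoeo_group_id: str
    subgenome: str
    chrom: str
    strand: str
    atg_pos: int                      # 1-based genomic coordinate of the A of ATG
    target_interval: tuple[int, int]  # 0-based half-open
    partitions: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    arm: str = ""

    @property
    def span(self) -> int:
        return self.target_interval[1] - self.target_interval[0]

    @property
    def atg_pos0(self) -> int:
        return self.atg_pos - 1

    def cds_interval(self) -> tuple[int, int] | None:
        exons = self.partitions.get("exon") or []
        if not exons:
            return None
        return (min(s for s, _ in exons), max(e for _, e in exons))

    def analysis_window(self) -> tuple[int, int]:
        """Target plus the annotated gene body downstream of the ATG."""
        lo, hi = self.target_interval
        cds = self.cds_interval()
        if cds:
            lo, hi = min(lo, cds[0]), max(hi, cds[1])
        return lo, hi


@dataclass
class Accession:
    accession_id: str
    display_code: str
    category: str  # reference | commercial | landrace | diploid_relative | tetraploid | wild | synthetic_hexaploid
    genome_composition: tuple[str, ...]  # e.g. ("A","A","B","B","D","D")

    @property
    def ploidy(self) -> int:
        return len(self.genome_composition)

    @property
    def subgenomes(self) -> tuple[str, ...]:
        seen: list[str] = []
        for s in self.genome_composition:
            if s not in seen:
                seen.append(s)
        return tuple(seen)

    @property
    def is_hexaploid(self) -> bool:
        return self.ploidy == 6


@dataclass(frozen=True)
class Variant:
    """A single ALT allele from a VCF record (1-based position as on disk)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    allele_frequency: float
    qual: float
    depth: int

    @property
    def vtype(self) -> str:
        return "SNP" if len(self.ref_allele) == 1 and len(self.alt_allele) == 1 else "InDel"

    @property
    def indel_length(self) -> int:
        return abs(len(self.ref_allele) - len(self.alt_allele))

    @property
    def pos0(self) -> int:
        return self.pos - 1

    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class DepthProfile:
    """Per-base capture depth over one target (plus CDS) window."""

    accession_id: str
    gene_id: str
    chrom: str
    window: tuple[int, int]  # 0-based half-open genomic interval
    depths: np.ndarray       # one non-negative int per base

    def __post_init__(self) -> None:
        self.depths = np.asarray(self.depths, dtype=np.int64)
        if len(self.depths) != self.window[1] - self.window[0]:
            raise ValueError(
                f"{self.accession_id}/{self.gene_id}: depth array length "
                f"{len(self.depths)} != window length {self.window[1] - self.window[0]}"
            )
        if (self.depths < 0).any():
            raise ValueError("negative depth")


@dataclass(frozen=True)
class Motif:
    name: str
    source_species: tuple[str, ...]
    consensus: str

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name}: empty consensus")
        bad = set(self.consensus.upper()) - set(IUPAC)
        if bad:
            raise ValueError(f"motif {self.name}: invalid IUPAC characters {sorted(bad)}")


@dataclass(frozen=True)
class RepeatEntry:
    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"repeat {self.name}: empty sequence")


def merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open intervals, sorted and merged."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(i for i in intervals if i[1] > i[0]):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def intersect_length(a: list[tuple[int, int]], b: list[tuple[int, int]]) -> int:
    """Total overlap (bp) between two interval lists."""
    total = 0
    for s1, e1 in a:
        for s2, e2 in b:
            total += max(0, min(e1, e2) - max(s1, s2))
    return total


def intervals_total(intervals: list[tuple[int, int]]) -> int:
    return sum(e - s for s, e in merge_intervals(list(intervals)))
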