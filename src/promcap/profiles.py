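"""Capture profiling: captured intervals, annotation partitioning, subgenome
specificity verdicts and homozygous polymorphism frequency."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .models import (
    Accession,
    DepthProfile,
    TargetGene,
    intersect_length,
    merge_intervals,
    percent_rounded,
    round_half_away,
)

#: default mapping of related-genome labels to the subgenome their capture maps to
DEFAULT_RELATEDNESS = {
    "A": "A", "B": "B", "D": "D",
    "Am": "A",   # T. monococcum-style A relative
    "S": "B",    # Ae. speltoides-style B relative
    "U": "D",    # U genome maps mostly to D
    "Sv": "",    # unresolved: contributes no expectation
}

MIN_DEPTH = 10          # "a minimum coverage of 10 total reads"
MIN_CAPTURED_BP = 200   # a homoeologue counts as captured above this


@dataclass
class CaptureSummary:
    accession_id: str
    gene_id: str
    intervals: list[tuple[int, int]]
    promoter_bp: int = 0
    five_utr_bp: int = 0
    target_bp: int = 0
    exon_intron_bp: int = 0
    total_bp: int = 0
    max_depth: int = 0


@dataclass
class SubgenomeReport:
    accession_id: str
    captured_homoeologues: dict[str, int]
    captured_bases: dict[str, int]
    percent_by_homoeologue: dict[str, float]
    percent_by_bases: dict[str, float]
    expected_presence: set[str]
    observed_presence: set[str]
    verdict: str  # pass | warn


def captured_intervals(profile: DepthProfile, min_depth: int = MIN_DEPTH) -> list[tuple[int, int]]:
    """Maximal runs with depth >= min_depth, as genomic 0-based half-open
    intervals."""
    mask = profile.depths >= min_depth
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1) + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [len(mask)]))
    off = profile.window[0]
    return [(int(s) + off, int(e) + off) for s, e in zip(starts, ends)]


def partition_lengths(
    intervals: list[tuple[int, int]], target: TargetGene, profile: DepthProfile | None = None
) -> CaptureSummary:
    """Intersect captured intervals with the annotation partitions."""
    merged = merge_intervals(list(intervals))
    promoter = intersect_length(merged, target.partitions.get("promoter", []))
    utr = intersect_length(merged, target.partitions.get("five_utr", []))
    target_bp = intersect_length(merged, [target.target_interval])
    gene_body = target.partitions.get("exon", []) + target.partitions.get("intron", [])
    exon_intron = intersect_length(merged, gene_body)
    return CaptureSummary(
        accession_id=profile.accession_id if profile else "",
        gene_id=target.gene_id,
        intervals=merged,
        promoter_bp=promoter,
        five_utr_bp=utr,
        target_bp=target_bp,
        exon_intron_bp=exon_intron,
        total_bp=target_bp + exon_intron,
        max_depth=int(profile.depths.max()) if profile is not None and len(profile.depths) else 0,
    )


def summarize_profile(profile: DepthProfile, target: TargetGene, min_depth: int = MIN_DEPTH) -> CaptureSummary:
    return partition_lengths(captured_intervals(profile, min_depth), target, profile)


def expected_pattern(
    genome_composition: tuple[str, ...],
    relatedness: dict[str, str] | None = None,
) -> set[str]:
    """Subgenomes where capture is expected for this genome composition.

    Related labels map through the relatedness table (Am->A, S->B, U->D by
    default); an empty mapping means 'unresolved' and adds no expectation;
    an unknown label without a table entry is an error.
    """
    table = DEFAULT_RELATEDNESS if relatedness is None else relatedness
    out: set[str] = set()
    for label in genome_composition:
        if label not in table:
            raise ValueError(f"unknown subgenome label {label!r}: extend the relatedness table")
        mapped = table[label]
        if mapped:
            out.add(mapped)
    return out


def subgenome_capture_fractions(
    summaries: list[CaptureSummary],
    accession: Accession,
    targets_by_gene: dict[str, TargetGene],
    min_captured_bp: int = MIN_CAPTURED_BP,
    relatedness: dict[str, str] | None = None,
) -> SubgenomeReport:
    """Per-subgenome captured homoeologue counts and base fractions, with a
    verdict against the expected homoeologue-specificity pattern."""
    counts: dict[str, int] = {}
    bases: dict[str, int] = {}
    for s in summaries:
        sub = targets_by_gene[s.gene_id].subgenome
        bases[sub] = bases.get(sub, 0) + s.target_bp
        if s.target_bp >= min_captured_bp:
            counts[sub] = counts.get(sub, 0) + 1

    total_count = sum(counts.values())
    total_bases = sum(bases.values())
    pct_count = {
        sub: percent_rounded(n, total_count, 1) for sub, n in counts.items()
    } if total_count else {}
    pct_bases = {
        sub: percent_rounded(b, total_bases, 1) for sub, b in bases.items() if total_bases
    }

    expected = expected_pattern(accession.genome_composition, relatedness)
    observed = {sub for sub, n in counts.items() if n > 0}
    verdict = "pass" if observed and observed <= expected else "warn"
    return SubgenomeReport(
        accession_id=accession.accession_id,
        captured_homoeologues=counts,
        captured_bases=bases,
        percent_by_homoeologue=pct_count,
        percent_by_bases=pct_bases,
        expected_presence=expected,
        observed_presence=observed,
        verdict=verdict,
    )


def polymorphism_frequency(homozygous_variant_count: int, captured_bp: int) -> float:
    """Homozygous polymorphisms per kbp of captured (1x-collapsed) sequence,
    reported to one decimal."""
    if captured_bp <= 0:
        raise ValueError("captured_bp must be positive")
    return round_half_away(1000.0 * homozygous_variant_count / captured_bp, 1)


def reference_self_check(
    variants_by_gene: dict[str, list], n_genes_analysed: int
) -> dict:
    """Count targets where the reference accession unexpectedly carries
    homozygous variants against its own assembly (should be zero on synthetic
    data) plus the headline per-promoter rate."""
    with_snps = {g: vs for g, vs in variants_by_gene.items() if vs}
    snp_total = sum(len(vs) for vs in with_snps.values())
    return {
        "targets_with_snps": len(with_snps),
        "snp_total": snp_total,
        "percent_of_targets": percent_rounded(len(with_snps), n_genes_analysed, 0)
        if n_genes_analysed
        else 0.0,
        "mean_snps_per_promoter": round_half_away(snp_total / n_genes_analysed, 1)
        if n_genes_analysed
        else 0.0,
    }
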