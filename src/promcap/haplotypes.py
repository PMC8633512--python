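"""Promoter haplotype grouping from homozygous variant signatures.

A haplotype here is the exact set of homozygous SNPs and small InDels
(<= 20 bp) an accession carries across one target window.  Identical
signatures are merged into groups; a group is 'shared' if at least two
accessions of the comparison set (hexaploids by default) carry it, otherwise
'unique'; the empty signature is the reference-identical haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .models import TargetGene, Variant, percent_rounded, round_half_away

AF_EPSILON = 1e-6
MIN_QUAL = 30.0
MIN_DEPTH = 10
MAX_SIGNATURE_INDEL = 20
COMPLETENESS_FRACTION = 0.5


@dataclass
class Signature:
    gene_id: str
    accession_id: str
    variants: tuple[Variant, ...]
    complete: bool = True

    def key(self) -> tuple:
        return tuple((v.pos, v.ref_allele, v.alt_allele) for v in self.variants)


@dataclass
class HaplotypeGroup:
    gene_id: str
    label: str
    signature: tuple
    members: tuple[str, ...]
    n_snps: int
    n_indels: int
    klass: str  # shared | unique
    ref_identical: bool


@dataclass
class GeneStatus:
    accession_id: str
    gene_id: str
    status: str  # captured | missing_gene | promoter_absent_cds_present


def homozygous_filter(
    variants: list[Variant],
    af_min: float = 1.0 - AF_EPSILON,
    min_depth: int = MIN_DEPTH,
    min_qual: float = MIN_QUAL,
    max_indel: int = MAX_SIGNATURE_INDEL,
) -> list[Variant]:
    """Keep homozygous (allele frequency 1.0), well-supported small variants;
    larger InDels are the structural-variant module's business."""
    return [
        v
        for v in variants
        if v.allele_frequency >= af_min
        and v.depth >= min_depth
        and v.qual >= min_qual
        and v.indel_length <= max_indel
    ]


def build_signature(
    accession_id: str,
    target: TargetGene,
    filtered_variants: list[Variant],
    captured_target_bp: int,
    completeness_fraction: float = COMPLETENESS_FRACTION,
) -> Signature:
    """Sorted variant list restricted to the target window, flagged complete
    when enough of the target was captured to trust an empty signature."""
    t0, t1 = target.target_interval
    inside = sorted(
        (v for v in filtered_variants if v.chrom == target.chrom and t0 <= v.pos0 < t1),
        key=lambda v: (v.pos, v.alt_allele),
    )
    complete = captured_target_bp >= completeness_fraction * target.span
    return Signature(target.gene_id, accession_id, tuple(inside), complete)


def group_haplotypes(
    signatures: list[Signature],
    target: TargetGene,
    comparison_set: set[str] | None = None,
) -> list[HaplotypeGroup]:
    """Merge identical complete signatures into labelled haplotype groups.

    Labels are subgenome letter + rank: rank 1 is the reference-identical
    group when present, then descending member count, ties broken by first
    variant position then alt allele (so grouping is invariant to accession
    input order).  Incomplete signatures are excluded: absent evidence is not
    evidence of reference identity.
    """
    complete = [s for s in signatures if s.complete]
    groups: dict[tuple, list[Signature]] = {}
    for s in complete:
        groups.setdefault(s.key(), []).append(s)

    def sort_key(item: tuple[tuple, list[Signature]]):
        sig, members = item
        ref_id = 0 if len(sig) == 0 else 1
        first = sig[0] if sig else (0, "", "")
        return (ref_id, -len(members), first[0], first[2], sig)

    comparison = comparison_set if comparison_set is not None else {s.accession_id for s in complete}
    out: list[HaplotypeGroup] = []
    for rank, (sig, mem) in enumerate(sorted(groups.items(), key=sort_key), start=1):
        member_ids = tuple(sorted(s.accession_id for s in mem))
        in_comparison = sum(1 for m in member_ids if m in comparison)
        n_snps = sum(1 for p, r, a in sig if len(r) == 1 and len(a) == 1)
        out.append(
            HaplotypeGroup(
                gene_id=target.gene_id,
                label=f"{target.subgenome}{rank}",
                signature=sig,
                members=member_ids,
                n_snps=n_snps,
                n_indels=len(sig) - n_snps,
                klass="shared" if in_comparison >= 2 else "unique",
                ref_identical=len(sig) == 0,
            )
        )
    return out


def call_gene_status(
    accession_id: str,
    gene_id: str,
    promoter_bp: int,
    cds_bp: int,
    min_bp: int = 100,
) -> GeneStatus:
    """missing_gene when neither promoter nor CDS was captured; a present CDS
    with an absent promoter suggests a long deletion or replacement."""
    if promoter_bp < min_bp and cds_bp < min_bp:
        status = "missing_gene"
    elif promoter_bp < min_bp:
        status = "promoter_absent_cds_present"
    else:
        status = "captured"
    return GeneStatus(accession_id, gene_id, status)


def detect_missing_arm_clusters(
    statuses: list[GeneStatus],
    targets_by_gene: dict[str, TargetGene],
    min_genes: int = 5,
) -> list[dict]:
    """Flag accession x chromosome-arm pairs where every target on the arm is
    missing (>= min_genes of them) while the sister arm retains capture —
    the nullisomic signature."""
    by_acc_arm: dict[tuple[str, str, str], list[GeneStatus]] = {}
    for st in statuses:
        t = targets_by_gene[st.gene_id]
        by_acc_arm.setdefault((st.accession_id, t.chrom, t.arm), []).append(st)

    flags = []
    for (acc, chrom, arm), sts in sorted(by_acc_arm.items()):
        if len(sts) < min_genes:
            continue
        if not all(s.status == "missing_gene" for s in sts):
            continue
        sister = [
            s
            for (a, c, other_arm), lst in by_acc_arm.items()
            if a == acc and c == chrom and other_arm != arm
            for s in lst
        ]
        if any(s.status == "captured" for s in sister):
            flags.append(
                {
                    "accession_id": acc,
                    "chrom": chrom,
                    "arm": arm,
                    "n_missing": len(sts),
                    "genes": tuple(sorted(s.gene_id for s in sts)),
                }
            )
    return flags


def cross_ploidy_sharing(
    groups_by_gene: dict[str, list[HaplotypeGroup]],
    relative_signatures: dict[str, list[Signature]],  # accession -> signatures
    hexaploid_ids: set[str],
) -> tuple[list[dict], dict[str, float]]:
    """Introgression candidates: hexaploids carrying a relative's exact
    non-empty signature.  Empty (reference-identical) relative signatures are
    uninformative and skipped.  Also returns, per relative, the percent of
    profiled genes with at least one sharing."""
    rows: list[dict] = []
    per_relative: dict[str, tuple[int, int]] = {}
    for rel_id, sigs in relative_signatures.items():
        informative = 0
        shared_genes = 0
        for sig in sigs:
            if not sig.complete:
                continue
            informative += 1
            if not sig.variants:
                continue
            key = sig.key()
            carriers: tuple[str, ...] = ()
            for grp in groups_by_gene.get(sig.gene_id, []):
                if grp.signature == key:
                    carriers = tuple(m for m in grp.members if m in hexaploid_ids)
                    break
            if carriers:
                shared_genes += 1
                rows.append(
                    {
                        "relative": rel_id,
                        "gene_id": sig.gene_id,
                        "n_variants": len(sig.variants),
                        "hexaploid_carriers": carriers,
                    }
                )
        per_relative[rel_id] = (shared_genes, informative)
    percent = {
        rel: percent_rounded(n, total, 1) if total else 0.0
        for rel, (n, total) in per_relative.items()
    }
    return rows, percent


def summarize_haplotypes(
    groups_by_gene: dict[str, list[HaplotypeGroup]],
    n_genes: int | None = None,
    focal_accession: str | None = None,
) -> dict:
    """Headline statistics: shared/unique counts, per-accession unique
    percentages, reference-identical-only genes and the SNPs-per-haplotype
    occurrence histogram (normalised per gene)."""
    genes = list(groups_by_gene)
    n = n_genes or len(genes)
    shared_per_gene = {g: sum(1 for h in hs if h.klass == "shared") for g, hs in groups_by_gene.items()}
    unique_per_gene = {g: sum(1 for h in hs if h.klass == "unique") for g, hs in groups_by_gene.items()}

    unique_by_acc: dict[str, int] = {}
    for hs in groups_by_gene.values():
        for h in hs:
            if h.klass == "unique":
                for m in h.members:
                    unique_by_acc[m] = unique_by_acc.get(m, 0) + 1

    ref_only = sum(
        1
        for hs in groups_by_gene.values()
        if len(hs) == 1 and hs[0].ref_identical
    )

    hist: dict[int, int] = {}
    for hs in groups_by_gene.values():
        for h in hs:
            if h.signature:
                hist[h.n_snps] = hist.get(h.n_snps, 0) + 1
    hist_norm = {k: round_half_away(v / n, 3) for k, v in sorted(hist.items())} if n else {}

    out = {
        "n_genes": n,
        "shared_per_gene": shared_per_gene,
        "unique_per_gene": unique_per_gene,
        "unique_by_accession": unique_by_acc,
        "unique_percent_by_accession": {
            acc: percent_rounded(cnt, n, 0) for acc, cnt in unique_by_acc.items()
        }
        if n
        else {},
        "ref_identical_only_genes": ref_only,
        "ref_identical_only_percent": percent_rounded(ref_only, n, 0) if n else 0.0,
        "snps_per_haplotype_hist": hist_norm,
    }
    if focal_accession is not None:
        total_snps = sum(
            h.n_snps
            for hs in groups_by_gene.values()
            for h in hs
            if focal_accession in h.members
        )
        out["focal_mean_snps_per_promoter"] = round_half_away(total_snps / n, 1) if n else 0.0
    return out
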