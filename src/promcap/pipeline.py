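"""Pipeline orchestration and headline reporting.

Consumes the standard artefacts (genome FASTA, targets TSV + GFF3, per-
accession VCF and bedGraph, repeat and motif libraries) and runs
profile -> haplotypes -> structural variants -> TFBS in order, writing TSV/
JSON reports with the shared rounding conventions.  All analysis stages are
deterministic; randomness lives only in the simulator.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import pandas as pd
from Bio import Align

from . import haplotypes as hap
from . import io as pio
from . import profiles as prof
from . import sv as svmod
from . import tfbs as tfbsmod
from .models import Accession, TargetGene, percent_rounded


@dataclass
class RunConfig:
    genome: str
    gff3: str
    targets_tsv: str
    panel_tsv: str
    vcf_dir: str
    depth_dir: str
    repeats: str
    motifs: str
    outdir: str
    af_key: str = "AF"
    min_depth: int = 10
    min_qual: float = 30.0
    af_min: float = 1.0 - 1e-6
    min_captured_bp: int = 200
    completeness_fraction: float = 0.5
    status_min_bp: int = 100
    arm_min_genes: int = 5
    tfbs_flank: int = 5
    deletion_flank_depth: int = 10
    deletion_floor_depth: int = 0
    deletion_min_len: int = 21
    deletion_max_edge: int = 5
    force: bool = False


def read_panel(path: str) -> list[Accession]:
    df = pd.read_csv(path, sep="\t")
    return [
        Accession(
            row.accession_id,
            str(row.display_code),
            row.category,
            tuple(_split_composition(str(row.genome_composition))),
        )
        for row in df.itertuples(index=False)
    ]


def _split_composition(comp: str) -> list[str]:
    # "AABBDD" or "AmAm" style: an upper-case letter starts each label
    labels = []
    cur = ""
    for ch in comp:
        if ch.isupper() and cur:
            labels.append(cur)
            cur = ch
        else:
            cur += ch
    if cur:
        labels.append(cur)
    return labels


def run_pipeline(config: RunConfig) -> dict:
    """Execute every analysis stage; returns the headline report dict and
    writes all artefact tables under ``config.outdir``."""
    log: list[str] = []

    def stage(name):
        log.append(f"stage: {name}")

    for pathname in ("genome", "gff3", "targets_tsv", "panel_tsv", "repeats", "motifs"):
        p = getattr(config, pathname)
        if not os.path.exists(p):
            raise FileNotFoundError(f"config path {pathname} does not exist: {p}")

    pio.ensure_outdir(config.outdir, force=config.force)

    stage("load")
    genome = pio.read_fasta(config.genome)
    targets = pio.read_targets(config.gff3, config.targets_tsv)
    targets_by_gene = {t.gene_id: t for t in targets}
    panel = read_panel(config.panel_tsv)
    reference = next((a for a in panel if a.category == "reference"), None)
    hexaploids = {a.accession_id for a in panel if a.is_hexaploid}
    repeat_library = pio.read_repeat_library(config.repeats)
    motif_library = pio.load_motifs(config.motifs)
    windows = [(t.gene_id, t.chrom, t.analysis_window()) for t in targets]

    # ---------------- profile stage
    stage("profile")
    profiles: dict[str, dict[str, object]] = {}
    summaries: dict[str, dict[str, prof.CaptureSummary]] = {}
    variants_raw: dict[str, list] = {}
    for acc in panel:
        bg = os.path.join(config.depth_dir, f"{acc.accession_id}.bedGraph")
        vcf = os.path.join(config.vcf_dir, f"{acc.accession_id}.vcf")
        plist = pio.read_depth(bg, windows, acc.accession_id)
        profiles[acc.accession_id] = {p.gene_id: p for p in plist}
        summaries[acc.accession_id] = {
            p.gene_id: prof.summarize_profile(p, targets_by_gene[p.gene_id], config.min_depth)
            for p in plist
        }
        variants_raw[acc.accession_id] = pio.read_vcf(vcf, config.af_key) if os.path.exists(vcf) else []

    filtered = {
        acc: hap.homozygous_filter(vs, config.af_min, config.min_depth, config.min_qual)
        for acc, vs in variants_raw.items()
    }

    subgenome_reports = {
        acc.accession_id: prof.subgenome_capture_fractions(
            list(summaries[acc.accession_id].values()),
            acc,
            targets_by_gene,
            config.min_captured_bp,
        )
        for acc in panel
    }
    poly_freq = {}
    for acc in panel:
        total_bp = sum(s.total_bp for s in summaries[acc.accession_id].values())
        poly_freq[acc.accession_id] = (
            prof.polymorphism_frequency(len(filtered[acc.accession_id]), total_bp)
            if total_bp
            else float("nan")
        )

    # ---------------- haplotype stage
    stage("haplotypes")
    groups_by_gene: dict[str, list[hap.HaplotypeGroup]] = {}
    signatures_by_gene: dict[str, list[hap.Signature]] = {}
    statuses: list[hap.GeneStatus] = []
    for t in targets:
        sigs = []
        for acc in panel:
            s = summaries[acc.accession_id].get(t.gene_id)
            if s is None:
                continue
            statuses.append(
                hap.call_gene_status(
                    acc.accession_id, t.gene_id, s.promoter_bp + s.five_utr_bp,
                    s.exon_intron_bp, config.status_min_bp,
                )
            )
            sigs.append(
                hap.build_signature(
                    acc.accession_id, t, filtered[acc.accession_id], s.target_bp,
                    config.completeness_fraction,
                )
            )
        signatures_by_gene[t.gene_id] = sigs
        groups_by_gene[t.gene_id] = hap.group_haplotypes(
            [s for s in sigs if s.accession_id in hexaploids], t, hexaploids
        )

    arm_flags = hap.detect_missing_arm_clusters(statuses, targets_by_gene, config.arm_min_genes)
    relative_ids = [a.accession_id for a in panel if not a.is_hexaploid]
    relative_sigs = {
        rid: [s for sigs in signatures_by_gene.values() for s in sigs if s.accession_id == rid]
        for rid in relative_ids
    }
    sharing_rows, sharing_percent = hap.cross_ploidy_sharing(
        groups_by_gene, relative_sigs, hexaploids
    )
    hap_summary = hap.summarize_haplotypes(groups_by_gene, len(targets))

    self_check = None
    if reference is not None:
        ref_by_gene = {
            t.gene_id: [
                v
                for v in filtered[reference.accession_id]
                if v.chrom == t.chrom and t.target_interval[0] <= v.pos0 < t.target_interval[1]
            ]
            for t in targets
        }
        self_check = prof.reference_self_check(ref_by_gene, len(targets))

    # ---------------- structural-variant stage
    stage("structural_variants")
    deletions: list[svmod.DeletionEvent] = []
    truncated_rows = []
    for acc in panel:
        for gid, p in profiles[acc.accession_id].items():
            evs, trunc = svmod.detect_cliff_deletions(
                p,
                config.deletion_flank_depth,
                config.deletion_floor_depth,
                config.deletion_min_len,
                config.deletion_max_edge,
            )
            deletions.extend(evs)
            truncated_rows.extend(
                {"accession_id": acc.accession_id, "gene_id": gid, "start": s, "end": e}
                for s, e in trunc
            )

    distinct: dict[tuple[str, tuple[int, int]], list[str]] = {}
    for ev in deletions:
        distinct.setdefault((ev.chrom, ev.interval), []).append(ev.accession_id)
    repeat_rows = []
    hairpin_rows = []
    deletion_tfbs_rows = []
    for (chrom, (d0, d1)), carriers in sorted(distinct.items()):
        dseq = genome[chrom][d0:d1]
        hits, chimera = svmod.annotate_deletion_repeats(dseq, repeat_library)
        for h in hits:
            repeat_rows.append(
                {
                    "chrom": chrom, "start": d0, "end": d1,
                    "repeat": h.name,
                    "hit_start": h.query_interval[0], "hit_end": h.query_interval[1],
                    "identity": h.identity, "orientation": h.orientation,
                    "nested": h.nested, "chimera": chimera,
                    "carriers": ",".join(sorted(set(carriers))),
                }
            )
        hp = svmod.find_hairpin(dseq)
        if hp is not None:
            hairpin_rows.append(
                {
                    "chrom": chrom, "start": d0, "end": d1,
                    "stem_len": hp.stem_len, "loop_len": hp.loop_len,
                    "stem_identity": hp.stem_identity,
                }
            )
        n_tfbs, _ = tfbsmod.deletion_tfbs_content(dseq, motif_library)
        deletion_tfbs_rows.append(
            {"chrom": chrom, "start": d0, "end": d1, "n_tfbs": n_tfbs}
        )

    indel_counts = svmod.catalogue_small_indels(filtered)

    # ---------------- TFBS stage
    stage("tfbs")
    delta_rows = []
    for t in targets:
        t0, _t1 = t.target_interval
        tseq = genome[t.chrom][t.target_interval[0] : t.target_interval[1]]
        seen: set = set()
        for grp in groups_by_gene[t.gene_id]:
            for pos1, ref_allele, alt_allele in grp.signature:
                if len(ref_allele) != 1 or len(alt_allele) != 1:
                    continue  # deltas are defined for SNPs
                key = (pos1, alt_allele)
                if key in seen:
                    continue
                seen.add(key)
                off = pos1 - 1 - t0
                delta = tfbsmod.snp_window_delta(
                    tseq, off, alt_allele, motif_library,
                    config.tfbs_flank, t.gene_id, grp.label, atg_offset=t.span,
                )
                delta_rows.append(
                    {
                        "gene_id": t.gene_id,
                        "haplotype": grp.label,
                        "snp_pos_atg": delta.snp_offset_atg,
                        "n_wt_hits": len(delta.wt_hits),
                        "n_alt_hits": len(delta.alt_hits),
                        "gained": ";".join(n for n, _ in delta.gained),
                        "lost": ";".join(n for n, _ in delta.lost),
                    }
                )

    # ---------------- write artefacts
    stage("write")
    out = config.outdir

    def write(df: pd.DataFrame, name: str) -> None:
        df.to_csv(os.path.join(out, name), sep="\t", index=False)

    write(
        pd.DataFrame(
            [
                {
                    "accession_id": a,
                    "gene_id": g,
                    "promoter_bp": s.promoter_bp,
                    "five_utr_bp": s.five_utr_bp,
                    "target_bp": s.target_bp,
                    "exon_intron_bp": s.exon_intron_bp,
                    "total_bp": s.total_bp,
                    "max_depth": s.max_depth,
                }
                for a in sorted(summaries)
                for g, s in sorted(summaries[a].items())
            ]
        ),
        "profiles.tsv",
    )
    write(
        pd.DataFrame(
            [
                {
                    "accession_id": r.accession_id,
                    "subgenome": sub,
                    "captured_homoeologues": r.captured_homoeologues.get(sub, 0),
                    "captured_bases": r.captured_bases.get(sub, 0),
                    "percent_by_homoeologue": r.percent_by_homoeologue.get(sub, 0.0),
                    "percent_by_bases": r.percent_by_bases.get(sub, 0.0),
                    "expected": sub in r.expected_presence,
                    "verdict": r.verdict,
                }
                for r in subgenome_reports.values()
                for sub in sorted(set(r.captured_homoeologues) | r.expected_presence)
            ]
        ),
        "subgenomes.tsv",
    )
    write(
        pd.DataFrame(
            [
                {
                    "gene_id": g.gene_id,
                    "label": g.label,
                    "class": g.klass,
                    "ref_identical": g.ref_identical,
                    "n_members": len(g.members),
                    "n_snps": g.n_snps,
                    "n_indels": g.n_indels,
                    "members": ",".join(g.members),
                    "signature": ";".join(f"{p}:{r}>{a}" for p, r, a in g.signature) or ".",
                }
                for gid in sorted(groups_by_gene)
                for g in groups_by_gene[gid]
            ]
        ),
        "haplotype_groups.tsv",
    )
    write(
        pd.DataFrame([{"accession_id": s.accession_id, "gene_id": s.gene_id, "status": s.status} for s in statuses]),
        "gene_status.tsv",
    )
    write(pd.DataFrame(arm_flags or [{}]), "arm_flags.tsv")
    write(
        pd.DataFrame(
            [
                {**row, "hexaploid_carriers": ",".join(row["hexaploid_carriers"])}
                for row in sharing_rows
            ]
            or [{}]
        ),
        "introgression.tsv",
    )
    write(
        pd.DataFrame(
            [
                {
                    "accession_id": ev.accession_id,
                    "gene_id": ev.gene_id,
                    "chrom": ev.chrom,
                    "start": ev.interval[0],
                    "end": ev.interval[1],
                    "size": ev.size,
                    "class": ev.klass,
                }
                for ev in deletions
            ]
            or [{}]
        ),
        "deletions.tsv",
    )
    write(pd.DataFrame(truncated_rows or [{}]), "truncated_coverage.tsv")
    write(pd.DataFrame(repeat_rows or [{}]), "repeat_hits.tsv")
    write(pd.DataFrame(hairpin_rows or [{}]), "hairpins.tsv")
    write(pd.DataFrame(deletion_tfbs_rows or [{}]), "deletion_tfbs.tsv")
    write(pd.DataFrame(delta_rows or [{}]), "tfbs_deltas.tsv")

    report = {
        "n_targets": len(targets),
        "n_accessions": len(panel),
        "polymorphism_frequency_per_kbp": poly_freq,
        "subgenome_verdicts": {a: r.verdict for a, r in subgenome_reports.items()},
        "haplotype_summary": {
            k: v
            for k, v in hap_summary.items()
            if k not in ("shared_per_gene", "unique_per_gene")
        },
        "reference_self_check": self_check,
        "introgression_percent_by_relative": sharing_percent,
        "n_deletions": len(deletions),
        "n_distinct_deletions": len(distinct),
        "snp_indel_counts": {a: list(c) for a, c in indel_counts.items()},
        "thresholds": {
            "min_depth": config.min_depth,
            "min_qual": config.min_qual,
            "af_min": config.af_min,
            "min_captured_bp": config.min_captured_bp,
            "completeness_fraction": config.completeness_fraction,
            "deletion_min_len": config.deletion_min_len,
            "tfbs_flank": config.tfbs_flank,
        },
    }
    with open(os.path.join(out, "summary.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    log.append("thresholds: " + json.dumps(report["thresholds"], sort_keys=True))
    with open(os.path.join(out, "run.log"), "w") as fh:
        fh.write("\n".join(log) + "\n")
    return report


# ------------------------------------------------------------- roll-ups

def trait_rollup(targets: list[TargetGene]) -> pd.DataFrame:
    """Per-trait unique gene counts, homoeologue totals and subgenome
    composition classes, with a grand-total row."""
    rows: dict[str, dict] = {}
    groups: dict[tuple[str, str], set[str]] = {}
    for t in targets:
        groups.setdefault((t.trait_tag, t.homoeo_group_id), set()).add(t.subgenome)
    for (trait, _grp), subs in groups.items():
        r = rows.setdefault(
            trait, {"trait": trait, "unique_genes": 0, "homoeologues": 0}
        )
        r["unique_genes"] += 1
        r["homoeologues"] += len(subs)
        comp = "".join(sorted(subs))
        r[comp] = r.get(comp, 0) + 1
    df = pd.DataFrame(sorted(rows.values(), key=lambda r: r["trait"])).fillna(0)
    num = df.select_dtypes("number")
    total = {c: int(num[c].sum()) for c in num.columns}
    total["trait"] = "Total"
    return pd.concat([df, pd.DataFrame([total])], ignore_index=True).fillna(0)


def column_totals(df: pd.DataFrame) -> dict:
    """Sum every numeric column of a per-trait table (grand-total row)."""
    num = df.select_dtypes("number")
    return {c: num[c].sum() for c in num.columns}


# ------------------------------------------------------------- identity

def pairwise_target_identity(seq_a: str, seq_b: str) -> tuple[int, int, float]:
    """Global alignment (unit scores, gap -2) identity between two target
    sequences: (identities, aligned length incl. gaps, rounded percent)."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1
    aligner.mismatch_score = -1
    aligner.open_gap_score = -2
    aligner.extend_gap_score = -2
    alignment = aligner.align(seq_a, seq_b)[0]
    a_blocks, b_blocks = alignment.aligned
    identities = 0
    aligned_cols = 0
    prev_a = prev_b = 0
    for (as_, ae), (bs, be) in zip(a_blocks, b_blocks):
        aligned_cols += (as_ - prev_a) + (bs - prev_b)  # gap columns
        aligned_cols += ae - as_
        identities += sum(1 for x, y in zip(seq_a[as_:ae], seq_b[bs:be]) if x == y)
        prev_a, prev_b = ae, be
    aligned_cols += (len(seq_a) - prev_a) + (len(seq_b) - prev_b)
    return identities, aligned_cols, percent_rounded(identities, aligned_cols, 0)
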