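"""Readers and writers for the standard on-disk formats.

FASTA via Biopython, GFF3 via gffutils, VCF via cyvcf2; targets/bedGraph are
simple TSV conventions documented here.  Everything read is converted to the
package's 0-based half-open in-memory coordinates.
"""

from __future__ import annotations

import os
from typing import Iterable, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .models import (
    DepthProfile,
    Motif,
    RepeatEntry,
    TargetGene,
    Variant,
    merge_intervals,
)

TARGET_COLUMNS = [
    "gene_id", "trait_tag", "homoeo_group_id", "subgenome",
    "chrom", "strand", "atg_pos", "span", "arm",
]


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}


def write_fasta(path: str, sequences: dict[str, str] | Iterable[tuple[str, str]]) -> None:
    items = sequences.items() if isinstance(sequences, dict) else sequences
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in items]
    SeqIO.write(records, path, "fasta")


def read_repeat_library(path: str) -> list[RepeatEntry]:
    return [RepeatEntry(name, seq) for name, seq in read_fasta(path).items()]


# ---------------------------------------------------------------- targets

def target_interval_from_atg(atg_pos: int, span: int, strand: str) -> tuple[int, int]:
    """0-based half-open target window immediately upstream of the start codon.

    For a plus-strand gene with the A of ATG at 1-based ``atg_pos`` the window
    is ``[atg_pos - 1 - span, atg_pos - 1)``; on the minus strand the upstream
    region lies genomically downstream: ``[atg_pos, atg_pos + span)``.
    """
    atg0 = atg_pos - 1
    if strand == "+":
        return (atg0 - span, atg0)
    if strand == "-":
        return (atg0 + 1, atg0 + 1 + span)
    raise ValueError(f"bad strand {strand!r}")


def read_targets(gff3_path: str, targets_tsv_path: str) -> list[TargetGene]:
    """Load target definitions and derive annotation partitions from GFF3.

    The TSV carries gene_id, trait_tag, homoeo_group_id, subgenome, chrom,
    strand, atg_pos (1-based), span and arm.  Partitions: ``five_utr`` and
    ``exon``/``intron`` come from the GFF3 gene model; ``promoter`` is the part
    of the target window not annotated as 5'UTR.
    """
    df = pd.read_csv(targets_tsv_path, sep="\t", dtype={"arm": str})
    missing_cols = set(TARGET_COLUMNS) - set(df.columns)
    if missing_cols:
        raise ValueError(f"targets TSV missing columns: {sorted(missing_cols)}")

    db = gffutils.create_db(
        gff3_path, ":memory:", merge_strategy="create_unique", keep_order=True
    )
    known = {f.id for f in db.features_of_type("gene")}

    targets: list[TargetGene] = []
    for row in df.itertuples(index=False):
        if row.gene_id not in known:
            raise ValueError(f"gene model missing from GFF3: {row.gene_id}")
        span = int(row.span)
        atg_pos = int(row.atg_pos)
        if span <= 0:
            raise ValueError(f"{row.gene_id}: malformed target span {span}")
        interval = target_interval_from_atg(atg_pos, span, row.strand)

        utr: list[tuple[int, int]] = []
        exon: list[tuple[int, int]] = []
        for feat in db.children(row.gene_id):
            iv = (feat.start - 1, feat.end)  # GFF3 is 1-based inclusive
            if feat.featuretype == "five_prime_UTR":
                utr.append(iv)
            elif feat.featuretype in ("CDS", "exon"):
                exon.append(iv)
        utr = merge_intervals(utr)
        exon = merge_intervals(exon)
        # promoter = target window minus annotated 5'UTR
        promoter = _subtract(interval, utr)
        intron = _gaps(exon)
        targets.append(
            TargetGene(
                gene_id=row.gene_id,
                trait_tag=row.trait_tag,
                homoeo_group_id=row.homoeo_group_id,
                subgenome=row.subgenome,
                chrom=row.chrom,
                strand=row.strand,
                atg_pos=atg_pos,
                target_interval=interval,
                partitions={
                    "promoter": promoter,
                    "five_utr": [iv for iv in utr if _overlaps(iv, interval)],
                    "exon": exon,
                    "intron": intron,
                },
                arm=str(row.arm),
            )
        )
    targets.sort(key=lambda t: (t.chrom, t.target_interval[0], t.gene_id))
    return targets


def write_targets_tsv(path: str, rows: Sequence[dict]) -> None:
    pd.DataFrame(rows, columns=TARGET_COLUMNS).to_csv(path, sep="\t", index=False)


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return max(a[0], b[0]) < min(a[1], b[1])


def _subtract(interval: tuple[int, int], minus: list[tuple[int, int]]) -> list[tuple[int, int]]:
    pieces = [interval]
    for ms, me in merge_intervals(minus):
        nxt: list[tuple[int, int]] = []
        for s, e in pieces:
            if me <= s or ms >= e:
                nxt.append((s, e))
                continue
            if s < ms:
                nxt.append((s, ms))
            if me < e:
                nxt.append((me, e))
        pieces = nxt
    return pieces


def _gaps(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    ivs = merge_intervals(intervals)
    return [(ivs[i][1], ivs[i + 1][0]) for i in range(len(ivs) - 1)]


# ---------------------------------------------------------------- VCF

VCF_META = """##fileformat=VCFv4.2
##INFO=<ID=AF,Number=A,Type=Float,Description="Allele frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth">
"""
VCF_COLUMNS = "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"


def read_vcf(path: str, af_key: str = "AF") -> list[Variant]:
    """One Variant per ALT allele.  The homozygosity field key is configurable
    (Freebayes-style callers differ); a record without it is an error naming
    the key."""
    out: list[Variant] = []
    for rec in VCF(path):
        af = rec.INFO.get(af_key)
        if af is None:
            raise ValueError(
                f"{path}: record {rec.CHROM}:{rec.POS} lacks INFO field {af_key!r}"
            )
        afs = af if isinstance(af, tuple) else (af,)
        depth = int(rec.INFO.get("DP") or 0)
        qual = float(rec.QUAL) if rec.QUAL is not None else 0.0
        for i, alt in enumerate(rec.ALT):
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref_allele=rec.REF,
                    alt_allele=alt,
                    allele_frequency=float(afs[min(i, len(afs) - 1)]),
                    qual=qual,
                    depth=depth,
                )
            )
    return out


def write_vcf(
    path: str,
    variants: Sequence[Variant],
    contigs: dict[str, int] | None = None,
) -> None:
    with open(path, "w") as fh:
        fh.write(VCF_META)
        for chrom, length in (contigs or {}).items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write(VCF_COLUMNS)
        for v in sorted(variants, key=lambda v: (v.chrom, v.pos, v.alt_allele)):
            fh.write(
                f"{v.chrom}\t{v.pos}\t.\t{v.ref_allele}\t{v.alt_allele}\t"
                f"{v.qual:g}\t.\tAF={v.allele_frequency:g};DP={v.depth}\n"
            )


# ---------------------------------------------------------------- bedGraph

def read_depth(
    path: str,
    windows: Sequence[tuple[str, str, tuple[int, int]]],
    accession_id: str = "",
) -> list[DepthProfile]:
    """Expand a bedGraph to per-base depth over each configured window.

    ``windows`` is a sequence of ``(gene_id, chrom, (start, end))``; bases not
    covered by any bedGraph interval are 0; intervals outside every window are
    ignored; two intervals assigning different depths to the same base are a
    contradiction and raise.
    """
    arrays = {
        gid: np.zeros(win[1] - win[0], dtype=np.int64) for gid, _, win in windows
    }
    assigned = {gid: np.zeros(win[1] - win[0], dtype=bool) for gid, _, win in windows}
    by_chrom: dict[str, list[tuple[str, tuple[int, int]]]] = {}
    for gid, chrom, win in windows:
        by_chrom.setdefault(chrom, []).append((gid, win))

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("track", "#")):
                continue
            chrom, s, e, d = line.split("\t")
            s, e, d = int(s), int(e), int(float(d))
            for gid, (ws, we) in by_chrom.get(chrom, []):
                lo, hi = max(s, ws), min(e, we)
                if lo >= hi:
                    continue
                sl = slice(lo - ws, hi - ws)
                clash = assigned[gid][sl] & (arrays[gid][sl] != d)
                if clash.any():
                    raise ValueError(
                        f"{path}: contradictory depth at {chrom}:{lo + int(np.argmax(clash))}"
                    )
                arrays[gid][sl] = d
                assigned[gid][sl] = True
    return [
        DepthProfile(accession_id, gid, chrom, win, arrays[gid])
        for gid, chrom, win in windows
    ]


def write_bedgraph(path: str, depth_by_chrom: dict[str, np.ndarray]) -> None:
    """Write non-zero constant-depth runs, 0-based half-open."""
    with open(path, "w") as fh:
        for chrom in sorted(depth_by_chrom):
            d = np.asarray(depth_by_chrom[chrom])
            if d.size == 0:
                continue
            change = np.flatnonzero(np.diff(d)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [d.size]))
            for s, e in zip(starts, ends):
                if d[s] > 0:
                    fh.write(f"{chrom}\t{s}\t{e}\t{int(d[s])}\n")


# ---------------------------------------------------------------- motifs

def load_motifs(path: str) -> list[Motif]:
    """TSV with name, species, IUPAC consensus; duplicate (name, consensus)
    rows are collapsed with the species list retained."""
    df = pd.read_csv(path, sep="\t")
    need = {"name", "species", "consensus"}
    if not need <= set(df.columns):
        raise ValueError(f"motif TSV must have columns {sorted(need)}")
    grouped: dict[tuple[str, str], list[str]] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        cons = str(row.consensus).upper()
        from .models import IUPAC

        bad = set(cons) - set(IUPAC)
        if bad:
            raise ValueError(
                f"motif row {i + 1} ({row.name}): invalid IUPAC characters {sorted(bad)}"
            )
        grouped.setdefault((str(row.name), cons), []).append(str(row.species))
    return [
        Motif(name=name, source_species=tuple(dict.fromkeys(sp)), consensus=cons)
        for (name, cons), sp in grouped.items()
    ]


def ensure_outdir(outdir: str, force: bool = False) -> None:
    if os.path.isdir(outdir) and os.listdir(outdir) and not force:
        raise FileExistsError(f"output directory {outdir} exists and is not empty (use force)")
    os.makedirs(outdir, exist_ok=True)
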