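"""Synthetic allopolyploid capture panel with planted truth.

Builds a toy hexaploid reference (one pseudo-chromosome per subgenome, one
homoeologous gene copy per subgenome and group), plants shared/unique promoter
haplotypes with geometric SNP-count structure, introgressed signatures, a
chimeric transposable element (a MITE with terminal inverted repeats nested
inside a larger element) whose excision produces cliff-edge coverage gaps, and
a nullisomic accession missing every target on one chromosome arm.  A simple
hybridization-capture model (probe-fragment mismatch fraction over the
overlap) then turns the panel into per-accession VCF + bedGraph files, so the
whole downstream pipeline is testable without any external data.

Homoeologue divergence is laid down as evenly spaced substitutions (grid
``1/divergence`` with +/-1 bp jitter, distinct alleles per derived copy) so
that every probe-sized window carries close to the nominal divergence and no
two homoeologues share a perfect 16-mer; capture specificity at
``tau < divergence`` is then deterministic rather than asymptotic.
"""

from __future__ import annotations

import hashlib
import os
from bisect import bisect_left, insort
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import io as pio
from .baits import Probe
from .models import Accession, RepeatEntry, TargetGene, Variant, revcomp

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: related-genome labels mapped to the base subgenome whose chromosome they carry
RELATED_SUBGENOME = {"A": "A", "B": "B", "D": "D", "Am": "A", "S": "B", "U": "D"}


@dataclass
class CaptureConfig:
    fragment_len_range: tuple[int, int] = (400, 600)  # sheared-fragment size selection
    min_overlap: int = 50
    max_mismatch_fraction: float = 0.10  # tau: probe-fragment mismatch tolerance
    mean_fragments_per_target: int = 200


@dataclass
class PanelSimConfig:
    seed: int = 0
    n_homoeo_groups: int = 30
    subgenomes: tuple[str, ...] = ("A", "B", "D")
    homoeologue_divergence: float = 0.08
    target_span: int = 1700
    five_utr_len: int = 235
    cds_len: int = 500
    flank: int = 700
    spacer: int = 800
    n_commercial: int = 8
    n_landrace: int = 3
    n_diploid: int = 2          # one A-related, one D relative by default
    n_tetraploid: int = 1
    haplotype_snp_geometric_p: float = 0.5
    relative_snp_geometric_p: float = 0.25
    n_shared_haplotypes_per_target: tuple[int, int] = (1, 3)
    snp_max_per_haplotype: int = 30
    snp_min_spacing: int = 40
    indel_prob: float = 0.25
    mite_spec: tuple[int, int] = (25, 100)  # terminal-inverted-repeat stem, loop
    outer_te_len: int = 362                 # chimera total = outer + MITE = 512 bp
    introgression_spec: list[tuple[str, list[str], list[str]]] | None = None
    deletion_spec: list[tuple[str, str, list[str]]] | None = None
    nullisomic: tuple[str, str, str] | None = None  # (accession, subgenome, arm)
    capture: CaptureConfig = field(default_factory=CaptureConfig)


@dataclass
class SimTruth:
    """Planted ground truth, all in reference coordinates (signatures use the
    VCF-style 1-based anchored representation)."""

    haplotypes: dict[str, list[tuple[tuple, tuple[str, ...]]]]  # gene -> [(sig, members)]
    signature_map: dict[str, dict[str, tuple]]                  # gene -> accession -> sig
    introgressions: list[dict]
    deletions: list[dict]
    missing_genes: list[tuple[str, str]]                        # (accession, gene)
    nullisomic: tuple[str, str, str] | None


@dataclass
class ReferenceBundle:
    sequences: dict[str, str]
    targets: list[TargetGene]
    gene_info: dict[str, tuple[int, str]]          # gene_id -> (group, subgenome)
    locus_start: dict[tuple[int, str], int]
    insertions: dict[tuple[int, str], list[tuple[int, int]]]  # ancestral (pos, len)
    repeat_library: list[RepeatEntry]
    chimera: dict
    config: PanelSimConfig

    def chrom_of(self, subgenome: str) -> str:
        return f"chr{subgenome}"

    def target_of(self, gene_id: str) -> TargetGene:
        return next(t for t in self.targets if t.gene_id == gene_id)

    def local_to_ancestral(self, group: int, sub: str, local: int) -> int | None:
        for pos, L in self.insertions.get((group, sub), []):
            if local < pos:
                continue
            if local < pos + L:
                return None  # inside the insertion
            local -= L
        return local

    def ancestral_to_local(self, group: int, sub: str, anc: int) -> int:
        for pos, L in self.insertions.get((group, sub), []):
            if anc >= pos:
                anc += L
        return anc


def _rand_seq_arr(rng: np.random.Generator, n: int) -> np.ndarray:
    return BASES[rng.integers(0, 4, n)]


def _arr_to_str(a: np.ndarray) -> str:
    return a.tobytes().decode()


def arm_of_group(group: int, n_groups: int) -> str:
    return "S" if group < n_groups // 2 else "L"


def build_mite(rng: np.random.Generator, stem: int, loop: int) -> str:
    """A MITE-style element: terminal inverted repeats around a loop, so
    revcomp(seq[:stem]) == seq[-stem:]."""
    s = _arr_to_str(_rand_seq_arr(rng, stem))
    mid = _arr_to_str(_rand_seq_arr(rng, loop))
    return s + mid + revcomp(s)


# ===================================================================== genome

def build_reference_genome(config: PanelSimConfig) -> ReferenceBundle:
    """Deterministic synthetic reference + annotation targets + repeats."""
    rng = np.random.default_rng(config.seed)
    c = config
    if not (0 < c.homoeologue_divergence <= 0.25):
        raise ValueError("homoeologue_divergence must be in (0, 0.25]")

    stem, loop = c.mite_spec
    inner = build_mite(rng, stem, loop)
    outer = _arr_to_str(_rand_seq_arr(rng, c.outer_te_len))
    insert_at = int(round(c.outer_te_len * 0.69))  # MITE sits in the outer element's 3' part
    chimera_seq = outer[:insert_at] + inner + outer[insert_at:]
    repeat_library = [
        RepeatEntry("DTH_Syn_Coeus", outer),
        RepeatEntry("DTC_Syn_Jorge", inner),
    ]

    del_group = c.n_homoeo_groups * 2 // 3  # long arm by default
    del_sub = "B" if "B" in c.subgenomes else c.subgenomes[-1]
    te_anc_pos = c.flank + 800  # inside the promoter, well inside the target window
    insertions: dict[tuple[int, str], list[tuple[int, int]]] = {
        (del_group, del_sub): [(te_anc_pos, len(chimera_seq))]
    }

    step = 1.0 / c.homoeologue_divergence
    locus_base_len = 2 * c.flank + c.target_span + c.cds_len

    chrom_parts: dict[str, list[np.ndarray]] = {f"chr{s}": [] for s in c.subgenomes}
    locus_start: dict[tuple[int, str], int] = {}
    offsets = {chrom: 0 for chrom in chrom_parts}

    def append(chrom: str, arr: np.ndarray) -> None:
        chrom_parts[chrom].append(arr)
        offsets[chrom] += len(arr)

    inner_arr = np.frombuffer(inner.encode(), dtype=np.uint8)
    gene_rows: list[dict] = []
    gene_info: dict[str, tuple[int, str]] = {}

    for chrom in chrom_parts:
        append(chrom, _rand_seq_arr(rng, c.spacer))

    for g in range(c.n_homoeo_groups):
        ancestral = _rand_seq_arr(rng, locus_base_len)
        n_sub = int(locus_base_len * c.homoeologue_divergence)
        grid = np.unique(
            np.clip(
                np.round(np.arange(n_sub) * step + rng.integers(-1, 2, n_sub)).astype(int),
                0,
                locus_base_len - 1,
            )
        )
        # at each grid position a permutation of the three non-ancestral bases:
        # derived copy i takes entry i-1, so all copies differ pairwise there
        alt_tables = np.empty((len(grid), 3), dtype=np.uint8)
        for k, p in enumerate(grid):
            others = np.array([b for b in BASES if b != ancestral[p]], dtype=np.uint8)
            alt_tables[k] = rng.permutation(others)

        for si, s in enumerate(c.subgenomes):
            copy = ancestral.copy()
            if si > 0:
                copy[grid] = alt_tables[:, (si - 1) % 3]
            if (g, s) in insertions:
                pos, _L = insertions[(g, s)][0]
                ch = np.frombuffer(chimera_seq.encode(), dtype=np.uint8)
                copy = np.concatenate([copy[:pos], ch, copy[pos:]])
            chrom = f"chr{s}"
            locus_start[(g, s)] = offsets[chrom]
            append(chrom, copy)
            sp = _rand_seq_arr(rng, c.spacer)
            if s == c.subgenomes[0] and g in (1, 3):
                # two extra genomic MITE copies (hit-count truth: 3 loci total)
                sp = np.concatenate([sp[:100], inner_arr, sp[100:]])
            append(chrom, sp)

            shift = sum(L for _p, L in insertions.get((g, s), []))
            atg_local = c.flank + c.target_span + shift
            gene_id = f"G{g:03d}{s}"
            gene_info[gene_id] = (g, s)
            gene_rows.append(
                {
                    "gene_id": gene_id,
                    "trait_tag": f"T{g % 10 + 1}",
                    "homoeo_group_id": f"HG{g:03d}",
                    "subgenome": s,
                    "chrom": chrom,
                    "strand": "+",
                    "atg_pos": locus_start[(g, s)] + atg_local + 1,
                    "span": c.target_span,
                    "arm": arm_of_group(g, c.n_homoeo_groups),
                }
            )

    sequences = {chrom: _arr_to_str(np.concatenate(parts)) for chrom, parts in chrom_parts.items()}
    targets = sorted(
        (_make_target(row, c) for row in gene_rows),
        key=lambda t: (t.chrom, t.target_interval[0]),
    )

    for g in range(c.n_homoeo_groups):  # homoeologue copies must actually differ
        seen = set()
        for s in c.subgenomes:
            t0 = locus_start[(g, s)] + c.flank
            seen.add(sequences[f"chr{s}"][t0 : t0 + 200])
        if len(seen) < len(c.subgenomes):
            raise ValueError(f"homoeologue promoters identical in group {g}: divergence too low")

    chim_start = locus_start[(del_group, del_sub)] + te_anc_pos
    chimera = {
        "group": del_group,
        "subgenome": del_sub,
        "gene_id": f"G{del_group:03d}{del_sub}",
        "chrom": f"chr{del_sub}",
        "interval": (chim_start, chim_start + len(chimera_seq)),
        "inner_interval": (chim_start + insert_at, chim_start + insert_at + len(inner)),
        "outer_name": "DTH_Syn_Coeus",
        "inner_name": "DTC_Syn_Jorge",
        "sequence": chimera_seq,
    }
    return ReferenceBundle(
        sequences=sequences,
        targets=targets,
        gene_info=gene_info,
        locus_start=locus_start,
        insertions=insertions,
        repeat_library=repeat_library,
        chimera=chimera,
        config=c,
    )


def _make_target(row: dict, c: PanelSimConfig) -> TargetGene:
    atg0 = row["atg_pos"] - 1
    t0 = atg0 - c.target_span
    return TargetGene(
        gene_id=row["gene_id"],
        trait_tag=row["trait_tag"],
        homoeo_group_id=row["homoeo_group_id"],
        subgenome=row["subgenome"],
        chrom=row["chrom"],
        strand=row["strand"],
        atg_pos=row["atg_pos"],
        target_interval=(t0, atg0),
        partitions={
            "promoter": [(t0, atg0 - c.five_utr_len)],
            "five_utr": [(atg0 - c.five_utr_len, atg0)],
            "exon": [(atg0, atg0 + c.cds_len)],
            "intron": [],
        },
        arm=row["arm"],
    )


# ===================================================================== panel

def default_panel(config: PanelSimConfig) -> list[Accession]:
    panel = [Accession("CS_REF", "CS", "reference", ("A", "A", "B", "B", "D", "D"))]
    for i in range(config.n_commercial):
        panel.append(Accession(f"H{i + 1:02d}", f"C{i + 1}", "commercial", ("A", "A", "B", "B", "D", "D")))
    for i in range(config.n_landrace):
        panel.append(Accession(f"W{601 + i}", f"W{601 + i}", "landrace", ("A", "A", "B", "B", "D", "D")))
    diploid_kinds = [("M", ("Am", "Am")), ("ENT", ("D", "D")), ("ASP", ("S", "S"))]
    for i in range(config.n_diploid):
        name, comp = diploid_kinds[i % len(diploid_kinds)]
        panel.append(Accession(f"{name}{i + 1:02d}", f"{name}{i + 1}", "diploid_relative", comp))
    for i in range(config.n_tetraploid):
        panel.append(Accession(f"K{i + 1:02d}", f"K{i + 1}", "tetraploid", ("A", "A", "B", "B")))
    return panel


def accession_chroms(acc: Accession) -> list[str]:
    seen: list[str] = []
    for label in acc.genome_composition:
        base = RELATED_SUBGENOME.get(label)
        if base is None:
            continue
        chrom = f"chr{base}"
        if chrom not in seen:
            seen.append(chrom)
    return seen


def _sig_key(edits: tuple, ref_seq: str) -> tuple:
    """VCF-style (pos1, ref, alt) tuples for a set of planted edits."""
    out = []
    for e in edits:
        if e[0] == "SNP":
            _, p, ref, alt = e
            out.append((p + 1, ref, alt))
        else:
            _, d0, d1 = e
            out.append((d0, ref_seq[d0 - 1 : d1], ref_seq[d0 - 1]))
    return tuple(sorted(out))


class _SigSampler:
    """Draws non-overlapping planted signatures inside one target window."""

    def __init__(self, ref, target: TargetGene, rng: np.random.Generator):
        self.rng = rng
        self.ref_seq = ref.sequences[target.chrom]
        c = ref.config
        t0, t1 = target.target_interval
        margin = 30
        excluded: list[tuple[int, int]] = []
        chim = ref.chimera
        if chim["gene_id"] == target.gene_id:
            ci = chim["interval"]
            excluded.append((ci[0] - 60, ci[1] + 60))
        allowed = []
        for p in range(t0 + margin, t1 - margin):
            if not any(s <= p < e for s, e in excluded):
                allowed.append(p)
        self.allowed = np.array(allowed)
        self.spacing = c.snp_min_spacing
        self.max_snps = c.snp_max_per_haplotype
        self.indel_prob = c.indel_prob

    def _pick_positions(self, n: int, taken: list[int]) -> list[int]:
        got: list[int] = []
        order = self.rng.permutation(len(self.allowed))
        occupied = sorted(taken)
        for idx in order:
            p = int(self.allowed[idx])
            j = bisect_left(occupied, p)
            near = []
            if j > 0:
                near.append(occupied[j - 1])
            if j < len(occupied):
                near.append(occupied[j])
            if all(abs(p - q) >= self.spacing for q in near):
                got.append(p)
                insort(occupied, p)
                if len(got) == n:
                    break
        return got

    def _geom(self, p: float) -> int:
        while True:
            n = int(self.rng.geometric(p))
            if n <= self.max_snps:
                return n

    def draw(self, p_geom: float, with_indel: bool | None = None) -> tuple:
        n = self._geom(p_geom)
        positions = self._pick_positions(n, [])
        edits = []
        for p in positions:
            ref_b = self.ref_seq[p]
            alts = [b for b in "ACGT" if b != ref_b]
            edits.append(("SNP", p, ref_b, alts[self.rng.integers(0, 3)]))
        if with_indel is None:
            with_indel = self.rng.random() < self.indel_prob
        if with_indel:
            extra = self._pick_positions(1, [e[1] for e in edits])
            if extra:
                d0 = extra[0]
                L = int(self.rng.integers(3, 9))
                edits.append(("DEL", d0, d0 + L))
        return tuple(sorted(edits, key=lambda e: e[1]))

    def related(self, core: tuple, existing: set) -> tuple:
        """A signature sharing the core plus/minus 1-2 SNPs."""
        for _ in range(30):
            sig = list(core)
            for _op in range(int(self.rng.integers(1, 3))):
                snps = [e for e in sig if e[0] == "SNP"]
                if snps and (self.rng.random() < 0.5 or len(sig) >= self.max_snps):
                    sig.remove(snps[self.rng.integers(0, len(snps))])
                else:
                    taken = [e[1] for e in sig]
                    pos = self._pick_positions(1, taken)
                    if pos:
                        p = pos[0]
                        ref_b = self.ref_seq[p]
                        alts = [b for b in "ACGT" if b != ref_b]
                        sig.append(("SNP", p, ref_b, alts[self.rng.integers(0, 3)]))
            key = tuple(sorted(sig, key=lambda e: e[1]))
            if key and key not in existing:
                return key
        return self.draw(0.5, with_indel=False)


def simulate_panel(
    ref: ReferenceBundle, config: PanelSimConfig | None = None
) -> tuple[list[Accession], dict, SimTruth]:
    """Plant haplotypes, introgressions, deletions and the nullisomic arm.

    Returns (panel, edits, truth) where ``edits`` maps accession ->
    chromosome -> list of non-overlapping edits in reference coordinates.
    """
    c = config or ref.config
    rng = np.random.default_rng(c.seed + 1)
    panel = default_panel(c)
    by_id = {a.accession_id: a for a in panel}
    hexaploids = [a.accession_id for a in panel if a.is_hexaploid and a.category != "reference"]
    relatives = [a for a in panel if a.category in ("diploid_relative", "tetraploid", "wild")]

    commercial = [a.accession_id for a in panel if a.category == "commercial"]
    landrace = [a.accession_id for a in panel if a.category == "landrace"]

    chim = ref.chimera
    if c.deletion_spec is None:
        carriers = (commercial[:4] + landrace[:1])[:5]
        deletion_spec = [(chim["outer_name"], chim["gene_id"], carriers)]
    else:
        deletion_spec = c.deletion_spec

    if c.introgression_spec is None and relatives:
        donor = relatives[0].accession_id
        donor_subs = {RELATED_SUBGENOME[l] for l in by_id[donor].genome_composition}
        cand = [
            t.gene_id
            for t in ref.targets
            if t.subgenome in donor_subs and t.gene_id != chim["gene_id"]
        ][3:5]
        recips = commercial[4:6] if len(commercial) >= 6 else commercial[:2]
        introgression_spec = [(donor, cand, recips)] if cand and len(recips) >= 2 else []
    else:
        introgression_spec = c.introgression_spec or []

    if c.nullisomic is None:
        null_acc = commercial[6] if len(commercial) > 6 else (landrace[-1] if landrace else None)
        nullisomic = (null_acc, "D", "S") if null_acc else None
    else:
        nullisomic = c.nullisomic

    sig_map: dict[str, dict[str, tuple]] = {}
    for target in ref.targets:
        sampler = _SigSampler(ref, target, rng)
        gene_sigs: dict[str, tuple] = {}
        existing: set = set()

        pool = list(rng.permutation(hexaploids))
        lo, hi = c.n_shared_haplotypes_per_target
        k = int(rng.integers(lo, hi + 1))
        n_unique = int(rng.integers(0, 3))
        core: tuple | None = None
        for j in range(k):
            if len(pool) < 2:
                break
            sig = sampler.draw(c.haplotype_snp_geometric_p) if j == 0 else sampler.related(core, existing)
            if not sig or sig in existing:
                continue
            existing.add(sig)
            if j == 0:
                core = sig
            size = min(2 + int(rng.geometric(0.6)) - 1, len(pool))
            members, pool = pool[:size], pool[size:]
            if len(members) < 2:  # cannot be shared; return to pool
                pool = members + pool
                break
            for m in members:
                gene_sigs[m] = sig
        for _ in range(n_unique):
            if not pool:
                break
            sig = sampler.related(core, existing) if core else sampler.draw(c.haplotype_snp_geometric_p)
            if not sig or sig in existing:
                continue
            existing.add(sig)
            gene_sigs[pool.pop()] = sig
        # remaining hexaploids and the reference carry the reference sequence
        gene_sigs["CS_REF"] = ()
        for m in pool:
            gene_sigs[m] = ()

        for rel in relatives:
            subs = {RELATED_SUBGENOME.get(l) for l in rel.genome_composition}
            if target.subgenome in subs:
                sig = sampler.draw(c.relative_snp_geometric_p)
                gene_sigs[rel.accession_id] = sig or ()
        sig_map[target.gene_id] = gene_sigs

    # introgression: recipients take the donor's exact signature
    introgressions = []
    for donor, gene_ids, recipients in introgression_spec:
        for gid in gene_ids:
            donor_sig = sig_map[gid].get(donor)
            if donor_sig is None:
                raise ValueError(f"introgression donor {donor} has no profile at {gid}")
            for r in recipients:
                if f"chr{ref.target_of(gid).subgenome}" not in accession_chroms(by_id[r]):
                    raise ValueError(f"recipient {r} lacks subgenome of {gid}")
                sig_map[gid][r] = donor_sig
            introgressions.append({"donor": donor, "gene_id": gid, "recipients": tuple(recipients)})

    # nullisomic arm: drop every target on that arm for the chosen accession
    missing_genes: list[tuple[str, str]] = []
    null_gene_ids: set[str] = set()
    if nullisomic:
        acc_id, sub, arm = nullisomic
        for t in ref.targets:
            if t.subgenome == sub and t.arm == arm:
                null_gene_ids.add(t.gene_id)
                missing_genes.append((acc_id, t.gene_id))
                sig_map[t.gene_id].pop(acc_id, None)

    # materialise per-accession edits from the signature map
    edits: dict[str, dict[str, list]] = {
        a.accession_id: {chrom: [] for chrom in accession_chroms(a)} for a in panel
    }
    for target in ref.targets:
        chrom = target.chrom
        for acc_id, sig in sig_map[target.gene_id].items():
            if chrom in edits[acc_id]:
                edits[acc_id][chrom].extend(sig)

    deletions = []
    for _rep_name, gene_id, carriers in deletion_spec:
        interval = chim["interval"] if gene_id == chim["gene_id"] else None
        if interval is None:
            raise ValueError(f"deletion_spec names unknown planted element at {gene_id}")
        for acc_id in carriers:
            edits[acc_id][chim["chrom"]].append(("DEL", interval[0], interval[1]))
        deletions.append(
            {
                "gene_id": gene_id,
                "chrom": chim["chrom"],
                "interval": interval,
                "carriers": tuple(carriers),
                "repeats": (chim["outer_name"], chim["inner_name"]),
                "inner_interval": chim["inner_interval"],
            }
        )

    if nullisomic:
        acc_id, sub, arm = nullisomic
        chrom = f"chr{sub}"
        for t in ref.targets:
            if t.gene_id in null_gene_ids:
                lo, hi = t.analysis_window()
                edits[acc_id][chrom].append(("DEL", lo, hi))

    for acc_edits in edits.values():
        for chrom in acc_edits:
            acc_edits[chrom].sort(key=lambda e: e[1])

    truth_haps: dict[str, list[tuple[tuple, tuple[str, ...]]]] = {}
    for target in ref.targets:
        ref_seq = ref.sequences[target.chrom]
        grouping: dict[tuple, list[str]] = {}
        for acc_id, sig in sig_map[target.gene_id].items():
            if not by_id[acc_id].is_hexaploid:
                continue
            grouping.setdefault(_sig_key(sig, ref_seq), []).append(acc_id)
        truth_haps[target.gene_id] = [
            (sig, tuple(sorted(members))) for sig, members in grouping.items()
        ]

    truth = SimTruth(
        haplotypes=truth_haps,
        signature_map={
            gid: {acc: _sig_key(sig, ref.sequences[ref.target_of(gid).chrom]) for acc, sig in accs.items()}
            for gid, accs in sig_map.items()
        },
        introgressions=introgressions,
        deletions=deletions,
        missing_genes=missing_genes,
        nullisomic=nullisomic,
    )
    return panel, edits, truth


# ===================================================================== capture

def apply_edits(ref_seq: str, chrom_edits: list) -> tuple[np.ndarray, np.ndarray]:
    """Accession sequence and the accession->reference position map.

    Returns (acc_arr, acc2ref): deleted reference bases simply do not appear;
    SNPs substitute in place.  Edits must be sorted and non-overlapping.
    """
    arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8).copy()
    keep = np.ones(len(arr), dtype=bool)
    for e in chrom_edits:
        if e[0] == "SNP":
            _, p, _ref, alt = e
            arr[p] = ord(alt)
        elif e[0] == "DEL":
            _, d0, d1 = e
            keep[d0:d1] = False
    acc2ref = np.flatnonzero(keep)
    return arr[keep], acc2ref


@dataclass
class CaptureResult:
    depth: dict[str, dict[str, np.ndarray]]          # accession -> chrom -> per-base depth
    variants: dict[str, list[Variant]]               # accession -> VCF records
    cross_captured_bases: dict[str, int]             # bases captured only by cross-subgenome probes
    captured_fragments: dict[str, int]


def simulate_capture(
    ref: ReferenceBundle,
    panel: list[Accession],
    edits: dict[str, dict[str, list]],
    probes: list[Probe],
    config: PanelSimConfig | None = None,
    min_vcf_depth: int = 10,
) -> CaptureResult:
    """Fragment capture model.

    Fragments (uniform starts, lengths in ``fragment_len_range``) are drawn
    around each target locus of each chromosome the accession carries.  A
    fragment is captured iff it overlaps a probe binding site by at least
    ``min_overlap`` bp with a mismatch fraction over the overlap of at most
    ``tau``.  Captured fragments pile into reference-coordinate depth: bases
    deleted in the accession get no coverage (cliff-edge gaps).  Homozygous
    variants (allele frequency 1.0) are emitted for every small edit whose
    site reaches ``min_vcf_depth``.
    """
    c = config or ref.config
    cap = c.capture
    tau = cap.max_mismatch_fraction
    rng = np.random.default_rng(c.seed + 2)
    retained = [p for p in probes if p.status in ("retained", "")]

    # group probes by homoeo-group; precompute ancestral offsets
    probes_by_group: dict[int, list[tuple[Probe, str, int]]] = {}
    for p in retained:
        g, s = ref.gene_info[p.gene_id]
        local = p.genomic_start - ref.locus_start[(g, s)]
        probes_by_group.setdefault(g, []).append((p, s, local))

    flen_lo, flen_hi = cap.fragment_len_range
    ext = flen_hi
    result = CaptureResult(depth={}, variants={}, cross_captured_bases={}, captured_fragments={})

    for acc in panel:
        acc_depth: dict[str, np.ndarray] = {}
        acc_vars: list[Variant] = []
        cross_bases = 0
        n_captured = 0
        for chrom in accession_chroms(acc):
            sub = chrom[3:]
            ref_seq = ref.sequences[chrom]
            chrom_edits = edits.get(acc.accession_id, {}).get(chrom, [])
            acc_arr, acc2ref = apply_edits(ref_seq, chrom_edits)
            ref2acc = np.full(len(ref_seq), -1, dtype=np.int64)
            ref2acc[acc2ref] = np.arange(len(acc2ref))
            depth_acc = np.zeros(len(acc_arr), dtype=np.int64)
            ref_arr = np.frombuffer(ref_seq.encode(), dtype=np.uint8)

            # ---- binding sites per homoeo-group on this chromosome
            sites_by_group: dict[int, list[tuple[int, int, np.ndarray, bool]]] = {}
            for g, plist in probes_by_group.items():
                if (g, sub) not in ref.locus_start:
                    continue
                sites = []
                for probe, s_p, local in plist:
                    if s_p == sub:
                        r0 = probe.genomic_start
                    else:
                        a0 = ref.local_to_ancestral(g, s_p, local)
                        a1 = ref.local_to_ancestral(g, s_p, local + len(probe.sequence))
                        if a0 is None or a1 is None or a1 - a0 != len(probe.sequence):
                            continue  # probe straddles an insertion: no clean homolog
                        h0 = ref.ancestral_to_local(g, sub, a0)
                        h1 = ref.ancestral_to_local(g, sub, a1)
                        if h1 - h0 != len(probe.sequence):
                            continue
                        r0 = ref.locus_start[(g, sub)] + h0
                    r1 = r0 + len(probe.sequence)
                    if r0 < 0 or r1 > len(ref_seq):
                        continue
                    apos = ref2acc[r0:r1]
                    present = apos >= 0
                    if not present.any():
                        continue
                    parr = np.frombuffer(probe.sequence.encode(), dtype=np.uint8)
                    match = np.zeros(len(parr), dtype=bool)
                    match[present] = acc_arr[apos[present]] == parr[present]
                    mism_frac = 1.0 - match.sum() / len(parr)
                    if mism_frac > tau:
                        continue
                    a_lo = int(apos[present].min())
                    a_hi = int(apos[present].max()) + 1
                    site_match = np.zeros(a_hi - a_lo, dtype=bool)
                    site_match[apos[present] - a_lo] = match[present]
                    sites.append((a_lo, a_hi, site_match, s_p == sub))
                if sites:
                    sites_by_group[g] = sites

            # ---- fragments around each locus present on this chromosome
            for g in range(c.n_homoeo_groups):
                if (g, sub) not in ref.locus_start:
                    continue
                l0 = ref.locus_start[(g, sub)]
                l1 = l0 + 2 * c.flank + c.target_span + c.cds_len + sum(
                    L for _p, L in ref.insertions.get((g, sub), [])
                )
                # map locus bounds into accession coordinates (nearest kept base)
                kept = ref2acc[l0:l1]
                kept = kept[kept >= 0]
                if kept.size == 0:
                    continue
                reg_lo, reg_hi = int(kept.min()), int(kept.max()) + 1
                # scale the draw so the expected number of fragments
                # overlapping the target equals mean_fragments_per_target
                region_len = (reg_hi - reg_lo) + 2 * ext
                mean_flen = (flen_lo + flen_hi) / 2
                n_frag = int(
                    round(
                        cap.mean_fragments_per_target
                        * region_len
                        / (c.target_span + mean_flen)
                    )
                )
                starts = rng.integers(max(0, reg_lo - ext), max(1, reg_hi), n_frag)
                lens = rng.integers(flen_lo, flen_hi + 1, n_frag)
                f0s = starts
                f1s = np.minimum(starts + lens, len(acc_arr))

                sites = sites_by_group.get(g, [])
                if not sites:
                    continue
                captured = np.zeros(n_frag, dtype=bool)
                cross = np.zeros(n_frag, dtype=bool)
                for s_lo, s_hi, smatch, is_own in sites:
                    o_lo = np.maximum(f0s, s_lo)
                    o_hi = np.minimum(f1s, s_hi)
                    ov = o_hi - o_lo
                    cand = np.flatnonzero(ov >= cap.min_overlap)
                    if cand.size == 0:
                        continue
                    pre = np.concatenate(([0], np.cumsum(~smatch)))
                    mism = pre[o_hi[cand] - s_lo] - pre[o_lo[cand] - s_lo]
                    ok = cand[mism <= tau * ov[cand]]
                    captured[ok] = True
                    if not is_own:
                        cross[ok] = True
                for i in np.flatnonzero(captured):
                    depth_acc[f0s[i] : f1s[i]] += 1
                    if cross[i]:
                        cross_bases += int(f1s[i] - f0s[i])
                n_captured += int(captured.sum())

            depth_ref = np.zeros(len(ref_seq), dtype=np.int64)
            depth_ref[acc2ref] = depth_acc
            acc_depth[chrom] = depth_ref

            # ---- homozygous variant records for small edits with coverage
            for e in chrom_edits:
                if e[0] == "SNP":
                    _, p, ref_b, alt = e
                    if depth_ref[p] >= min_vcf_depth:
                        acc_vars.append(
                            Variant(chrom, p + 1, ref_b, alt, 1.0, 60.0, int(depth_ref[p]))
                        )
                elif e[0] == "DEL" and (e[2] - e[1]) <= 20:
                    _, d0, d1 = e
                    if d0 >= 1 and depth_ref[d0 - 1] >= min_vcf_depth:
                        acc_vars.append(
                            Variant(
                                chrom,
                                d0,
                                ref_seq[d0 - 1 : d1],
                                ref_seq[d0 - 1],
                                1.0,
                                60.0,
                                int(depth_ref[d0 - 1]),
                            )
                        )
        result.depth[acc.accession_id] = acc_depth
        result.variants[acc.accession_id] = acc_vars
        result.cross_captured_bases[acc.accession_id] = cross_bases
        result.captured_fragments[acc.accession_id] = n_captured
    return result


# ===================================================================== output

def write_gff3(path: str, ref: ReferenceBundle) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in sorted(ref.targets, key=lambda t: (t.chrom, t.atg_pos)):
            atg0 = t.atg_pos0
            utr = t.partitions["five_utr"][0]
            cds = t.partitions["exon"][0]
            lo = min(utr[0], cds[0]) + 1
            hi = max(utr[1], cds[1])
            fh.write(
                f"{t.chrom}\tpromcap\tgene\t{lo}\t{hi}\t.\t{t.strand}\t.\tID={t.gene_id}\n"
            )
            fh.write(
                f"{t.chrom}\tpromcap\tfive_prime_UTR\t{utr[0] + 1}\t{utr[1]}\t.\t{t.strand}\t.\t"
                f"ID={t.gene_id}.utr;Parent={t.gene_id}\n"
            )
            fh.write(
                f"{t.chrom}\tpromcap\tCDS\t{cds[0] + 1}\t{cds[1]}\t.\t{t.strand}\t0\t"
                f"ID={t.gene_id}.cds;Parent={t.gene_id}\n"
            )


def write_panel(
    outdir: str,
    ref: ReferenceBundle,
    panel: list[Accession],
    truth: SimTruth,
    capture: CaptureResult,
    force: bool = False,
) -> pd.DataFrame:
    """Write every artefact (FASTA/GFF3/TSV/VCF/bedGraph + truth tables) and
    return a manifest with SHA-256 checksums."""
    pio.ensure_outdir(outdir, force=force)
    os.makedirs(os.path.join(outdir, "vcf"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "depth"), exist_ok=True)
    os.makedirs(os.path.join(outdir, "truth"), exist_ok=True)

    files: list[str] = []

    def out(rel: str) -> str:
        files.append(rel)
        return os.path.join(outdir, rel)

    pio.write_fasta(out("genome.fa"), ref.sequences)
    write_gff3(out("annotation.gff3"), ref)
    pio.write_targets_tsv(
        out("targets.tsv"),
        [
            {
                "gene_id": t.gene_id,
                "trait_tag": t.trait_tag,
                "homoeo_group_id": t.homoeo_group_id,
                "subgenome": t.subgenome,
                "chrom": t.chrom,
                "strand": t.strand,
                "atg_pos": t.atg_pos,
                "span": t.span,
                "arm": t.arm,
            }
            for t in ref.targets
        ],
    )
    pio.write_fasta(out("repeats.fa"), {r.name: r.sequence for r in ref.repeat_library})

    contigs = {chrom: len(seq) for chrom, seq in sorted(ref.sequences.items())}
    for acc in panel:
        pio.write_vcf(
            out(f"vcf/{acc.accession_id}.vcf"), capture.variants[acc.accession_id], contigs
        )
        pio.write_bedgraph(
            out(f"depth/{acc.accession_id}.bedGraph"), capture.depth[acc.accession_id]
        )

    pd.DataFrame(
        {
            "accession_id": [a.accession_id for a in panel],
            "display_code": [a.display_code for a in panel],
            "category": [a.category for a in panel],
            "genome_composition": ["".join(a.genome_composition) for a in panel],
        }
    ).to_csv(out("truth/panel.tsv"), sep="\t", index=False)

    hap_rows = []
    for gid, groups in truth.haplotypes.items():
        for sig, members in groups:
            hap_rows.append(
                {
                    "gene_id": gid,
                    "signature": ";".join(f"{p}:{r}>{a}" for p, r, a in sig) or ".",
                    "n_members": len(members),
                    "members": ",".join(members),
                }
            )
    pd.DataFrame(hap_rows).to_csv(out("truth/haplotypes.tsv"), sep="\t", index=False)
    pd.DataFrame(truth.introgressions or [{}]).to_csv(
        out("truth/introgressions.tsv"), sep="\t", index=False
    )
    pd.DataFrame(
        [
            {
                "gene_id": d["gene_id"],
                "chrom": d["chrom"],
                "start": d["interval"][0],
                "end": d["interval"][1],
                "carriers": ",".join(d["carriers"]),
                "repeats": ",".join(d["repeats"]),
            }
            for d in truth.deletions
        ]
    ).to_csv(out("truth/deletions.tsv"), sep="\t", index=False)
    pd.DataFrame(truth.missing_genes, columns=["accession_id", "gene_id"]).to_csv(
        out("truth/missing_genes.tsv"), sep="\t", index=False
    )

    rows = []
    for rel in files:
        with open(os.path.join(outdir, rel), "rb") as fh:
            digest = hashlib.sha256(fh.read()).hexdigest()
        rows.append({"file": rel, "sha256": digest})
    manifest = pd.DataFrame(rows)
    manifest.to_csv(os.path.join(outdir, "manifest.tsv"), sep="\t", index=False)
    return manifest


def simulate_all(config: PanelSimConfig, probes: list[Probe] | None = None):
    """Convenience driver: genome -> panel -> (optional external probes) ->
    capture.  Returns (ref, panel, edits, truth, capture_result, probes)."""
    from .baits import design_baits

    ref = build_reference_genome(config)
    panel, edits, truth = simulate_panel(ref, config)
    if probes is None:
        probes, _cov = design_baits(ref.sequences, ref.targets, ref.repeat_library)
    capture = simulate_capture(ref, panel, edits, probes, config)
    return ref, panel, edits, truth, capture, probes
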