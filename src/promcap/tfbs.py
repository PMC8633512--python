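"""IUPAC consensus motif scanning with 100%-match semantics, SNP gain/loss
deltas in an 11-bp window, and deletion motif content.

Only exact matches under IUPAC expansion count; an N in the scanned sequence
never matches.  Hits with the same motif name over the same matched interval
(species duplications, palindromic double-hits) are collapsed to one."""

from __future__ import annotations

import re
from dataclasses import dataclass

from .models import IUPAC, Motif, revcomp


@dataclass(frozen=True)
class TFBSHit:
    name: str
    source_species: tuple[str, ...]
    position: int  # 0-based start within the scanned sequence (forward coords)
    length: int
    strand: str
    matched: str  # forward-strand sequence of the matched interval

    @property
    def interval(self) -> tuple[int, int]:
        return (self.position, self.position + self.length)


@dataclass
class TFBSDelta:
    gene_id: str
    accession_or_haplotype: str
    snp_offset_atg: int  # negative offset relative to the ATG, e.g. -143
    wt_hits: list[TFBSHit]
    alt_hits: list[TFBSHit]
    gained: list[tuple[str, str]]  # (motif name, matched substring)
    lost: list[tuple[str, str]]


def _pattern(consensus: str) -> re.Pattern:
    # character classes over unambiguous bases only: a sequence N never matches
    parts = [f"[{IUPAC[c]}]" if len(IUPAC[c]) > 1 else IUPAC[c] for c in consensus.upper()]
    return re.compile("(?=(" + "".join(parts) + "))")


def scan(seq: str, library: list[Motif], both_strands: bool = True) -> list[TFBSHit]:
    """All exact IUPAC matches of every motif; overlapping occurrences are
    found; duplicates by (name, matched interval) are collapsed."""
    seq = seq.upper()
    n = len(seq)
    hits: dict[tuple[str, int, int], TFBSHit] = {}
    for motif in library:
        pat = _pattern(motif.consensus)
        L = len(motif.consensus)
        for m in pat.finditer(seq):
            p = m.start()
            key = (motif.name, p, p + L)
            if key not in hits:
                hits[key] = TFBSHit(motif.name, motif.source_species, p, L, "+", seq[p : p + L])
        if both_strands:
            rc = revcomp(seq)
            for m in pat.finditer(rc):
                p_rc = m.start()
                p = n - p_rc - L
                key = (motif.name, p, p + L)
                if key not in hits:
                    hits[key] = TFBSHit(
                        motif.name, motif.source_species, p, L, "-", seq[p : p + L]
                    )
    return sorted(hits.values(), key=lambda h: (h.position, h.name))


def snp_window_delta(
    target_seq: str,
    snp_offset: int,
    alt_base: str,
    library: list[Motif],
    flank: int = 5,
    gene_id: str = "",
    label: str = "",
    atg_offset: int | None = None,
    both_strands: bool = True,
) -> TFBSDelta:
    """Scan the +/-flank window (11 bp at the default) around a SNP in its
    reference and variant form; gained/lost are set differences keyed by
    (motif name, matched substring).  The window is truncated at the sequence
    edges rather than shifted."""
    lo = max(0, snp_offset - flank)
    hi = min(len(target_seq), snp_offset + flank + 1)
    wt = target_seq[lo:hi]
    alt = wt[: snp_offset - lo] + alt_base + wt[snp_offset - lo + 1 :]
    wt_hits = scan(wt, library, both_strands)
    alt_hits = scan(alt, library, both_strands)
    wt_keys = {(h.name, h.matched) for h in wt_hits}
    alt_keys = {(h.name, h.matched) for h in alt_hits}
    return TFBSDelta(
        gene_id=gene_id,
        accession_or_haplotype=label,
        snp_offset_atg=(snp_offset - atg_offset) if atg_offset is not None else snp_offset,
        wt_hits=wt_hits,
        alt_hits=alt_hits,
        gained=sorted(alt_keys - wt_keys),
        lost=sorted(wt_keys - alt_keys),
    )


def deletion_tfbs_content(
    deletion_seq: str, library: list[Motif], both_strands: bool = True
) -> tuple[int, list[TFBSHit]]:
    """Deduped motif hits within a deleted reference span; zero is a valid
    (and in practice common) outcome."""
    hits = scan(deletion_seq, library, both_strands) if deletion_seq else []
    return len(hits), hits
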