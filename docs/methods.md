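# Methods

This note documents the models and conventions behind `promcap`: what each
stage assumes, the parameters that matter, what the synthetic panel does and
does not emulate, and the numerical choices made where the design was open.

## Coordinates and rounding

Internally everything is 0-based half-open; VCF and GFF3 keep their 1-based
disk conventions; positions quoted relative to the start codon use the
negative-offset style (`[-143]` = 143 bp upstream of the A of ATG).  Every
percentage and rate in every report goes through one rounding convention —
half away from zero at the stated number of decimals (`percent_rounded`,
`round_half_away`) — so that printed values like 22% (200/908) or 93%
(1617/1748) are exact and reproducible.

## Bait design

Targets are the 1700 bp upstream of the annotated ATG (promoter + 5'UTR).
Candidates are 120-nt probes tiled every 60 nt, anchored at the target start:
`floor((L-120)/60)+1` candidates for a span-L target.  No end-anchored probe
is added, so a full 1700 bp tiling covers 1680 bp (98.8%); the 20 bp shortfall
is a documented consequence of the anchoring convention, and coverage
percentages report it honestly.

Repeat soft-masking replaces cross_match with seeded exact-match extension:
any genomic window sharing a 16-mer with a library element (either
orientation) is compared ungapped along that diagonal, and the widest window
of length ≥ 60 bp with mismatch fraction ≤ 0.10 is masked.  Probes with
masked fraction ≥ 0.25 are removed.

A *strong hybridization site* in the specificity screen is a locus that
(i) shares at least one exact `seed_len = 16` mer with the probe and
(ii) aligns ungapped over ≥ 80 bp at identity ≥ 0.90.  The seed requirement
models hybridization nucleation — a duplex cannot zip up without a short
perfectly paired core — and is what separates homoeologues (≈ 92% identity
but, at 8% evenly spread divergence, never 16 consecutive matches) from true
multi-copy sequence.  Probes with more than one site are removed; the mask
test takes precedence when both apply.  All thresholds are configurable
because the original workflow is proprietary.

## Synthetic panel

The generator's defaults are the study conditions, not tuning knobs:

| parameter | default | meaning |
|---|---|---|
| `n_homoeo_groups` | 30 | homoeologous triads (desk-scale stand-in for 459 genes) |
| `homoeologue_divergence` | 0.08 | substitution fraction between subgenome copies |
| `target_span` | 1700 bp | promoter + 5'UTR window upstream of the ATG |
| `five_utr_len` / `cds_len` | 235 / 500 bp | annotation geometry per gene |
| `haplotype_snp_geometric_p` | 0.5 | SNPs per haplotype ~ geometric, truncated 1–30 |
| `relative_snp_geometric_p` | 0.25 | denser signatures for diploid/tetraploid relatives |
| `snp_min_spacing` | 40 bp | keeps ≤ 3 planted SNPs per 120-nt probe window |
| `mite_spec` | (25, 100) | terminal-inverted-repeat stem and loop of the inner MITE |
| `outer_te_len` | 362 bp | outer element; chimera (outer + nested MITE) = 512 bp |
| fragment lengths | 400–600 bp | sheared-fragment size selection |
| `min_overlap` | 50 bp | probe–fragment overlap needed for capture (free parameter; nothing in the underlying chemistry pins it, so it is exposed and documented) |
| `max_mismatch_fraction` (tau) | 0.10 | mismatch tolerance over the probe–fragment overlap |
| `mean_fragments_per_target` | 200 | expected fragments overlapping each target |

Design points worth knowing:

* **Divergence placement.**  Substitutions between homoeologues sit on an
  evenly spaced grid (spacing `1/divergence`, ±1 bp jitter, alleles distinct
  across the derived copies).  An i.i.d. substitution model leaves a few
  percent of probe-sized windows under-diverged, which would make capture
  specificity a statistical statement; the grid makes every window carry
  close to nominal divergence, so `tau < divergence` implies zero
  cross-subgenome capture deterministically, and no two homoeologues share a
  16-mer seed.  Real wheat divergence is clustered, not even — the grid is a
  deliberate idealization that makes the specificity contract testable.
* **Fragments per target.**  Fragments are drawn uniformly over each locus
  ±600 bp; the draw count is scaled by `region/(target + mean fragment)` so
  that the *expected number of fragments overlapping the target* equals the
  parameter.  At the default this yields interior depths of ~40–60× and
  maximum depths below ~85× for hexaploids, inside the plausibly observed
  10–120× range, with a negligible probability of any base in a captured
  region dipping below the 10× call filter.
* **Capture model.**  A fragment is captured iff it overlaps a probe binding
  site by ≥ `min_overlap` with mismatch fraction over the overlap ≤ tau.
  Binding sites are evaluated for every probe against every homologous locus
  (per-base mismatch arrays through the accession's edits); bases deleted in
  the accession receive no coverage (hard cliff edges), inserted bases are
  invisible, matching how depth behaves in reference coordinates.
* **Relatives.**  Diploid/tetraploid accessions are modelled as the reference
  subgenome plus denser planted signatures rather than genome-wide
  divergence; this keeps every planted fact exactly recoverable while still
  separating their polymorphism rates (~2–2.5 kbp⁻¹) from hexaploids'
  (~0.6–0.8 kbp⁻¹).  True relatives also diverge in InDels and rearrangements
  the simulator does not model.
* **Homozygosity.**  All planted edits are emitted at allele frequency 1.0;
  heterozygous simulation is out of scope.  Variant records carry AF/DP/QUAL
  so the analysis-side filters (AF ≥ 1−10⁻⁶ to absorb float representation,
  DP ≥ 10, Q ≥ 30, InDel ≤ 20 bp) exercise their thresholds.
* **Nullisomic scenario.**  One accession loses every target locus on one
  chromosome arm (deletion of the windows, not a modelled translocation);
  the downstream inference only needs all-arm absence.

Passing tests on this panel show the pipeline's logic is correct under a
clean capture model; they do not show robustness to mapping artefacts,
duplicate reads, heterozygosity, uneven GC, or reference errors, none of
which the simulator emulates.

## Analysis conventions

* **Captured** means depth ≥ 10 (`min coverage 10`); a homoeologue counts as
  captured at ≥ 200 bp of target at that depth (stray-fragment guard; the
  underlying filter value is not pinned by anything stronger, so it is
  configurable).  Subgenome percentages are reported both by homoeologue
  count and by bases, since either reading of a capture-fraction figure is
  defensible; percentages by bases sum to 100 ± 0.1 whenever anything is
  captured.
* **Expected patterns** map related genomes through a configurable table
  (A^m → A, S → B, U → D; S^v unresolved, contributing no expectation).
* **Polymorphism frequency** divides homozygous variant count by the
  accession's total captured bp collapsed to 1×, reported per kbp to one
  decimal.
* **Haplotype grouping** uses only *complete* signatures (≥ 50% of the
  target captured): an accession with incomplete capture is excluded from
  that gene's grouping rather than mistaken for reference-identical.  Group
  labels are subgenome letter + rank: reference-identical first, then
  descending member count, ties by first variant position then alt allele —
  an invented but deterministic convention, so grouping is invariant to
  input order.  Shared/unique is evaluated over hexaploids; relatives are
  overlaid afterwards.  Introgression candidacy requires identity of the
  full signature (InDels included) — the stricter of the two readings — and
  empty relative signatures are uninformative and skipped.
* **Deletions** are runs of depth ≤ 0 spanning ≥ 21 bp (events ≤ 20 bp belong
  to the VCF) with ≥ 10× flanks reached within 5 bp; runs touching the window
  edge cannot display both cliffs and are reported separately as truncated
  (promoter-absent candidates).  The 21 bp boundary and the large/mid class
  split at 100 bp are labels, not different algorithms.  Both the VCF route
  (≤ 20 bp) and the coverage route emit events with a source column, since
  how 21–99 bp events split between callers is data-dependent.
* **Repeat annotation** is Smith–Waterman with unit scores (match +1,
  mismatch −1, gap −2), iterated: after each accepted local hit (≥ 30 bp,
  identity ≥ 0.8) the matched segment is masked and the element re-aligned,
  so an element interrupted by an insertion yields one hit per arm.  Nesting
  is judged against each element's merged span — the inner element of a
  chimera lies strictly inside the outer element's span even though it lies
  between the outer's two arm hits.  The chimera flag requires ≥ 2 distinct
  elements jointly covering ≥ 80% of the deletion.
* **Hairpins** maximize matches − mismatches over all arm pairs with stem
  ≥ 20 bp, loop ≤ 200 bp and stem identity ≥ 0.8, walking anti-diagonals of
  the complement-match matrix with prefix sums; ties break leftmost arm
  start, then longest stem, then smallest loop.  An exhaustive
  all-anchor-pairs oracle checks it on sequences ≤ 300 bp.
* **TFBS matching** is exact IUPAC consensus expansion (an N in the scanned
  sequence never matches), both strands by default (strand policy is not
  dictated by anything, so it is a flag).  Duplicate hits collapse by
  (motif name, matched interval) — the stricter reading of "without species
  duplications" — and SNP deltas compare (name, matched substring) sets over
  the ±5 bp window, truncated at target edges rather than shifted.

## Problem sizes

The shipped study runs 30 triads × 15 accessions (~500 kb genome, ~2 400
probes, ~270 k fragments); tests and the acceptance script complete in well
under a minute each.  These sizes are the package's chosen desk-scale study
conditions; every algorithm is linear or near-linear in targets × accessions
and has been run unchanged at several times this size.

## Known limitations

No read-level simulation (FASTQ, sequencing error, duplicates), no
heterozygous genotypes, no phasing or pedigree inference, no
melting-temperature modelling in bait design, no insertion reconstruction
(insertions relative to the reference are invisible in depth space), and no
claim that predicted TFBS are functional — they are exact string matches, a
starting point for experimental work, not evidence of binding.
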