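# Methods

## The problem and the model

A canonical spidroin gene encodes a tri-partite protein: a nonrepetitive
N-terminal domain (~100–150 aa), a long tandem-repeat array emitted from a
small motif vocabulary, and a nonrepetitive C-terminal domain. The package
treats each part as its own inference problem — terminal domains are found
by homology, the repeat array by self-similarity, and the full gene model by
combining both on the genome — and ships a generator that simulates all
three so every stage can be scored against ground truth.

## Synthetic study conditions

The generator's defaults are the study conditions under which all recovery
numbers are measured.

* **Repeat grammar.** One repeat unit is a concatenation of motif emissions
  — poly-A runs (length uniform on 4–10), (GA)n arrays (2–5 dyads), GGX,
  GPGXX, XQQ and single spacer residues — drawn by per-family weights until
  the unit reaches 24–40 aa (rejection-sampled on overshoot). Families are
  caricatures of the published repeat chemistries: MaSp1 GGX/poly-A rich,
  MaSp2 GPGXX rich, MiSp (GA)n rich, FlSp nearly pure GPGXX, the remaining
  families serine/glutamine-dominated. A gene's array is one unit repeated
  in tandem (`n_units` uniform on 16–24) — real arrays are strongly
  homogenised — and the whole protein then receives independent point
  substitutions at rate 0.02.
* **Terminal domains.** The library is synthetic: one N and one C domain
  per family (110–140 aa, helix-former-enriched composition), generated
  once from a fixed seed and shipped as `data/terminal_domains.fasta`.
  Nothing is copied from real spidroins, so the package needs no downloads;
  the trade-off is that cross-family homology (real NTDs are related) is
  absent, which makes typing easier than in real data.
* **Default bundle.** 10 spidroins across 8 families plus 50 decoys
  (half with a collagen-like G-X-Y low-complexity block — a realistic
  repeat-detection confounder; rejection sampling keeps every decoy below
  40% identity to any library terminus) on 3 chromosomes, random strands,
  intergenic flanks 0.8–2 kb (compact by design: anchor search is quadratic
  in sequence length and the geometry, not the spacing, is what is tested).
  Corruption: one dragline gene gets a single 1-nt indel placed in the
  middle third of its repeat span (so repair operates in the regime the
  grammar can guide); one gets a C-terminal truncation at the repeat
  midpoint (truth completeness becomes "partial"). Genes are single-exon
  CDSs with uniform synonymous codon usage; the bundled proteome is
  annotation-style (translation of the embedded, possibly corrupted CDS up
  to the first stop).
* **Grouped bundle.** 13 genes arranged as the three-group layout
  (4 MaSp1a–c + MaSp2e, 4 MaSp2a–d, 5 MiSp a–e on three chromosomes) used
  to test chromosome grouping.
* **Expression design.** Baseline FPKM ~ LogNormal(ln 10, 1) per gene and
  sample; 7 gland tissues plus the Ma-gland Tail/Sac/Duct tri-section,
  3 replicates each. Each spidroin is multiplied by the cognate-gland fold
  F (default 100) in its gland; in the segments, MaSp1-group and
  unclassified dragline genes are boosted in Tail and Sac, MaSp2-group
  genes in Sac only — the qualitative segment co-expression pattern.
  Because the simulated background is only ~50 genes (not a full
  transcriptome), segment silk loads come out far higher (~80%) than a
  real gland would show; the load *ordering* (Tail ≈ Sac ≫ Duct) is the
  tested property.

## Discovery and statistics

Local alignment is Smith–Waterman with BLOSUM62 and affine gaps (open 11,
extend 1; a length-L gap costs 11 + L). Expect values use the
Karlin–Altschul form E = K·m·n·e^(−λS) with the canonical gapped-BLOSUM62
constants λ = 0.267, K = 0.041 and n = summed database length, so E-values
are reproducible without an external search tool. Cutoffs: 1e−10 for
spidroin discovery, 1e−5 for ortholog-style support. Per-gene deduplication
keeps the smallest E (ties: larger bit score, then smallest reference id).
Ambiguous residues B/Z/X are scored through the matrix; other characters
raise an alphabet error.

## Repeat detection

The periodicity profile is m(ℓ) = |{i : seq[i] = seq[i+ℓ]}|/(len−ℓ) for
ℓ = 5…200. The unit length ℓ* is the smallest lag within 5% of the profile
maximum (preferring the fundamental period over its multiples). The region
is the maximal run of positions whose 2ℓ*-window shifted-match fraction is
≥ θ = 0.5, then trimmed at residue resolution: an edge residue stays only
if it and ≥3 of its 5-residue block match at lag ℓ* (a θ window alone lets
flanking-domain residues bleed up to ℓ*/2 into the region). A valid region
spans ≥ 2 units. Motif classes are counted independently of each other
(no cross-class precedence — the order-free rule is the one an oracle can
check); within a class, matches are maximal, non-overlapping, scanned left
to right, with (A)n requiring ≥ 4 alanines and (GA)n ≥ 2 dyads. The
terminus window for architecture calls is 250 aa from either end. A
candidate with a repeat but no terminal evidence is conservatively called
non-spidroin: low-complexity repeats alone (collagens, cuticle proteins)
are not silk evidence.

## Genomic reconstruction

Terminal domains are aligned against all six reading frames; stop-free
frame segments shorter than 30 aa are skipped (intergenic frames fragment
into ~20-codon segments, genic frames stay long, which is also what makes
the search tractable). Hits are projected to full-domain genomic extents.
Pairing is greedy nearest (N before C in transcription orientation, span
≤ 50 kb) with one additional rule: a C anchor beyond another gene's N
anchor is not pairable — without it, a terminus-truncated gene's lone N
anchor swallows the next gene's C anchor. Unpaired anchors become partial
loci extended to the first in-frame stop.

**Frameshift repair.** A 1-nt indel shows up either as internal stops or —
because a shifted reading of a repetitive CDS is often stop-free for
hundreds of codons — only as a terminal frame break (CDS length ≢ 0 mod 3).
Downstream motif coverage cannot localise the edit in that regime: both
frames of a silk repeat are motif-covered. The repair therefore separates
two decisions. The *position and direction* of the edit are chosen by
repeat-phase continuity: among codon boundaries k upstream of the trigger,
maximise the agreement between the unit-length-lag window upstream of k
(current frame) and downstream of k (shifted frame), with ±1 residue slack
for the garbled junction codon; only the true indel position continues the
tandem phase, and a best phase score below 0.6 flags the locus unresolved.
The *acceptance* of a repair requires the downstream continuation to carry
silk-motif coverage ≥ 0.15 over a 60-aa look-ahead — a stop inside a
terminal domain has no repeat grammar downstream and is left unresolved
rather than guessed. At most 3 edits are applied; every edit (position,
±1, score) is recorded and serialised into the GFF3 attributes. The
repaired CDS (edits applied) always translates to the reported protein and
has length ≡ 0 mod 3.

## Catalog, grouping, expression, composition

Typing is an argmax over reference families of summed bit scores (ties:
highest single hit, then C-terminus evidence, then name) — a deterministic,
testable stand-in for tree-based classification, which is out of scope.
Chromosome groups are single-linkage clusters with gap ≤ 1 Mb and ≥ 3
members; the label is the majority superfamily and mixed membership is
expected (the first MaSp group contains a MaSp2 gene by design).

τ uses per-tissue mean FPKM; τ ≥ 0.8 is reported as gland-specific (the
source heatmaps carry no numeric rule; 0.8 is this package's reporting
convention). The integration filter implements strict inequalities
(repeat proportion < 0.5, protein length > 50 aa, Iso-seq identity > 95%,
homolog E < 1e−5 and identity > 50%) with ≥ 10 expressed samples; boundary
values drop, and each drop carries the first failing reason code in the
fixed order repeat → length → expression → support.

Tryptic digestion cleaves after K/R except before P with zero missed
cleavages; the iBAQ denominator counts peptides of 7–30 aa (7 matches the
minimal search peptide length; the window is a declared convention).
The bundled dragline proteome fixture carries the five published core-
component shares exactly and spreads the remaining 20.6% across the other
23 named proteins (which the source quantifies but does not itemise), so
both the top-5 cumulative share (79.4%) and the 28-protein class tally
stay consistent. Metabolite names in the fixture other than xanthurenic
acid are synthetic placeholders encoding the published category counts.

## What passing tests do and do not show

The synthetic genes are cleaner than real ones: single-exon, one
homogenised repeat unit per gene, type-specific termini, at most one indel.
Perfect precision/recall here demonstrates the pipeline logic — anchor
geometry, pairing, repair localisation, grouping — not performance on a
real assembly, where introns, nested paralogs, assembly gaps in repeat
arrays and shared terminal-domain homology would all lower it. Quantities
tied to full-scale data (genome-wide FPKM loads, raw-spectrum iBAQ) are
reproduced in *structure* (ordering, tallies, shares over worked inputs),
not in magnitude.

## Numerical and degenerate-input conventions

Internal coordinates are 0-based half-open; GFF3 export is 1-based closed.
Empty local alignments (all extensions negative) return score 0 with empty
spans. Degenerate grammars (all weights zero), empty reference databases,
empty composition input, overlapping chromosome plans, out-of-bounds locus
spans and unknown segments all raise typed errors rather than degrading.
All randomness flows from a single `numpy` Generator seeded per run;
bundles serialise to byte-identical files under a fixed (config, seed).
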