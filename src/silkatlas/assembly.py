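"""Genomic reconstruction of full-length spidroin gene models.

Terminal-domain references are aligned against all six reading frames of
the genome; N/C anchor pairs on one chromosome and strand delimit
candidate loci; the intervening CDS is extracted and translated in the
N-anchor frame; internal stops or frame breaks are repaired by single
±1-nucleotide frame shifts chosen to maximise the downstream silk-motif
grammar score.  Unrepairable loci are flagged, never silently fixed.

Internal coordinates are 0-based half-open; GFF3 export is 1-based
closed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Data.CodonTable import standard_dna_table

from ._alphabet import check_nucleotide
from .align import (ConfigurationError, E_SPIDROIN, ReferenceDomain,
                    ScoringScheme, align_local, evalue)
from .io import Gff3Record, reverse_complement
from .repeats import find_repeat_region, motif_coverage

MIN_SEGMENT = 30  # aa; shortest open segment worth aligning a domain against

_CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
_CODON_TO_AA.update({c: "*" for c in standard_dna_table.stop_codons})


def fast_translate(cds: str) -> str:
    """Codon-table translation; any codon containing N becomes X."""
    n = len(cds) - len(cds) % 3
    get = _CODON_TO_AA.get
    return "".join(get(cds[i:i + 3], "X") for i in range(0, n, 3))


@dataclass
class Frame:
    """One of the six reading frames of a chromosome, with its coordinate map."""

    chromosome: str
    strand: str  # "+" or "-"
    offset: int  # 0, 1 or 2 (on the read strand)
    protein: str
    chrom_length: int

    def genomic_span(self, i: int, j: int) -> tuple[int, int]:
        """Genomic span (0-based half-open) of protein positions [i, j)."""
        if self.strand == "+":
            return self.offset + 3 * i, self.offset + 3 * j
        L = self.chrom_length
        return L - self.offset - 3 * j, L - self.offset - 3 * i


def six_frame_translate(chromosome: str, name: str = "chr") -> list[Frame]:
    """All six reading frames with coordinate maps back to the genome."""
    check_nucleotide(chromosome)
    frames = []
    rc = reverse_complement(chromosome)
    for strand, seq in (("+", chromosome), ("-", rc)):
        for off in range(3):
            frames.append(Frame(chromosome=name, strand=strand, offset=off,
                                protein=fast_translate(seq[off:]),
                                chrom_length=len(chromosome)))
    return frames


@dataclass
class GenomicAnchor:
    """A terminal-domain hit projected onto the genome."""

    chromosome: str
    strand: str
    start: int  # genomic, 0-based half-open, full projected domain extent
    end: int
    frame: int
    terminus: str  # "N" or "C"
    sptype: str
    ref_id: str
    score: float
    evalue: float

    @property
    def tx_start(self) -> int:
        """Position along the transcription direction (for sorting)."""
        return self.start if self.strand == "+" else -self.end


def _open_segments(protein: str, min_len: int = MIN_SEGMENT):
    """(start, seq) for every stop-free stretch of at least min_len residues."""
    pos = 0
    for seg in protein.split("*"):
        if len(seg) >= min_len:
            yield pos, seg
        pos += len(seg) + 1


def anchor_search(refdb: list[ReferenceDomain], genome: dict[str, str],
                  scheme: ScoringScheme | None = None,
                  e_max: float = E_SPIDROIN) -> list[GenomicAnchor]:
    """Align each N/C reference terminus against all six frames of every
    chromosome; hits below ``e_max`` become genomic anchors.

    The database length for E-values is the summed residue count of all
    frames.  Overlapping anchors of the same terminus keep the best hit.
    """
    scheme = scheme or ScoringScheme()
    if not genome or not any(genome.values()):
        raise ConfigurationError("empty genome")
    termini = [r for r in refdb if r.terminus in ("N", "C")]
    if not termini:
        raise ConfigurationError("reference database has no terminal domains")
    all_frames = [f for name in sorted(genome)
                  for f in six_frame_translate(genome[name], name)]
    n_db = sum(len(f.protein) for f in all_frames)
    anchors: list[GenomicAnchor] = []
    for frame in all_frames:
        for seg_off, seg in _open_segments(frame.protein):
            for ref in termini:
                la = align_local(ref.sequence, seg, scheme, _skip_check=True)
                if la.score <= 0:
                    continue
                e = evalue(la.score, len(ref.sequence), n_db, scheme)
                if e >= e_max:
                    continue
                # project the *full* domain extent (unaligned ref flanks
                # extend the hit) back to genomic coordinates
                r0, r1 = la.qspan
                s0, s1 = la.rspan
                p0 = max(0, seg_off + s0 - r0)
                p1 = min(len(frame.protein),
                         seg_off + s1 + (len(ref.sequence) - r1))
                g0, g1 = frame.genomic_span(p0, p1)
                anchors.append(GenomicAnchor(
                    chromosome=frame.chromosome, strand=frame.strand,
                    start=g0, end=g1, frame=frame.offset,
                    terminus=ref.terminus, sptype=ref.sptype, ref_id=ref.id,
                    score=la.score, evalue=e))
    return _dedupe_anchors(anchors)


def _dedupe_anchors(anchors: list[GenomicAnchor]) -> list[GenomicAnchor]:
    """Collapse overlapping same-terminus anchors to the best E-value."""
    anchors = sorted(anchors, key=lambda a: (a.chromosome, a.strand, a.terminus,
                                             a.evalue, -a.score, a.ref_id))
    kept: list[GenomicAnchor] = []
    for a in anchors:
        clash = any(k.chromosome == a.chromosome and k.strand == a.strand
                    and k.terminus == a.terminus
                    and min(k.end, a.end) - max(k.start, a.start) > 0
                    for k in kept)
        if not clash:
            kept.append(a)
    kept.sort(key=lambda a: (a.chromosome, a.start, a.end, a.terminus))
    return kept


@dataclass
class CandidateLocus:
    chromosome: str
    strand: str
    start: int  # genomic 0-based half-open, includes the stop codon when known
    end: int
    n_anchor: GenomicAnchor | None
    c_anchor: GenomicAnchor | None

    @property
    def completeness(self) -> str:
        return "full-length" if self.n_anchor and self.c_anchor else "partial"

    @property
    def missing(self) -> str:
        if self.n_anchor is None:
            return "missing N"
        if self.c_anchor is None:
            return "missing C"
        return ""


def pair_anchors(anchors: list[GenomicAnchor], genome: dict[str, str],
                 max_span: int = 50_000) -> list[CandidateLocus]:
    """Pair N with C anchors into candidate loci (greedy nearest pairing).

    A pair must share chromosome and strand, have the N anchor 5' of the
    C anchor in transcription orientation, and span at most ``max_span``.
    Unpaired anchors become partial loci whose open end is extended to
    the first in-frame stop.
    """
    loci: list[CandidateLocus] = []
    groups: dict[tuple[str, str], list[GenomicAnchor]] = {}
    for a in anchors:
        groups.setdefault((a.chromosome, a.strand), []).append(a)
    for (chrom, strand), group in sorted(groups.items()):
        group.sort(key=lambda a: a.tx_start)
        ns = [a for a in group if a.terminus == "N"]
        cs = [a for a in group if a.terminus == "C"]
        used: set[int] = set()
        for n in ns:
            best = None
            for idx, c in enumerate(cs):
                if idx in used:
                    continue
                if strand == "+":
                    ok = c.start >= n.end and c.end - n.start <= max_span
                    dist = c.start - n.end
                else:
                    ok = c.end <= n.start and n.end - c.start <= max_span
                    dist = n.start - c.end
                # a C anchor beyond another gene's N anchor belongs to
                # that downstream gene, not to this one
                if ok and any(o is not n and n.tx_start < o.tx_start < c.tx_start
                              for o in ns):
                    ok = False
                if ok and (best is None or dist < best[0]):
                    best = (dist, idx, c)
            if best is None:
                loci.append(_partial_locus(n, genome, max_span))
                continue
            _, idx, c = best
            used.add(idx)
            if strand == "+":
                start, end = n.start, min(c.end + 3, len(genome[chrom]))
            else:
                start, end = max(c.start - 3, 0), n.end
            loci.append(CandidateLocus(chrom, strand, start, end, n, c))
        for idx, c in enumerate(cs):
            if idx not in used:
                loci.append(_partial_locus(c, genome, max_span))
    loci.sort(key=lambda l: (l.chromosome, l.start, l.end))
    return loci


def _partial_locus(anchor: GenomicAnchor, genome: dict[str, str],
                   max_span: int) -> CandidateLocus:
    """Extend a lone anchor along the transcript to the first in-frame stop."""
    seq = genome[anchor.chromosome]
    L = len(seq)
    downstream = anchor.terminus == "N"  # N extends 3', C extends 5'
    if (anchor.strand == "+") == downstream:
        # extend right on the genome
        pos = anchor.end
        limit = min(L, anchor.start + max_span)
        while pos + 3 <= limit:
            codon = seq[pos:pos + 3] if anchor.strand == "+" else \
                reverse_complement(seq[pos:pos + 3])
            pos += 3
            if _CODON_TO_AA.get(codon, "X") == "*":
                break
        start, end = anchor.start, pos
    else:
        # extend left on the genome
        pos = anchor.start
        limit = max(0, anchor.end - max_span)
        while pos - 3 >= limit:
            codon = seq[pos - 3:pos] if anchor.strand == "+" else \
                reverse_complement(seq[pos - 3:pos])
            if _CODON_TO_AA.get(codon, "X") == "*":
                break
            pos -= 3
        start, end = pos, anchor.end
    n = anchor if anchor.terminus == "N" else None
    c = anchor if anchor.terminus == "C" else None
    return CandidateLocus(anchor.chromosome, anchor.strand, start, end, n, c)


def extract_cds(locus: CandidateLocus, genome: dict[str, str]) -> str:
    seq = genome[locus.chromosome]
    if not (0 <= locus.start <= locus.end <= len(seq)):
        raise IndexError(f"locus span {locus.start}-{locus.end} outside "
                         f"{locus.chromosome} (length {len(seq)})")
    cds = seq[locus.start:locus.end]
    return cds if locus.strand == "+" else reverse_complement(cds)


def extract_and_translate(locus: CandidateLocus, genome: dict[str, str]
                          ) -> tuple[str, list[tuple[int, int]]]:
    """Translate the locus CDS in the N-anchor frame.

    Returns the protein (stops kept as '*') and a list of
    (protein_index, genomic_position) for every internal stop.
    """
    cds = extract_cds(locus, genome)
    protein = fast_translate(cds)
    stops = []
    for i, aa in enumerate(protein):
        if aa == "*" and i < len(protein) - 1:
            stops.append((i, cds_to_genomic(locus, 3 * i)))
    return protein, stops


def cds_to_genomic(locus: CandidateLocus, cds_pos: int) -> int:
    return locus.start + cds_pos if locus.strand == "+" else locus.end - cds_pos


@dataclass
class RepairEdit:
    cds_pos: int  # nt offset in the locus CDS where reading resumes shifted
    genomic_pos: int
    shift: int  # +1 (skip one base) or -1 (re-read one base)
    score: float  # motif-grammar coverage that selected this edit


@dataclass
class LocusModel:
    chromosome: str
    strand: str
    start: int
    end: int
    cds: str  # repaired CDS (edits applied); translates to `protein`
    protein: str
    completeness: str  # full-length | partial
    unresolved: bool = False
    repair_log: list[RepairEdit] = field(default_factory=list)
    locus: CandidateLocus | None = None

    @property
    def locus_id(self) -> str:
        return f"{self.chromosome}:{self.start}-{self.end}:{self.strand}"


def _phase_score(head: str, shifted: str, k: int, unit: int) -> float:
    """Repeat-phase continuity of the junction at codon k.

    Compares the `unit` residues upstream of the junction (read in the
    current frame) with the `unit` residues downstream (read in the
    shifted frame) at the repeat's unit-length lag: only the true edit
    position continues the tandem-repeat phase across the junction.
    """
    if k - unit < 0:
        return -1.0
    best = -1.0
    # the lost/garbled codon at the junction slips the register by one
    # residue, so allow +/-1 slack on the lag
    for o in (-1, 0, 1):
        if k + o < 0 or k + unit + o > len(shifted):
            continue
        hits = sum(head[k - unit + t] == shifted[k + t + o] for t in range(unit))
        best = max(best, hits / unit)
    return best


def _choose_edit(prot: str, cds: str, off: int, j: int | None,
                 lookahead: int, min_cov: float, min_phase: float,
                 forced_d: int | None = None):
    """Pick (d, k, coverage, phase) for one frameshift repair, or None.

    ``j`` is the codon index of the triggering stop (None for a
    stop-free frame break); candidate junctions k run over codon
    boundaries upstream of it.  The shifted frame d in {1, 2} (skip one
    base = +1 shift; skip two = -1 shift) and the junction are chosen to
    maximise phase continuity; downstream silk-motif coverage of the
    chosen continuation must clear ``min_cov``.
    """
    head_end = j if j is not None else len(prot)
    rep = find_repeat_region(prot[:head_end]) if head_end >= 20 else None
    if rep is None:
        return None
    unit = rep.unit_length
    k_lo = max(rep.start + unit, 0)
    best = None
    for d in (1, 2) if forced_d is None else (forced_d,):
        shifted = fast_translate(cds[off + d:])
        k_hi = min(head_end, len(shifted) - unit)
        for k in range(k_lo, k_hi + 1):
            s = _phase_score(prot, shifted, k, unit)
            cand = (s, k, d)
            if best is None or cand > best:
                best = cand
    if best is None or best[0] < min_phase:
        return None
    phase, k, d = best
    shifted = fast_translate(cds[off + d:])
    clear = shifted[k:k + lookahead].split("*")[0]
    cov = motif_coverage(clear) * min(1.0, len(clear) / lookahead)
    if cov < min_cov:
        return None
    return d, k, cov, phase


def repair_frameshifts(locus: CandidateLocus, genome: dict[str, str],
                       max_edits: int = 3, lookahead: int = 60,
                       min_score: float = 0.15, min_phase: float = 0.6
                       ) -> LocusModel:
    """Build the locus model, repairing frameshifts where needed.

    Scanning 5'->3', each internal stop — or a terminal frame break when
    the shifted frame happens to be stop-free — is resolved by a +1 or
    -1 frame shift.  The junction is localised by repeat-phase
    continuity (see :func:`_phase_score`) and the chosen continuation
    must score at least ``min_score`` downstream silk-motif coverage
    over a ``lookahead``-residue window; otherwise (e.g. a corruption
    inside a terminal domain, where no repeat grammar lies downstream)
    the locus is flagged unresolved.  At most ``max_edits`` edits are
    applied; every edit is recorded.
    """
    cds = extract_cds(locus, genome)
    full = locus.completeness == "full-length"
    parts: list[str] = []
    edits: list[RepairEdit] = []
    consumed: list[str] = []
    unresolved = False
    off = 0
    while True:
        prot = fast_translate(cds[off:])
        j = prot.find("*")
        frame_break = (j == -1 or j == len(prot) - 1) and full and \
            (len(cds) - off) % 3 != 0
        if (j == -1 or j == len(prot) - 1) and not frame_break:
            parts.append(prot[:j] if j != -1 else prot)
            consumed.append(cds[off:off + 3 * len(parts[-1])])
            break
        if len(edits) >= max_edits:
            parts.append(prot[:j] if j != -1 else prot)
            consumed.append(cds[off:off + 3 * len(parts[-1])])
            unresolved = True
            break
        forced = (len(cds) - off) % 3 if frame_break else None
        choice = _choose_edit(prot, cds, off, None if frame_break else j,
                              lookahead, min_score, min_phase,
                              forced_d=forced or None)
        if choice is None:
            clean = prot[:j] if j != -1 else prot
            parts.append(clean)
            consumed.append(cds[off:off + 3 * len(clean)])
            unresolved = True
            break
        d, k, cov, phase = choice
        p = off + 3 * k
        parts.append(prot[:k])
        consumed.append(cds[off:p])
        edits.append(RepairEdit(cds_pos=p, genomic_pos=cds_to_genomic(locus, p),
                                shift=+1 if d == 1 else -1, score=cov))
        off = p + d
    protein = "".join(parts)
    repaired_cds = "".join(consumed)
    return LocusModel(chromosome=locus.chromosome, strand=locus.strand,
                      start=locus.start, end=locus.end, cds=repaired_cds,
                      protein=protein, completeness=locus.completeness,
                      unresolved=unresolved, repair_log=edits, locus=locus)


def assemble_loci(refdb: list[ReferenceDomain], genome: dict[str, str],
                  scheme: ScoringScheme | None = None,
                  e_max: float = E_SPIDROIN, max_span: int = 50_000
                  ) -> list[LocusModel]:
    """Anchor search + pairing + extraction + repair, end to end."""
    anchors = anchor_search(refdb, genome, scheme, e_max)
    loci = pair_anchors(anchors, genome, max_span)
    return [repair_frameshifts(l, genome) for l in loci]


def emit_gff3(models: list[LocusModel], source: str = "silkatlas") -> list[Gff3Record]:
    """gene/mRNA/CDS features, 1-based closed, with completeness and
    repair log serialised in the attributes column."""
    records = []
    for i, m in enumerate(models, start=1):
        gid = f"locus{i:03d}"
        repair = ",".join(f"{'+1' if e.shift > 0 else '-1'}@{e.genomic_pos}"
                          for e in m.repair_log) or "none"
        base = {"completeness": m.completeness,
                "unresolved": str(m.unresolved).lower(), "repair": repair}
        records.append(Gff3Record(m.chromosome, source, "gene", m.start + 1,
                                  m.end, ".", m.strand, ".",
                                  {"ID": gid, **base}))
        records.append(Gff3Record(m.chromosome, source, "mRNA", m.start + 1,
                                  m.end, ".", m.strand, ".",
                                  {"ID": f"{gid}.t1", "Parent": gid}))
        records.append(Gff3Record(m.chromosome, source, "CDS", m.start + 1,
                                  m.end, ".", m.strand, "0",
                                  {"ID": f"{gid}.cds", "Parent": f"{gid}.t1"}))
    return records
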