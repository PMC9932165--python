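"""Six-frame translation, anchoring, locus pairing and frameshift repair."""

import numpy as np
import pytest

import gffutils
from silkatlas import io as sio
from silkatlas._alphabet import AlphabetError
from silkatlas.assembly import (CandidateLocus, GenomicAnchor, anchor_search,
                                assemble_loci, emit_gff3, extract_and_translate,
                                fast_translate, pair_anchors, repair_frameshifts,
                                six_frame_translate)
from silkatlas.pipeline import identity
from silkatlas.synthetic import (CorruptionRecord, GeneSpec, Placement,
                                 embed_genes, library_by_type,
                                 load_terminal_library, make_decoy,
                                 make_spidroin, random_dna)


# ---------------------------------------------------------------- six frames

def test_forward_frame_zero_codon_table():
    frames = six_frame_translate("ATGAAA")
    fwd0 = next(f for f in frames if f.strand == "+" and f.offset == 0)
    assert fwd0.protein == "MK"


def test_reverse_frame_zero_is_reverse_complement_reading():
    frames = six_frame_translate("TTTCAT")
    rev0 = next(f for f in frames if f.strand == "-" and f.offset == 0)
    assert rev0.protein == "MK"


def test_frame_coordinate_maps_round_trip():
    rng = np.random.default_rng(17)
    genome = random_dna(rng, 999)
    for f in six_frame_translate(genome, "c"):
        for i in range(0, len(f.protein), 37):
            g0, g1 = f.genomic_span(i, i + 1)
            codon = genome[g0:g1]
            if f.strand == "-":
                codon = sio.reverse_complement(codon)
            assert fast_translate(codon) == f.protein[i]


def test_invalid_base_rejected():
    with pytest.raises(AlphabetError):
        six_frame_translate("ACGU")


# ---------------------------------------------------------------- anchors

@pytest.fixture(scope="module")
def single_gene_world():
    rng = np.random.default_rng(21)
    lib = library_by_type(load_terminal_library())
    prot, truth = make_spidroin("MaSp1", 14, lib, rng=rng, gene_id="g")
    spec = GeneSpec("g", prot, truth)
    chroms, _, _ = embed_genes([spec], [Placement("g", "chrS", "+", 2000)], rng)
    return load_terminal_library(), truth, chroms


def test_anchors_at_truth_coordinates(single_gene_world):
    refs, truth, chroms = single_gene_world
    anchors = anchor_search(refs, chroms)
    ns = [a for a in anchors if a.terminus == "N"]
    cs = [a for a in anchors if a.terminus == "C"]
    assert len(ns) == 1 and len(cs) == 1
    assert abs(ns[0].start - truth.cds_start) <= 30
    assert abs(cs[0].end - (truth.cds_end - 3)) <= 30  # stop codon excluded
    assert ns[0].sptype == "MaSp1" and ns[0].strand == "+"
    assert (ns[0].end - ns[0].start) % 3 == 0


def test_decoy_only_genome_yields_no_anchors():
    rng = np.random.default_rng(23)
    refs = load_terminal_library()
    genes = [GeneSpec(f"d{i}", make_decoy(250, 0.3 * (i % 2), rng))
             for i in range(6)]
    plan = [Placement(g.gene_id, "chrD", "+", 1000 + 1500 * i)
            for i, g in enumerate(genes)]
    chroms, _, _ = embed_genes(genes, plan, rng)
    assert anchor_search(refs, chroms) == []


def test_anchor_count_monotone_in_threshold(single_gene_world):
    refs, _, chroms = single_gene_world
    strict = anchor_search(refs, chroms, e_max=1e-40)
    loose = anchor_search(refs, chroms, e_max=1e-5)
    assert len(loose) >= len(strict)


# ---------------------------------------------------------------- pairing

def _anchor(terminus, start, end, strand="+", chrom="c1"):
    return GenomicAnchor(chromosome=chrom, strand=strand, start=start, end=end,
                         frame=start % 3, terminus=terminus, sptype="MaSp1",
                         ref_id=f"{terminus}r", score=500, evalue=1e-60)


def _toy_genome(n=20000):
    # stop-free-ish backbone is irrelevant for pairing geometry
    return {"c1": random_dna(np.random.default_rng(0), n)}


def test_pairing_worked_example():
    loci = pair_anchors([_anchor("N", 1000, 1300), _anchor("C", 9000, 9200)],
                        _toy_genome())
    assert len(loci) == 1
    l = loci[0]
    assert l.completeness == "full-length"
    assert l.start == 1000 and 9200 <= l.end <= 9203


def test_lone_N_anchor_becomes_partial_locus():
    loci = pair_anchors([_anchor("N", 1000, 1300)], _toy_genome())
    assert len(loci) == 1
    assert loci[0].completeness == "partial"
    assert loci[0].missing == "missing C"


def test_wrong_orientation_not_paired():
    loci = pair_anchors([_anchor("C", 1000, 1200), _anchor("N", 9000, 9300)],
                        _toy_genome())
    assert all(l.completeness == "partial" for l in loci)
    assert len(loci) == 2


def test_span_limit_blocks_distant_pairs():
    loci = pair_anchors([_anchor("N", 1000, 1300), _anchor("C", 9000, 9200)],
                        _toy_genome(), max_span=5000)
    assert all(l.completeness == "partial" for l in loci)


def test_minus_strand_pairing_orientation():
    # transcription right-to-left: N anchor lies right of C anchor
    loci = pair_anchors([_anchor("C", 1000, 1200, "-"),
                         _anchor("N", 9000, 9300, "-")], _toy_genome())
    assert len(loci) == 1
    assert loci[0].completeness == "full-length"
    assert loci[0].start in (997, 1000) and loci[0].end == 9300


# ---------------------------------------------------------------- extraction

def test_extraction_reproduces_truth_protein(single_gene_world):
    refs, truth, chroms = single_gene_world
    loci = pair_anchors(anchor_search(refs, chroms), chroms)
    assert len(loci) == 1
    protein, stops = extract_and_translate(loci[0], chroms)
    assert stops == []
    assert protein.rstrip("*") == truth.protein


def test_out_of_bounds_span_rejected(single_gene_world):
    _, _, chroms = single_gene_world
    bad = CandidateLocus("chrS", "+", 0, len(chroms["chrS"]) + 10, None, None)
    with pytest.raises(IndexError):
        extract_and_translate(bad, chroms)


# ---------------------------------------------------------------- repair

@pytest.fixture(scope="module")
def corrupted_world():
    rng = np.random.default_rng(31)
    lib = library_by_type(load_terminal_library())
    prot, truth = make_spidroin("MaSp1", 20, lib, rng=rng, gene_id="g")
    spec = GeneSpec("g", prot, truth)
    chroms, _, _ = embed_genes(
        [spec], [Placement("g", "chrS", "+", 1500)], rng,
        {"g": CorruptionRecord(kind="del", cds_pos=-1)})
    return load_terminal_library(), truth, chroms


def test_single_deletion_detected_then_repaired(corrupted_world):
    refs, truth, chroms = corrupted_world
    loci = pair_anchors(anchor_search(refs, chroms), chroms)
    assert len(loci) == 1 and loci[0].completeness == "full-length"
    protein, stops = extract_and_translate(loci[0], chroms)
    cds_len = loci[0].end - loci[0].start
    assert stops or cds_len % 3 != 0  # the frameshift is visible
    model = repair_frameshifts(loci[0], chroms)
    assert not model.unresolved
    assert len(model.repair_log) == 1
    assert model.repair_log[0].shift in (-1, +1)
    assert identity(model.protein, truth.protein) >= 0.95
    # repaired CDS is a consistent gene model
    assert len(model.cds) % 3 == 0
    assert fast_translate(model.cds) == model.protein
    # the edit lies inside the truth repeat array
    lo = truth.cds_start + 3 * truth.repeat_start
    hi = truth.cds_start + 3 * truth.repeat_end
    assert lo <= model.repair_log[0].genomic_pos <= hi


def test_clean_locus_returned_unchanged(single_gene_world):
    refs, truth, chroms = single_gene_world
    loci = pair_anchors(anchor_search(refs, chroms), chroms)
    model = repair_frameshifts(loci[0], chroms)
    assert model.repair_log == [] and not model.unresolved
    assert model.protein == truth.protein


def test_corruption_in_terminal_domain_unresolved():
    rng = np.random.default_rng(37)
    lib = library_by_type(load_terminal_library())
    prot, truth = make_spidroin("MaSp1", 20, lib, rng=rng, gene_id="g")
    spec = GeneSpec("g", prot, truth)
    # place the single deletion inside the C-terminal domain: downstream of
    # the break there is no repeat grammar left to guide a repair
    pos = 3 * truth.repeat_end + 150
    chroms, _, _ = embed_genes(
        [spec], [Placement("g", "chrS", "+", 1500)], rng,
        {"g": CorruptionRecord(kind="del", cds_pos=pos)})
    refs = load_terminal_library()
    loci = pair_anchors(anchor_search(refs, chroms), chroms)
    models = [repair_frameshifts(l, chroms) for l in loci]
    assert any(m.unresolved for m in models)


# ---------------------------------------------------------------- GFF export

def test_gff3_round_trip_and_strand(models):
    records = emit_gff3(models)
    text = sio.format_gff3(records)
    back = sio.parse_gff3(text)
    assert [r.line() for r in back] == [r.line() for r in records]
    for r in back:
        assert 1 <= r.start <= r.end
        assert r.strand in "+-"
    minus = [r for r in back if r.strand == "-"]
    assert minus, "expected at least one minus-strand locus"


def test_gff3_passes_external_syntax_checker(models, tmp_path):
    text = sio.format_gff3(emit_gff3(models))
    db = gffutils.create_db(text, dbfn=":memory:", from_string=True,
                            keep_order=True, force=True)
    genes = list(db.features_of_type("gene"))
    assert len(genes) == len(models)
    for g in genes:
        assert g.attributes["completeness"][0] in ("full-length", "partial")


# ---------------------------------------------------------------- end to end

def test_bundle_reconstruction_matches_truth(bundle, models):
    matched = {}
    decoy_loci = 0
    for m in models:
        hit = None
        for t in bundle.truths:
            if (t.chromosome == m.chromosome
                    and min(t.cds_end, m.end) - max(t.cds_start, m.start) > 0):
                hit = t
                break
        if hit is None:
            decoy_loci += 1
        else:
            matched[hit.gene_id] = m
    assert decoy_loci == 0
    assert len(matched) >= 0.9 * len(bundle.truths)
    agree = sum(matched[t.gene_id].completeness == t.completeness
                for t in bundle.truths if t.gene_id in matched)
    assert agree >= 0.9 * len(matched)
    for m in models:
        assert 0 <= m.start < m.end <= len(bundle.chromosomes[m.chromosome])
        assert len(m.cds) % 3 == 0
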