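"""Synthetic genome / proteome / expression bundles with ground truth.

Every downstream stage of the pipeline is exercised against bundles
produced here: spidroin genes with nonrepetitive terminal domains
flanking long grammar-emitted repeat arrays, terminus-truncated partial
genes, frameshift-corrupted loci, low-complexity decoys, and a
multi-tissue expression design with strong cognate-gland enrichment
plus the Tail/Sac/Duct tri-segment layout of the major ampullate gland.

The terminal-domain library is synthetic: one canonical N and C domain
per spidroin family, generated once from a fixed seed and shipped as a
package fixture, so no external sequence download is ever needed.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from importlib import resources

import numpy as np
import pandas as pd
from Bio.Data.CodonTable import standard_dna_table

from ._alphabet import AMINO_ACIDS
from .align import LocalAlignment, ReferenceDomain, ScoringScheme, align_local
from .grammar import DEFAULT_GRAMMARS, MotifGrammar, SPIDROIN_TYPES, make_repeat_unit
from . import io as sio

LIBRARY_SEED = 7_2023  # fixed seed of the shipped terminal-domain fixture
_STOP_CODONS = ("TAA", "TAG", "TGA")


class PlanError(ValueError):
    pass


# ---------------------------------------------------------------- library

def _random_domain(rng: np.random.Generator, length: int) -> str:
    """A nonrepetitive globular-looking domain (uniform-ish composition,
    mildly enriched in helix formers as real spidroin termini are)."""
    weights = {aa: 1.0 for aa in AMINO_ACIDS}
    for aa in "AELSKQD":
        weights[aa] = 2.0
    res, w = zip(*sorted(weights.items()))
    p = np.asarray(w) / sum(w)
    return "".join(rng.choice(list(res), size=length, p=p))


def build_terminal_library(seed: int = LIBRARY_SEED) -> list[ReferenceDomain]:
    """One canonical N and C domain (100-150 aa) per spidroin family."""
    rng = np.random.default_rng(seed)
    refs = []
    for sptype in SPIDROIN_TYPES:
        for terminus in ("N", "C"):
            length = int(rng.integers(110, 141))
            refs.append(ReferenceDomain(
                id=f"{sptype}_{terminus}TD", sptype=sptype, terminus=terminus,
                sequence=_random_domain(rng, length)))
    return refs


def load_terminal_library() -> list[ReferenceDomain]:
    text = resources.files("silkatlas.data").joinpath("terminal_domains.fasta").read_text()
    return sio.parse_reference_fasta(text)


def library_by_type(refs: list[ReferenceDomain]) -> dict[str, dict[str, str]]:
    out: dict[str, dict[str, str]] = {}
    for r in refs:
        out.setdefault(r.sptype, {})[r.terminus] = r.sequence
    return out


# ---------------------------------------------------------------- truth

@dataclass
class CorruptionRecord:
    kind: str  # "del" | "ins" | "truncate_C" | "truncate_N"
    cds_pos: int  # 0-based position in the (pre-corruption) CDS


@dataclass
class SpidroinTruth:
    gene_id: str
    sptype: str
    chromosome: str = ""
    strand: str = "+"
    cds_start: int = 0  # genomic, 0-based half-open
    cds_end: int = 0
    protein: str = ""  # pre-corruption protein
    repeat_start: int = 0  # protein coordinates
    repeat_end: int = 0
    unit_length: int = 0
    completeness: str = "full-length"
    corruption: CorruptionRecord | None = None


# ---------------------------------------------------------------- genes

def mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent point substitutions at the given per-residue rate."""
    if rate <= 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        choices = AMINO_ACIDS.replace(out[i], "")
        out[i] = choices[int(rng.integers(len(choices)))]
    return "".join(out)


def make_spidroin(sptype: str, n_units: int, library: dict[str, dict[str, str]],
                  substitution_rate: float = 0.02,
                  rng: np.random.Generator | None = None,
                  grammar: MotifGrammar | None = None,
                  gene_id: str = "") -> tuple[str, SpidroinTruth]:
    """One synthetic spidroin: mutated N domain + n_units tandem copies of
    a grammar-emitted repeat unit + mutated C domain."""
    if sptype not in library:
        raise ValueError(f"unknown spidroin type {sptype!r}")
    if rng is None:
        rng = np.random.default_rng()
    grammar = grammar or DEFAULT_GRAMMARS[sptype]
    unit = make_repeat_unit(grammar, rng) if n_units > 0 else ""
    ndom = mutate(library[sptype]["N"], substitution_rate, rng)
    array = mutate(unit * n_units, substitution_rate, rng)
    cdom = mutate(library[sptype]["C"], substitution_rate, rng)
    protein = ndom + array + cdom
    truth = SpidroinTruth(
        gene_id=gene_id or sptype, sptype=sptype, protein=protein,
        repeat_start=len(ndom), repeat_end=len(ndom) + len(array),
        unit_length=len(unit), completeness="full-length")
    return protein, truth


def terminal_identity(seq: str, terminus: str, scheme: ScoringScheme) -> float:
    """Fraction of terminus residues matched in the best local alignment."""
    la: LocalAlignment = align_local(seq, terminus, scheme)
    if la.score <= 0:
        return 0.0
    # identity is % over alignment columns; rescale to the terminus length
    cols = la.rspan[1] - la.rspan[0]
    return (la.identity / 100.0) * cols / len(terminus)


def make_decoy(length: int, low_complexity_fraction: float,
               rng: np.random.Generator,
               library: list[ReferenceDomain] | None = None,
               scheme: ScoringScheme | None = None,
               max_tries: int = 50) -> str:
    """A non-spidroin decoy protein.

    The low-complexity portion is a collagen-like G-X-Y repeat (a
    realistic confounder for repeat detection); the rest is uniform over
    the 20 amino acids.  Rejection sampling guarantees no segment shares
    more than 40% identity with any library terminal domain.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    scheme = scheme or ScoringScheme()
    xy = "PASQ"
    for _ in range(max_tries):
        lc_len = int(round(low_complexity_fraction * length))
        n_triplets = lc_len // 3
        lc = "".join("G" + xy[int(rng.integers(4))] + xy[int(rng.integers(4))]
                     for _ in range(n_triplets))
        plain_len = length - len(lc)
        plain = "".join(np.asarray(list(AMINO_ACIDS))[rng.integers(0, 20, plain_len)])
        cut = int(rng.integers(0, plain_len + 1))
        seq = plain[:cut] + lc + plain[cut:]
        if library and any(terminal_identity(seq, r.sequence, scheme) > 0.40
                           for r in library):
            continue
        return seq
    raise RuntimeError("could not sample a decoy clearing the identity bound")


# ---------------------------------------------------------------- genome

def _codon_choices() -> dict[str, tuple[str, ...]]:
    table: dict[str, list[str]] = {}
    for codon, aa in standard_dna_table.forward_table.items():
        table.setdefault(aa, []).append(codon)
    return {aa: tuple(sorted(cs)) for aa, cs in table.items()}


_CODONS = _codon_choices()


def reverse_translate(protein: str, rng: np.random.Generator,
                      codon_usage: dict[str, tuple[str, ...]] | None = None) -> str:
    """Protein -> CDS with a stop codon; uniform over synonymous codons."""
    usage = codon_usage or _CODONS
    parts = [usage[aa][int(rng.integers(len(usage[aa])))] for aa in protein]
    parts.append(_STOP_CODONS[int(rng.integers(3))])
    return "".join(parts)


@dataclass
class Placement:
    gene_id: str
    chromosome: str
    strand: str
    start: int  # genomic, 0-based


@dataclass
class GeneSpec:
    gene_id: str
    protein: str
    truth: SpidroinTruth | None = None  # None -> decoy


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, length)])


def corrupt_cds(cds: str, truth: SpidroinTruth, record: CorruptionRecord,
                rng: np.random.Generator) -> str:
    """Apply one corruption to a CDS and fill in the record position."""
    rs, re_ = 3 * truth.repeat_start, 3 * truth.repeat_end
    if record.kind in ("del", "ins"):
        if record.cds_pos < 0:
            # middle third of the repeat span: leaves enough repeat on both
            # sides for the grammar-guided repair to act within the array
            third = (re_ - rs) // 3
            record.cds_pos = int(rng.integers(rs + third, re_ - third))
        p = record.cds_pos
        if record.kind == "del":
            return cds[:p] + cds[p + 1:]
        base = "ACGT"[int(rng.integers(4))]
        return cds[:p] + base + cds[p:]
    if record.kind == "truncate_C":
        mid = 3 * ((truth.repeat_start + truth.repeat_end) // 2)
        record.cds_pos = mid
        truth.completeness = "partial"
        return cds[:mid]
    if record.kind == "truncate_N":
        mid = 3 * ((truth.repeat_start + truth.repeat_end) // 2)
        record.cds_pos = mid
        truth.completeness = "partial"
        return cds[mid:]
    raise ValueError(f"unknown corruption kind {record.kind!r}")


def embed_genes(genes: list[GeneSpec], plan: list[Placement],
                rng: np.random.Generator,
                corruption_plan: dict[str, CorruptionRecord] | None = None,
                codon_usage: dict[str, tuple[str, ...]] | None = None,
                trailing_flank: int = 600,
                ) -> tuple[dict[str, str], list[sio.Gff3Record], dict[str, str]]:
    """Reverse-translate and embed genes into chromosomes.

    Returns (chromosomes, gene models as GFF3 records, proteome).  The
    proteome is annotation-style: the translation of each embedded CDS
    up to its first stop, so corrupted loci yield corrupted proteins.
    Truth records (reached through ``genes[i].truth``) are updated in
    place with coordinates and corruption effects.
    """
    corruption_plan = corruption_plan or {}
    by_id = {g.gene_id: g for g in genes}
    placed: dict[str, list[tuple[int, int, Placement, str]]] = {}
    proteome: dict[str, str] = {}
    for pl in plan:
        g = by_id[pl.gene_id]
        cds = reverse_translate(g.protein, rng, codon_usage)
        if g.truth is not None:
            assert len(cds) % 3 == 0
        rec = corruption_plan.get(pl.gene_id)
        if rec is not None:
            if g.truth is None:
                raise PlanError(f"cannot corrupt decoy {pl.gene_id}")
            cds = corrupt_cds(cds, g.truth, rec, rng)
            g.truth.corruption = rec
        placed.setdefault(pl.chromosome, []).append(
            (pl.start, pl.start + len(cds), pl, cds))
        prot = sio.translate_cds(cds)
        proteome[pl.gene_id] = prot.split("*")[0]
    chromosomes: dict[str, str] = {}
    gff: list[sio.Gff3Record] = []
    for chrom in sorted(placed):
        spans = sorted(placed[chrom])
        for (s1, e1, *_), (s2, _, *_) in zip(spans, spans[1:]):
            if s2 < e1:
                raise PlanError(f"overlapping spans on {chrom}: {e1} > {s2}")
        length = spans[-1][1] + trailing_flank
        backbone = list(random_dna(rng, length))
        for start, end, pl, cds in spans:
            insert = cds if pl.strand == "+" else sio.reverse_complement(cds)
            backbone[start:end] = insert
            g = by_id[pl.gene_id]
            if g.truth is not None:
                g.truth.chromosome, g.truth.strand = chrom, pl.strand
                g.truth.cds_start, g.truth.cds_end = start, end
            attrs_gene = {"ID": pl.gene_id}
            attrs_mrna = {"ID": f"{pl.gene_id}.t1", "Parent": pl.gene_id}
            attrs_cds = {"ID": f"{pl.gene_id}.cds", "Parent": f"{pl.gene_id}.t1"}
            for ftype, attrs in (("gene", attrs_gene), ("mRNA", attrs_mrna),
                                 ("CDS", attrs_cds)):
                gff.append(sio.Gff3Record(chrom, "silkatlas", ftype,
                                          start + 1, end, ".", pl.strand,
                                          "0" if ftype == "CDS" else ".", attrs))
        chromosomes[chrom] = "".join(backbone)
    return chromosomes, gff, proteome


# ---------------------------------------------------------------- expression

GLANDS = ("Ma", "Mi", "Fl", "Tu", "Ag", "AcPy", "Venom")
SEGMENTS = ("Tail", "Sac", "Duct")

#: gland in which each spidroin family is predominantly expressed
COGNATE_GLAND = {"MaSp1": "Ma", "MaSp2": "Ma", "MiSp": "Mi", "FlSp": "Fl",
                 "TuSp": "Tu", "AgSp": "Ag", "AcSp": "AcPy", "PySp": "AcPy",
                 "other": "Ma"}


@dataclass(frozen=True)
class ExpressionDesign:
    """Sampling design: 7 gland types plus the Ma-gland tri-section.

    Baseline FPKM is LogNormal(mu0, sigma); each silk gene is multiplied
    by the cognate-gland fold factor ``fold`` in its cognate gland.  In
    the tri-segment columns, MaSp group-1 genes (MaSp1*, other dragline)
    are boosted in Tail and Sac, group-2 genes (MaSp2*) in the Sac only,
    mirroring the observed segment co-expression pattern.
    """

    glands: tuple[str, ...] = GLANDS
    segments: tuple[str, ...] = SEGMENTS
    replicates: int = 3
    mu0: float = float(np.log(10.0))
    sigma: float = 1.0
    fold: float = 100.0

    def __post_init__(self):
        if self.fold < 1:
            raise ValueError("fold factor must be >= 1")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")

    def columns(self) -> list[str]:
        cols = []
        for tissue in tuple(self.glands) + tuple(self.segments):
            for r in range(1, self.replicates + 1):
                cols.append(f"{tissue}_{r}:{tissue}")
        return cols


def tissue_of(column: str) -> str:
    return column.rsplit(":", 1)[1]


def _segment_fold(sptype: str | None, segment: str, fold: float) -> float:
    if sptype is None:
        return 1.0
    if sptype.startswith("MaSp2"):
        return fold if segment == "Sac" else 1.0
    if sptype.startswith("MaSp") or sptype == "other":
        return fold if segment in ("Tail", "Sac") else 1.0
    return 1.0


def make_expression(gene_types: dict[str, str | None], design: ExpressionDesign,
                    rng: np.random.Generator) -> pd.DataFrame:
    """FPKM matrix (genes x samples); column labels are ``sample:tissue``."""
    cols = design.columns()
    genes = list(gene_types)
    base = rng.lognormal(design.mu0, design.sigma, size=(len(genes), len(cols)))
    df = pd.DataFrame(base, index=genes, columns=cols)
    for gid, sptype in gene_types.items():
        if sptype is None:
            continue
        cognate = COGNATE_GLAND.get(sptype, "Ma")
        for col in cols:
            t = tissue_of(col)
            if t == cognate:
                df.loc[gid, col] *= design.fold
            elif t in design.segments:
                df.loc[gid, col] *= _segment_fold(sptype, t, design.fold)
    return df


# ---------------------------------------------------------------- bundle

@dataclass
class SyntheticConfig:
    """Study conditions for one synthetic bundle."""

    type_counts: dict[str, int] = field(default_factory=lambda: {
        "MaSp1": 2, "MaSp2": 1, "MiSp": 2, "FlSp": 1, "TuSp": 1,
        "AgSp": 1, "AcSp": 1, "PySp": 1})
    n_decoys: int = 50
    n_chromosomes: int = 3
    n_units: tuple[int, int] = (16, 24)
    substitution_rate: float = 0.02
    decoy_length: tuple[int, int] = (150, 400)
    decoy_lc_fraction: float = 0.3
    flank: tuple[int, int] = (800, 2000)
    n_indel: int = 1  # frameshift-corrupted genes
    n_truncated: int = 1  # terminus-truncated genes
    grouped_layout: bool = False
    design: ExpressionDesign = field(default_factory=ExpressionDesign)

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def grouped_config() -> SyntheticConfig:
    """Three chromosome groups of sizes 4 / 4 / 5 (MaSp1a-c + MaSp2e,
    MaSp2a-d, MiSp a-e), the layout used for group-recovery checks."""
    return SyntheticConfig(
        type_counts={"MaSp1": 3, "MaSp2": 5, "MiSp": 5},
        n_decoys=12, n_chromosomes=3, n_indel=0, n_truncated=0,
        grouped_layout=True)


def paper_catalog_counts() -> dict[str, int]:
    """The full-length per-family catalog breakdown used as a worked input."""
    return {"MaSp": 9, "MiSp": 5, "FlSp": 2, "TuSp": 1, "AgSp": 2,
            "AcSp": 1, "PySp": 1, "other": 5}


@dataclass
class SyntheticGenomeBundle:
    chromosomes: dict[str, str]
    gff: list[sio.Gff3Record]
    proteome: dict[str, str]
    truths: list[SpidroinTruth]
    decoy_ids: list[str]
    expression: pd.DataFrame
    provenance: dict

    # -- serialization ----------------------------------------------------

    def truth_frame(self) -> pd.DataFrame:
        rows = []
        for t in self.truths:
            corr = "" if t.corruption is None else f"{t.corruption.kind}@{t.corruption.cds_pos}"
            rows.append(dict(gene_id=t.gene_id, sptype=t.sptype,
                             chromosome=t.chromosome, strand=t.strand,
                             cds_start=t.cds_start, cds_end=t.cds_end,
                             repeat_start=t.repeat_start, repeat_end=t.repeat_end,
                             unit_length=t.unit_length,
                             completeness=t.completeness, corruption=corr,
                             protein=t.protein))
        for d in self.decoy_ids:
            rows.append(dict(gene_id=d, sptype="decoy", chromosome="", strand="",
                             cds_start=0, cds_end=0, repeat_start=0, repeat_end=0,
                             unit_length=0, completeness="", corruption="",
                             protein=""))
        return pd.DataFrame(rows)

    def serialize(self) -> dict[str, str]:
        return {
            "genome.fasta": sio.format_fasta(self.chromosomes),
            "genes.gff3": sio.format_gff3(self.gff),
            "proteome.fasta": sio.format_fasta(self.proteome),
            "truth.tsv": sio.format_tsv(self.truth_frame()),
            "expression.tsv": self.expression.rename_axis("gene_id").to_csv(sep="\t"),
            "provenance.json": json.dumps(self.provenance, sort_keys=True) + "\n",
        }

    def write(self, outdir) -> None:
        import pathlib
        d = pathlib.Path(outdir)
        d.mkdir(parents=True, exist_ok=True)
        for name, text in self.serialize().items():
            (d / name).write_text(text)

    def cds_of(self, truth: SpidroinTruth) -> str:
        seq = self.chromosomes[truth.chromosome][truth.cds_start:truth.cds_end]
        return seq if truth.strand == "+" else sio.reverse_complement(seq)

    def gene_types(self) -> dict[str, str | None]:
        d: dict[str, str | None] = {t.gene_id: t.sptype for t in self.truths}
        d.update({g: None for g in self.decoy_ids})
        return d


def _gene_names(type_counts: dict[str, int]) -> list[tuple[str, str]]:
    names = []
    for sptype in sorted(type_counts):
        n = type_counts[sptype]
        for i in range(n):
            suffix = chr(ord("a") + i) if n > 1 else ""
            names.append((f"{sptype}{suffix}", sptype))
    return names


def make_bundle(config: SyntheticConfig | None = None, seed: int = 0) -> SyntheticGenomeBundle:
    """Generate a complete bundle under the given study conditions."""
    config = config or SyntheticConfig()
    rng = np.random.default_rng(seed)
    library = load_terminal_library()
    lib = library_by_type(library)
    scheme = ScoringScheme()

    genes: list[GeneSpec] = []
    for gid, sptype in _gene_names(config.type_counts):
        n_units = int(rng.integers(config.n_units[0], config.n_units[1] + 1))
        protein, truth = make_spidroin(sptype, n_units, lib,
                                       config.substitution_rate, rng, gene_id=gid)
        genes.append(GeneSpec(gid, protein, truth))
    decoy_ids = []
    for i in range(config.n_decoys):
        gid = f"decoy_{i + 1:03d}"
        length = int(rng.integers(config.decoy_length[0], config.decoy_length[1] + 1))
        lcf = config.decoy_lc_fraction if i % 2 == 0 else 0.0
        genes.append(GeneSpec(gid, make_decoy(length, lcf, rng, library, scheme)))
        decoy_ids.append(gid)

    # corruption plan: dragline (MaSp) genes first — the repair stage is
    # guided by their strong repeat grammar, as in the real assemblies
    corruption: dict[str, CorruptionRecord] = {}
    spidroin_ids = sorted((g.gene_id for g in genes if g.truth is not None),
                          key=lambda gid: (not gid.startswith("MaSp"), gid))
    k = 0
    for _ in range(config.n_indel):
        kind = "del" if k % 2 == 0 else "ins"
        corruption[spidroin_ids[k]] = CorruptionRecord(kind=kind, cds_pos=-1)
        k += 1
    for _ in range(config.n_truncated):
        corruption[spidroin_ids[k]] = CorruptionRecord(kind="truncate_C", cds_pos=-1)
        k += 1

    # chromosome plan
    plan: list[Placement] = []
    cursors = {f"chr{i + 1}": 0 for i in range(config.n_chromosomes)}
    chrom_names = sorted(cursors)
    if config.grouped_layout:
        groups = {"chr1": ["MaSp1a", "MaSp1b", "MaSp1c", "MaSp2e"],
                  "chr2": ["MaSp2a", "MaSp2b", "MaSp2c", "MaSp2d"],
                  "chr3": ["MiSpa", "MiSpb", "MiSpc", "MiSpd", "MiSpe"]}
        assignment = {gid: chrom for chrom, gids in groups.items() for gid in gids}
        for i, d in enumerate(decoy_ids):
            assignment[d] = chrom_names[i % len(chrom_names)]
    else:
        order = [g.gene_id for g in genes]
        assignment = {gid: chrom_names[i % len(chrom_names)]
                      for i, gid in enumerate(order)}
    for g in genes:
        chrom = assignment[g.gene_id]
        flank = int(rng.integers(config.flank[0], config.flank[1] + 1))
        start = cursors[chrom] + flank
        strand = "+" if rng.random() < 0.5 else "-"
        plan.append(Placement(g.gene_id, chrom, strand, start))
        cursors[chrom] = start + 3 * (len(g.protein) + 1) + 2  # indels may grow CDS by 1
    chromosomes, gff, proteome = embed_genes(genes, plan, rng, corruption)

    truths = [g.truth for g in genes if g.truth is not None]
    expr = make_expression(
        {**{t.gene_id: t.sptype for t in truths}, **{d: None for d in decoy_ids}},
        config.design, rng)
    provenance = {"seed": int(seed), "config_hash": config.hash()}
    return SyntheticGenomeBundle(chromosomes=chromosomes, gff=gff,
                                 proteome=proteome, truths=truths,
                                 decoy_ids=decoy_ids, expression=expr,
                                 provenance=provenance)


def read_bundle(indir) -> SyntheticGenomeBundle:
    """Re-load a written bundle (round-trip counterpart of ``write``)."""
    import pathlib
    d = pathlib.Path(indir)
    chromosomes = sio.read_fasta(d / "genome.fasta")
    gff = sio.read_gff3(d / "genes.gff3")
    proteome = sio.read_fasta(d / "proteome.fasta")
    truth = sio.read_tsv(d / "truth.tsv", keep_default_na=False)
    expr = sio.read_tsv(d / "expression.tsv", index_col=0)
    expr.index.name = None
    truths, decoy_ids = [], []
    for _, r in truth.iterrows():
        if r.sptype == "decoy":
            decoy_ids.append(r.gene_id)
            continue
        corr = None
        if r.corruption:
            kind, pos = r.corruption.split("@")
            corr = CorruptionRecord(kind=kind, cds_pos=int(pos))
        truths.append(SpidroinTruth(
            gene_id=r.gene_id, sptype=r.sptype, chromosome=r.chromosome,
            strand=r.strand, cds_start=int(r.cds_start), cds_end=int(r.cds_end),
            protein=r.protein, repeat_start=int(r.repeat_start),
            repeat_end=int(r.repeat_end), unit_length=int(r.unit_length),
            completeness=r.completeness, corruption=corr))
    provenance = json.loads((d / "provenance.json").read_text())
    return SyntheticGenomeBundle(chromosomes=chromosomes, gff=gff,
                                 proteome=proteome, truths=truths,
                                 decoy_ids=decoy_ids, expression=expr,
                                 provenance=provenance)
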