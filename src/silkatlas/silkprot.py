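"""Dragline-silk composition bookkeeping.

In-silico tryptic digestion, iBAQ quantification (summed intensity over
the count of theoretically observable tryptic peptides), abundance
shares, top-k cumulative abundance, and proteome / metabolome category
tallies.  Bundled fixtures carry the published dragline-silk protein
shares and metabolite category counts as worked inputs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

from ._alphabet import check_protein

SPIDROIN_CLASSES = ("MaSp", "MiSp")
IBAQ_MIN_LEN = 7  # aa; matches the minimal search peptide length
IBAQ_MAX_LEN = 30

_CLEAVE = re.compile(r"(?<=[KR])(?!P)")


@dataclass
class PeptideDigest:
    peptides: list[str]
    spans: list[tuple[int, int]]


@dataclass
class ProteinQuantRecord:
    protein_id: str
    cls: str  # MaSp | MiSp | SpiCE-DS | GDH | mucin-19 | venom protein | other
    intensity: float
    n_peptides: int = 0
    ibaq: float = 0.0
    share: float = 0.0  # percent of total iBAQ


@dataclass
class SilkProteomeCatalog:
    records: list[ProteinQuantRecord]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.records:
            counts[r.cls] = counts.get(r.cls, 0) + 1
        return dict(sorted(counts.items()))

    def spidroin_count(self) -> int:
        return sum(r.cls in SPIDROIN_CLASSES for r in self.records)


@dataclass
class MetaboliteCatalog:
    records: pd.DataFrame  # columns: name, category, intensity
    unclassified_label: str = ""


def tryptic_digest(protein: str) -> PeptideDigest:
    """Cleave after K or R except before P; zero missed cleavages."""
    check_protein(protein)
    peptides = [p for p in _CLEAVE.split(protein) if p]
    spans = []
    pos = 0
    for p in peptides:
        spans.append((pos, pos + len(p)))
        pos += len(p)
    return PeptideDigest(peptides=peptides, spans=spans)


def count_theoretical_peptides(digest: PeptideDigest,
                               min_len: int = IBAQ_MIN_LEN,
                               max_len: int = IBAQ_MAX_LEN) -> int:
    """Observable tryptic peptides: those with min_len <= length <= max_len."""
    return sum(min_len <= len(p) <= max_len for p in digest.peptides)


def ibaq_quantify(records: list[ProteinQuantRecord],
                  proteins: dict[str, str] | None = None) -> SilkProteomeCatalog:
    """iBAQ = intensity / max(1, theoretical peptide count); shares sum to 100.

    When ``proteins`` provides sequences, peptide counts come from the
    tryptic digest; otherwise any pre-set ``n_peptides`` are used.
    """
    if not records:
        raise ValueError("no records")
    if all(r.intensity <= 0 for r in records):
        raise ValueError("all intensities are zero")
    for r in records:
        if proteins and r.protein_id in proteins:
            r.n_peptides = count_theoretical_peptides(
                tryptic_digest(proteins[r.protein_id]))
        r.ibaq = r.intensity / max(1, r.n_peptides)
    total = sum(r.ibaq for r in records)
    for r in records:
        r.share = 100.0 * r.ibaq / total
    return SilkProteomeCatalog(records=list(records))


def topk_cumulative_share(catalog: SilkProteomeCatalog, k: int) -> float:
    """Sum of the k largest abundance shares, in percent."""
    if k > len(catalog.records):
        raise ValueError("k exceeds the record count")
    return float(sum(sorted((r.share for r in catalog.records), reverse=True)[:k]))


def tally_proteome(catalog: SilkProteomeCatalog) -> dict:
    counts = catalog.class_counts()
    spid = catalog.spidroin_count()
    return {"by_class": counts, "spidroin": spid,
            "nonspidroin": len(catalog.records) - spid,
            "total": len(catalog.records)}


def tally_metabolites(catalog: MetaboliteCatalog) -> dict:
    """Per-category counts, classified total and category count."""
    df = catalog.records
    mask = df["category"] != catalog.unclassified_label
    by_cat = (df.loc[mask, "category"].value_counts()
              .sort_index().to_dict())
    return {"by_category": by_cat,
            "classified": int(mask.sum()),
            "categories": len(by_cat),
            "total": len(df)}


# -- bundled worked-example fixtures -------------------------------------

def _fixture(name: str) -> pd.DataFrame:
    text = resources.files("silkatlas.data").joinpath(name).read_text()
    import io
    return pd.read_csv(io.StringIO(text), sep="\t")


def load_dragline_proteome() -> SilkProteomeCatalog:
    """The published dragline-silk protein catalog (28 proteins) with
    iBAQ-share-scaled intensities; the un-itemised remainder of the
    abundance is carried by the non-core records."""
    df = _fixture("dragline_proteome.tsv")
    records = [ProteinQuantRecord(protein_id=r.protein_id, cls=r["class"],
                                  intensity=float(r.intensity), n_peptides=1)
               for _, r in df.iterrows()]
    return ibaq_quantify(records)


def load_dragline_metabolites() -> MetaboliteCatalog:
    df = _fixture("dragline_metabolites.tsv")
    return MetaboliteCatalog(records=df.fillna({"category": ""}),
                             unclassified_label="")
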