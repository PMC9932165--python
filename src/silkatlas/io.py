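"""Readers and writers for the bundle's on-disk formats.

Genome and proteome go to FASTA (60-character wrap), gene models to GFF3
(1-based closed intervals, ``ID=`` attributes), truth and expression
tables to TSV.  All writers are deterministic: identical in-memory
objects yield identical bytes.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .align import ReferenceDomain


def format_fasta(records: dict[str, str], wrap: int = 60) -> str:
    out = []
    for name, seq in records.items():
        out.append(f">{name}")
        for i in range(0, len(seq), wrap):
            out.append(seq[i:i + wrap])
    return "\n".join(out) + "\n"


def write_fasta(path, records: dict[str, str]) -> None:
    with open(path, "w") as fh:
        fh.write(format_fasta(records))


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def read_fasta_str(text: str) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(_io.StringIO(text), "fasta")}


# -- reference terminal-domain library -----------------------------------

def format_reference_fasta(refs: list[ReferenceDomain]) -> str:
    recs = {f"{r.id} type={r.sptype} terminus={r.terminus}": r.sequence for r in refs}
    return format_fasta(recs)


def parse_reference_fasta(text: str) -> list[ReferenceDomain]:
    refs = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        tokens = dict(t.split("=", 1) for t in rec.description.split()[1:] if "=" in t)
        refs.append(ReferenceDomain(id=rec.id, sptype=tokens["type"],
                                    terminus=tokens["terminus"], sequence=str(rec.seq)))
    return refs


def read_reference_fasta(path) -> list[ReferenceDomain]:
    with open(path) as fh:
        return parse_reference_fasta(fh.read())


# -- GFF3 -----------------------------------------------------------------

@dataclass
class Gff3Record:
    seqid: str
    source: str
    ftype: str
    start: int  # 1-based closed
    end: int
    score: str
    strand: str
    phase: str
    attributes: dict[str, str]

    def line(self) -> str:
        attrs = ";".join(f"{k}={v}" for k, v in self.attributes.items())
        return "\t".join([self.seqid, self.source, self.ftype, str(self.start),
                          str(self.end), self.score, self.strand, self.phase, attrs])


def format_gff3(records: list[Gff3Record]) -> str:
    return "##gff-version 3\n" + "\n".join(r.line() for r in records) + "\n"


def parse_gff3(text: str) -> list[Gff3Record]:
    records = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        f = line.split("\t")
        if len(f) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if kv)
        records.append(Gff3Record(f[0], f[1], f[2], int(f[3]), int(f[4]),
                                  f[5], f[6], f[7], attrs))
    return records


def read_gff3(path) -> list[Gff3Record]:
    with open(path) as fh:
        return parse_gff3(fh.read())


# -- tables ---------------------------------------------------------------

def format_tsv(df: pd.DataFrame, index: bool = False) -> str:
    return df.to_csv(sep="\t", index=index)


def read_tsv(path, **kw) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", **kw)


def translate_cds(cds: str) -> str:
    """Translate a CDS; N-containing codons become X; keeps '*' stops."""
    n = len(cds) - len(cds) % 3
    return str(Seq(cds[:n]).translate())


def reverse_complement(seq: str) -> str:
    return str(Seq(seq).reverse_complement())
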