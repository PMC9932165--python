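"""Spidroin typing, catalog tallies and chromosomal grouping.

Types are assigned by a bit-score-weighted vote over terminal-domain
hits (a deterministic stand-in for tree-based classification), catalogs
are tallied per family and completeness, and co-located genes are
clustered into chromosome groups by single-linkage with a gap
threshold — the rule behind the grouped MaSp/MiSp arrangements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .align import LocalAlignment
from .grammar import superfamily


class ClassificationError(ValueError):
    pass


@dataclass
class SpidroinCall:
    gene_id: str
    sptype: str
    confidence: float  # winning-type bit share, in (0, 1]
    evidence: list[LocalAlignment] = field(default_factory=list)
    completeness: str = "full-length"


@dataclass
class SpidroinCatalog:
    species: str
    calls: list[SpidroinCall]

    def __post_init__(self):
        n = len(self.calls)
        assert sum(self.type_counts().values()) == n
        assert self.full_length_count() + self.partial_count() == n

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for c in self.calls:
            counts[c.sptype] = counts.get(c.sptype, 0) + 1
        return dict(sorted(counts.items()))

    def full_length_count(self) -> int:
        return sum(c.completeness == "full-length" for c in self.calls)

    def partial_count(self) -> int:
        return sum(c.completeness != "full-length" for c in self.calls)


@dataclass
class ChromosomeGroup:
    chromosome: str
    members: list[str]
    span: tuple[int, int]
    label: str  # dominant superfamily


def assign_type(hits: list[LocalAlignment], gene_id: str = "",
                completeness: str = "full-length") -> SpidroinCall:
    """Type = argmax over reference types of summed bit scores.

    Ties break to the highest single bit score, then to the type with
    C-terminus evidence, then to the lexicographically smallest name.
    """
    if not hits:
        raise ClassificationError(f"no hits for gene {gene_id!r}")
    summed: dict[str, float] = {}
    best_single: dict[str, float] = {}
    has_c: dict[str, bool] = {}
    for h in hits:
        summed[h.sptype] = summed.get(h.sptype, 0.0) + h.bits
        best_single[h.sptype] = max(best_single.get(h.sptype, 0.0), h.bits)
        has_c[h.sptype] = has_c.get(h.sptype, False) or h.terminus in ("C", "complete")
    winner = min(summed,
                 key=lambda t: (-summed[t], -best_single[t], not has_c[t], t))
    total = sum(summed.values())
    return SpidroinCall(gene_id=gene_id or (hits[0].query or ""),
                        sptype=winner, confidence=summed[winner] / total,
                        evidence=list(hits), completeness=completeness)


def tally_catalog(catalog: SpidroinCatalog) -> dict:
    """Per-type and per-completeness counts plus grand totals."""
    return {
        "species": catalog.species,
        "by_type": catalog.type_counts(),
        "full_length": catalog.full_length_count(),
        "partial": catalog.partial_count(),
        "total": len(catalog.calls),
    }


def detect_groups(catalog: SpidroinCatalog,
                  coordinates: dict[str, tuple[str, int, int]],
                  max_gap: int = 1_000_000, min_size: int = 3
                  ) -> list[ChromosomeGroup]:
    """Single-linkage chromosome clusters of spidroin genes.

    ``coordinates`` maps gene id -> (chromosome, start, end).  Adjacent
    genes join one cluster when the gap between their spans is at most
    ``max_gap``; clusters smaller than ``min_size`` are dropped.  The
    label is the superfamily of the majority (mixed membership allowed).
    """
    for c in catalog.calls:
        if c.gene_id not in coordinates:
            raise KeyError(f"no coordinates for gene {c.gene_id!r}")
    per_chrom: dict[str, list[tuple[int, int, SpidroinCall]]] = {}
    for c in catalog.calls:
        chrom, start, end = coordinates[c.gene_id]
        per_chrom.setdefault(chrom, []).append((start, end, c))
    groups: list[ChromosomeGroup] = []
    for chrom in sorted(per_chrom):
        genes = sorted(per_chrom[chrom], key=lambda g: (g[0], g[1]))
        cluster: list[tuple[int, int, SpidroinCall]] = []
        for g in genes:
            if cluster and g[0] - cluster[-1][1] > max_gap:
                groups.extend(_close_cluster(chrom, cluster, min_size))
                cluster = []
            cluster.append(g)
        groups.extend(_close_cluster(chrom, cluster, min_size))
    return groups


def _close_cluster(chrom: str, cluster, min_size: int) -> list[ChromosomeGroup]:
    if len(cluster) < min_size:
        return []
    fams = [superfamily(c.sptype) for _, _, c in cluster]
    label = max(sorted(set(fams)), key=fams.count)
    return [ChromosomeGroup(chromosome=chrom,
                            members=[c.gene_id for _, _, c in cluster],
                            span=(cluster[0][0], cluster[-1][1]), label=label)]


def compare_catalogs(catalogs: list[SpidroinCatalog]) -> pd.DataFrame:
    """Species x type count matrix; row order follows the input order."""
    if not catalogs:
        raise ValueError("need at least one catalog")
    rows = {c.species: c.type_counts() for c in catalogs}
    df = pd.DataFrame.from_dict(rows, orient="index").fillna(0).astype(int)
    return df[sorted(df.columns)]
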