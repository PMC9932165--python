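"""End-to-end discovery pipeline and truth-table evaluation.

Glue over the individual stages: proteome homology search ->
architecture calls -> type assignment -> genomic reconstruction ->
chromosome grouping, plus precision/recall style evaluation against a
synthetic bundle's ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

from .align import (E_SPIDROIN, LocalAlignment, ReferenceDomain, ScoringScheme,
                    collapse_nonredundant, hits_by_query, search)
from .assembly import LocusModel, assemble_loci
from .catalog import SpidroinCall, SpidroinCatalog, assign_type, detect_groups
from .repeats import ArchitectureCall, call_architecture, find_repeat_region
from .synthetic import SyntheticGenomeBundle


@dataclass
class DiscoveryResult:
    hits: list[LocalAlignment]
    nonredundant: list[LocalAlignment]
    architectures: dict[str, ArchitectureCall]
    calls: list[SpidroinCall]

    def called_ids(self) -> set[str]:
        return {c.gene_id for c in self.calls}


def discover(proteome: dict[str, str], refdb: list[ReferenceDomain],
             scheme: ScoringScheme | None = None,
             e_max: float = E_SPIDROIN) -> DiscoveryResult:
    """Find and type spidroin candidates in a proteome.

    Candidates are proteome entries with at least one terminal-domain
    hit below ``e_max`` whose architecture call is not non-spidroin.
    """
    hits = search(proteome, refdb, scheme, e_max)
    nonred = collapse_nonredundant(hits)
    per_gene = hits_by_query(hits)
    architectures: dict[str, ArchitectureCall] = {}
    calls: list[SpidroinCall] = []
    for gid, gene_hits in per_gene.items():
        protein = proteome[gid]
        repeat = find_repeat_region(protein)
        arch = call_architecture(protein, gene_hits, repeat)
        architectures[gid] = arch
        if arch.classification == "non-spidroin":
            continue
        calls.append(assign_type(gene_hits, gene_id=gid,
                                 completeness=arch.classification))
    calls.sort(key=lambda c: c.gene_id)
    return DiscoveryResult(hits=hits, nonredundant=nonred,
                           architectures=architectures, calls=calls)


def catalog_from_discovery(result: DiscoveryResult,
                           species: str = "synthetic") -> SpidroinCatalog:
    return SpidroinCatalog(species=species, calls=result.calls)


# ---------------------------------------------------------------- evaluation

def identity(a: str, b: str) -> float:
    """Edit-distance identity between two proteins, in [0, 1]."""
    if not a or not b:
        return 0.0
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


@dataclass
class RecoveryReport:
    true_positives: int
    false_positives: int
    false_negatives: int
    type_correct: int
    completeness_correct: int
    n_loci: int
    repair_identities: list[float] = field(default_factory=list)
    decoy_loci: int = 0

    @property
    def precision(self) -> float:
        called = self.true_positives + self.false_positives
        return self.true_positives / called if called else 0.0

    @property
    def recall(self) -> float:
        truths = self.true_positives + self.false_negatives
        return self.true_positives / truths if truths else 0.0


def evaluate_discovery(result: DiscoveryResult,
                       bundle: SyntheticGenomeBundle) -> RecoveryReport:
    """Precision/recall of spidroin calls and type agreement vs truth."""
    truth = {t.gene_id: t for t in bundle.truths}
    called = result.called_ids()
    tp = sum(1 for g in called if g in truth)
    fp = len(called) - tp
    fn = sum(1 for g in truth if g not in called)
    type_ok = sum(1 for c in result.calls
                  if c.gene_id in truth and c.sptype == truth[c.gene_id].sptype)
    return RecoveryReport(true_positives=tp, false_positives=fp,
                          false_negatives=fn, type_correct=type_ok,
                          completeness_correct=0, n_loci=0)


def evaluate_assembly(models: list[LocusModel],
                      bundle: SyntheticGenomeBundle) -> RecoveryReport:
    """Match reconstructed loci to truth genes by genomic overlap and
    score completeness agreement and indel-repair identity."""
    tp = fp = comp_ok = decoys = 0
    matched: set[str] = set()
    repair_idents: list[float] = []
    for m in models:
        match = None
        for t in bundle.truths:
            if (t.chromosome == m.chromosome
                    and min(t.cds_end, m.end) - max(t.cds_start, m.start) > 0):
                match = t
                break
        if match is None:
            fp += 1
            decoys += 1
            continue
        tp += 1
        matched.add(match.gene_id)
        if m.completeness == match.completeness and not m.unresolved:
            comp_ok += 1
        if match.corruption is not None and match.corruption.kind in ("del", "ins"):
            repair_idents.append(identity(m.protein, match.protein))
    fn = len(bundle.truths) - len(matched)
    return RecoveryReport(true_positives=tp, false_positives=fp,
                          false_negatives=fn, type_correct=0,
                          completeness_correct=comp_ok, n_loci=len(models),
                          repair_identities=repair_idents, decoy_loci=decoys)


def recover_groups(bundle: SyntheticGenomeBundle, result: DiscoveryResult,
                   max_gap: int = 1_000_000, min_size: int = 3):
    """Chromosome groups of the called spidroins at truth coordinates."""
    coords = {t.gene_id: (t.chromosome, t.cds_start, t.cds_end)
              for t in bundle.truths}
    calls = [c for c in result.calls if c.gene_id in coords]
    cat = SpidroinCatalog(species="synthetic", calls=calls)
    return detect_groups(cat, coords, max_gap=max_gap, min_size=min_size)
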