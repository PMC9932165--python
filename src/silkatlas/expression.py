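"""Gland and segment expression analytics.

FPKM computation, the tau tissue-specificity index, silk transcriptional
load (the fraction of a segment's total FPKM contributed by silk genes),
segment-specific gene screening, pairwise segment correlation, and the
evidence-based annotation-integration filter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import tissue_of

TAU_SPECIFIC = 0.8  # tau at or above which a gene is reported gland-specific


@dataclass
class SpecificityCall:
    gene_id: str
    tau: float
    argmax_tissue: str
    specific: bool


def fpkm(counts: pd.DataFrame, lengths: pd.Series,
         library_sizes: pd.Series) -> pd.DataFrame:
    """FPKM = counts * 1e9 / (length * library size).

    ``lengths`` are effective transcript lengths in nt (index = genes);
    ``library_sizes`` are mapped-fragment totals (index = samples).
    """
    lengths = lengths.reindex(counts.index)
    library_sizes = library_sizes.reindex(counts.columns)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if (library_sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e9 / np.outer(lengths, library_sizes)


def tissue_means(matrix: pd.DataFrame) -> pd.DataFrame:
    """Average replicate columns (labelled ``sample:tissue``) per tissue."""
    groups = {}
    for col in matrix.columns:
        groups.setdefault(tissue_of(col), []).append(col)
    return pd.DataFrame({t: matrix[cols].mean(axis=1)
                         for t, cols in groups.items()})


def tau_specificity(row: pd.Series, threshold: float = TAU_SPECIFIC
                    ) -> SpecificityCall:
    """Tissue-specificity index tau = sum(1 - x_i/x_max) / (N - 1).

    0 for uniform expression, 1 for single-tissue expression; computed
    over per-tissue mean FPKM.
    """
    if len(row) < 2:
        raise ValueError("tau needs at least two tissues")
    x = row.to_numpy(dtype=float)
    xmax = x.max()
    if xmax <= 0:
        raise ValueError("tau undefined for an all-zero profile")
    tau = float(np.sum(1 - x / xmax) / (len(x) - 1))
    arg = str(row.idxmax())
    return SpecificityCall(gene_id=str(row.name), tau=tau, argmax_tissue=arg,
                           specific=tau >= threshold)


def silk_load(matrix: pd.DataFrame, silk_ids: list[str], segment: str) -> float:
    """Fraction of total FPKM in `segment` samples carried by silk genes."""
    missing = set(silk_ids) - set(matrix.index)
    if missing:
        raise KeyError(f"silk ids not in matrix: {sorted(missing)}")
    cols = [c for c in matrix.columns if tissue_of(c) == segment]
    if not cols:
        raise ValueError(f"no samples for segment {segment!r}")
    total = float(matrix[cols].to_numpy().sum())
    silk = float(matrix.loc[silk_ids, cols].to_numpy().sum())
    return silk / total


def segment_specific_genes(matrix: pd.DataFrame, segments: list[str],
                           min_fpkm: float = 1.0, min_fold: float = 4.0
                           ) -> dict[str, list[str]]:
    """Screen for segment-specific genes.

    A gene is specific to a segment when its mean FPKM there is at least
    ``min_fpkm`` and at least ``min_fold`` times its mean in every other
    segment.
    """
    if len(segments) < 2:
        raise ValueError("need at least two segments")
    means = tissue_means(matrix)[segments]
    out: dict[str, list[str]] = {s: [] for s in segments}
    for s in segments:
        others = [t for t in segments if t != s]
        focal = means[s]
        ok = (focal >= min_fpkm)
        for t in others:
            ok &= focal >= min_fold * means[t]
        out[s] = list(means.index[ok])
    return out


def segment_correlation(matrix: pd.DataFrame, segments: list[str] | None = None
                        ) -> pd.DataFrame:
    """Pairwise Pearson r between per-segment mean expression profiles."""
    if len(matrix) < 2:
        raise ValueError("need at least two genes")
    means = tissue_means(matrix)
    if segments is not None:
        means = means[segments]
    return means.corr(method="pearson")


# -- annotation-integration filter ---------------------------------------

FILTER_FIELDS = ("repeat_proportion", "protein_length", "expressed_samples",
                 "isoseq_identity", "homolog_evalue", "homolog_identity")


def integration_filter(evidence: pd.DataFrame,
                       max_repeat: float = 0.5, min_length: int = 50,
                       min_samples: int = 10, min_isoseq: float = 95.0,
                       max_homolog_e: float = 1e-5,
                       min_homolog_identity: float = 50.0) -> pd.DataFrame:
    """Keep/drop decisions for candidate gene models.

    A model is kept iff its repeat-sequence proportion is below
    ``max_repeat`` AND its protein is longer than ``min_length`` aa AND
    it is expressed (FPKM > 0.1) in at least ``min_samples`` samples AND
    it has transcript support (Iso-seq identity above ``min_isoseq``) or
    a cross-species homolog (E-value below ``max_homolog_e`` and
    identity above ``min_homolog_identity``).  All inequalities are
    strict except the sample count; a drop carries the first failing
    reason code among repeat / length / expression / support.
    """
    missing = [f for f in FILTER_FIELDS if f not in evidence.columns]
    if missing:
        raise KeyError(f"evidence table missing fields: {missing}")
    for gid, row in evidence.iterrows():
        if row[list(FILTER_FIELDS)].isna().any():
            bad = [f for f in FILTER_FIELDS if pd.isna(row[f])]
            raise ValueError(f"gene {gid!r}: missing value for {bad[0]!r}")
    decisions = []
    for gid, row in evidence.iterrows():
        if not row.repeat_proportion < max_repeat:
            verdict = ("drop", "repeat")
        elif not row.protein_length > min_length:
            verdict = ("drop", "length")
        elif not row.expressed_samples >= min_samples:
            verdict = ("drop", "expression")
        elif not (row.isoseq_identity > min_isoseq
                  or (row.homolog_evalue < max_homolog_e
                      and row.homolog_identity > min_homolog_identity)):
            verdict = ("drop", "support")
        else:
            verdict = ("keep", "")
        decisions.append({"gene_id": gid, "decision": verdict[0],
                          "reason": verdict[1]})
    return pd.DataFrame(decisions).set_index("gene_id")
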