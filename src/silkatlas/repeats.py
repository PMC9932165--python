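"""Tandem-repeat detection and silk motif grammar quantification.

The tri-partite spidroin architecture — a long tandem-repeat array
sandwiched between nonrepetitive N- and C-terminal domains — is called
from two signals: self-alignment periodicity (the repeat array matches
itself when shifted by its unit length) and terminal-domain homology
hits near the sequence ends.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from ._alphabet import check_protein

TERMINAL_WINDOW = 250  # residues from either end in which a terminus hit must fall


class InsufficientLengthError(ValueError):
    pass


class EmptyInputError(ValueError):
    pass


@dataclass
class PeriodicityProfile:
    """Self-match fraction m(l) per lag l."""

    lags: np.ndarray
    match_fraction: np.ndarray

    def best_lag(self, rel_tol: float = 0.05) -> int:
        """Smallest lag within `rel_tol` of the global maximum of m(l).

        Preferring the smallest near-maximal lag picks the fundamental
        period over its multiples.
        """
        peak = float(self.match_fraction.max())
        ok = self.match_fraction >= (1.0 - rel_tol) * peak
        return int(self.lags[ok][0])


@dataclass
class RepeatRegion:
    """Detected tandem-repeat span in protein coordinates (0-based, half-open)."""

    start: int
    end: int
    unit_length: int
    copy_number: float
    consensus: str


@dataclass
class MotifCounts:
    """Tallies of the canonical silk motifs in one sequence.

    Classes are counted independently of each other; within a class,
    matches are maximal and non-overlapping, scanned left to right.
    """

    ga_arrays: int = 0
    polyA_runs: int = 0
    polyA_residues: int = 0
    ggx: int = 0
    gpgxx: int = 0
    xqq: int = 0
    coverage: float = 0.0

    def __add__(self, o: "MotifCounts") -> "MotifCounts":
        return MotifCounts(self.ga_arrays + o.ga_arrays,
                           self.polyA_runs + o.polyA_runs,
                           self.polyA_residues + o.polyA_residues,
                           self.ggx + o.ggx, self.gpgxx + o.gpgxx,
                           self.xqq + o.xqq)

    def as_dict(self) -> dict[str, float]:
        return {"ga_arrays": self.ga_arrays, "polyA_runs": self.polyA_runs,
                "polyA_residues": self.polyA_residues, "ggx": self.ggx,
                "gpgxx": self.gpgxx, "xqq": self.xqq, "coverage": self.coverage}


@dataclass
class ArchitectureCall:
    has_N: bool
    has_C: bool
    has_repeat: bool
    classification: str  # full-length | partial | non-spidroin
    evidence_hits: list = field(default_factory=list)
    repeat: RepeatRegion | None = None


def periodicity(seq: str, min_lag: int = 5, max_lag: int = 200) -> PeriodicityProfile:
    """m(l) = |{i: seq[i] == seq[i+l]}| / (len - l) for each lag."""
    if len(seq) <= 2 * min_lag:
        raise InsufficientLengthError(
            f"sequence of length {len(seq)} too short for min_lag {min_lag}")
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    hi = min(max_lag, len(seq) - 1)
    lags = np.arange(min_lag, hi + 1)
    frac = np.array([float(np.mean(arr[:-l] == arr[l:])) for l in lags])
    return PeriodicityProfile(lags=lags, match_fraction=frac)


def find_repeat_region(seq: str, profile: PeriodicityProfile | None = None,
                       theta: float = 0.5, min_lag: int = 5,
                       max_lag: int = 200) -> RepeatRegion | None:
    """Locate the maximal tandem-repeat span, or None.

    The unit length l* is the fundamental period from the profile; the
    region is the maximal run of positions whose shifted-match fraction
    over a 2·l* window is at least `theta`.  A valid region spans at
    least two units.
    """
    if profile is None:
        try:
            profile = periodicity(seq, min_lag, max_lag)
        except InsufficientLengthError:
            return None
    unit = profile.best_lag()
    n = len(seq)
    if n < 2 * unit:
        return None
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    eq = (arr[:-unit] == arr[unit:]).astype(np.int32)
    # score(i): match fraction of seq[i:i+unit] against seq[i+unit:i+2*unit]
    c = np.concatenate([[0], np.cumsum(eq)])
    n_scores = n - 2 * unit + 1
    scores = (c[unit:unit + n_scores] - c[:n_scores]) / unit
    good = scores >= theta
    if not good.any():
        return None
    # maximal run of qualifying window starts
    best_len = best_start = -1
    i = 0
    while i < n_scores:
        if good[i]:
            j = i
            while j < n_scores and good[j]:
                j += 1
            if j - i > best_len:
                best_len, best_start = j - i, i
            i = j
        else:
            i += 1
    start, end = best_start, best_start + best_len - 1 + 2 * unit
    # refine edges at residue resolution: a window threshold of theta lets
    # flanking domain residues bleed up to unit/2 into the region.  An edge
    # residue stays only if it and most of its 5-residue block match at the
    # unit lag (single chance matches inside a domain do not stop the trim).
    def _left_ok(i: int) -> bool:
        block = sum(seq[i + t] == seq[i + t + unit]
                    for t in range(min(5, len(seq) - i - unit)))
        return seq[i] == seq[i + unit] and block >= 3

    def _right_ok(i: int) -> bool:  # i: last residue of the region
        block = sum(seq[i - t] == seq[i - t - unit]
                    for t in range(min(5, i - unit + 1)))
        return seq[i] == seq[i - unit] and block >= 3

    while start < end - 2 * unit and not _left_ok(start):
        start += 1
    while end - start > 2 * unit and not _right_ok(end - 1):
        end -= 1
    if end - start < 2 * unit:
        return None
    consensus = _consensus(seq[start:end], unit)
    return RepeatRegion(start=start, end=end, unit_length=unit,
                        copy_number=(end - start) / unit, consensus=consensus)


def _consensus(region: str, unit: int) -> str:
    """Column-wise majority over unit-sized slices (ties -> alphabetical)."""
    cols: list[dict[str, int]] = [dict() for _ in range(unit)]
    for i, ch in enumerate(region):
        d = cols[i % unit]
        d[ch] = d.get(ch, 0) + 1
    return "".join(sorted(d, key=lambda k: (-d[k], k))[0] for d in cols)


# -- motif grammar tallies ------------------------------------------------

_PATTERNS = {
    "polyA": re.compile(r"A{4,}"),
    "GA": re.compile(r"(?:GA){2,}"),
    "GGX": re.compile(r"GG."),
    "GPGXX": re.compile(r"GPG.."),
    "XQQ": re.compile(r".QQ"),
}


def count_motifs(seq: str) -> MotifCounts:
    """Count (A)n, (GA)n, GGX, GPGXX and XQQ motifs.

    Each class is scanned independently; within a class matches are
    maximal and non-overlapping, left to right.  (A)n requires runs of
    at least 4 alanines; (GA)n at least 2 consecutive dyads.
    """
    check_protein(seq) if seq else None
    counts = MotifCounts()
    covered = np.zeros(len(seq), dtype=bool)
    for name, pat in _PATTERNS.items():
        for m in pat.finditer(seq):
            covered[m.start():m.end()] = True
            if name == "polyA":
                counts.polyA_runs += 1
                counts.polyA_residues += m.end() - m.start()
            elif name == "GA":
                counts.ga_arrays += 1
            elif name == "GGX":
                counts.ggx += 1
            elif name == "GPGXX":
                counts.gpgxx += 1
            else:
                counts.xqq += 1
    counts.coverage = float(covered.mean()) if len(seq) else 0.0
    return counts


def motif_coverage(seq: str) -> float:
    """Fraction of positions covered by any silk motif (repair objective)."""
    if not seq:
        return 0.0
    covered = np.zeros(len(seq), dtype=bool)
    for pat in _PATTERNS.values():
        for m in pat.finditer(seq):
            covered[m.start():m.end()] = True
    return float(covered.mean())


def composition(seq: str) -> dict[str, float]:
    """Per-residue fraction over the 20 amino acids."""
    if not seq:
        raise EmptyInputError("cannot profile an empty sequence")
    check_protein(seq)
    n = len(seq)
    from ._alphabet import AMINO_ACIDS
    return {aa: seq.count(aa) / n for aa in AMINO_ACIDS}


def call_architecture(protein: str, hits: list, repeat: RepeatRegion | None,
                      terminal_window: int = TERMINAL_WINDOW) -> ArchitectureCall:
    """Call the tri-partite architecture of one candidate.

    has_N: an N-terminus (or complete) reference hit starting within the
    first `terminal_window` residues; has_C symmetric at the tail.
    full-length needs N + repeat + C; partial needs the repeat plus
    exactly one terminus; anything else is non-spidroin.
    """
    n = len(protein)
    has_N = any(h.terminus in ("N", "complete") and h.qspan[0] < terminal_window
                for h in hits)
    has_C = any(h.terminus in ("C", "complete") and h.qspan[1] > n - terminal_window
                for h in hits)
    has_repeat = repeat is not None
    if has_N and has_C and has_repeat:
        cls = "full-length"
    elif has_repeat and (has_N ^ has_C):
        cls = "partial"
    else:
        cls = "non-spidroin"
    return ArchitectureCall(has_N=has_N, has_C=has_C, has_repeat=has_repeat,
                            classification=cls, evidence_hits=list(hits),
                            repeat=repeat)
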