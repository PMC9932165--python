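"""Silk repeat-unit grammar.

Spidroin repeat regions are concatenations of a small set of canonical
motifs — poly-alanine runs, (GA)n dyad arrays, GGX, GPGXX and XQQ — joined
by single "spacer" residues.  A :class:`MotifGrammar` assigns an emission
weight to each motif class plus distributions for run lengths, dyad counts
and spacer/X residues; drawing motifs until a target unit length is reached
yields one repeat unit.  Tandem copies of that unit (the biological arrays
are strongly homogenised) form the repeat region of a synthetic spidroin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: canonical motif classes, in emission order
MOTIF_CLASSES = ("polyA", "GA", "GGX", "GPGXX", "XQQ", "spacer")


class GrammarError(ValueError):
    """Invalid grammar configuration (e.g. all emission weights zero)."""


def _freq_tuple(d: dict[str, float]) -> tuple[tuple[str, float], ...]:
    return tuple(sorted(d.items()))


@dataclass(frozen=True)
class MotifGrammar:
    """Emission model for one spidroin repeat unit.

    Parameters
    ----------
    weights : mapping of motif class -> non-negative emission weight.
    polyA_len : inclusive (min, max) poly-alanine run length, min >= 4.
    ga_dyads : inclusive (min, max) number of GA dyads per array, min >= 2.
    spacer_freqs : residue -> weight for single spacer emissions.
    x_freqs : residue -> weight for the "X" positions of GGX/GPGXX/XQQ.
    unit_len : inclusive (min, max) length bounds of one repeat unit.
    """

    weights: dict[str, float]
    polyA_len: tuple[int, int] = (4, 10)
    ga_dyads: tuple[int, int] = (2, 5)
    spacer_freqs: dict[str, float] = field(
        default_factory=lambda: {"G": 2.0, "S": 2.0, "Q": 1.0, "Y": 1.0, "A": 1.0}
    )
    x_freqs: dict[str, float] = field(
        default_factory=lambda: {"Q": 2.0, "Y": 1.5, "L": 1.0, "S": 1.0, "A": 1.0, "G": 1.0}
    )
    unit_len: tuple[int, int] = (24, 40)

    def __post_init__(self):
        unknown = set(self.weights) - set(MOTIF_CLASSES)
        if unknown:
            raise GrammarError(f"unknown motif classes: {sorted(unknown)}")
        if any(w < 0 for w in self.weights.values()):
            raise GrammarError("motif weights must be non-negative")
        if not any(w > 0 for w in self.weights.values()):
            raise GrammarError("at least one motif weight must be positive")
        if self.polyA_len[0] < 4:
            raise GrammarError("poly-A run length minimum is 4")
        if self.ga_dyads[0] < 2:
            raise GrammarError("(GA)n arrays need at least 2 dyads")
        if self.unit_len[0] < 1 or self.unit_len[1] < self.unit_len[0]:
            raise GrammarError("invalid unit length bounds")

    # -- sampling -----------------------------------------------------

    def _classes_and_probs(self) -> tuple[list[str], np.ndarray]:
        classes = [c for c in MOTIF_CLASSES if self.weights.get(c, 0.0) > 0]
        p = np.array([self.weights[c] for c in classes], dtype=float)
        return classes, p / p.sum()

    def _draw_residue(self, freqs: dict[str, float], rng: np.random.Generator) -> str:
        residues, w = zip(*_freq_tuple(freqs))
        p = np.asarray(w, dtype=float)
        return rng.choice(list(residues), p=p / p.sum())

    def emit_motif(self, cls: str, rng: np.random.Generator) -> str:
        if cls == "polyA":
            return "A" * int(rng.integers(self.polyA_len[0], self.polyA_len[1] + 1))
        if cls == "GA":
            return "GA" * int(rng.integers(self.ga_dyads[0], self.ga_dyads[1] + 1))
        if cls == "GGX":
            return "GG" + self._draw_residue(self.x_freqs, rng)
        if cls == "GPGXX":
            return "GPG" + "".join(self._draw_residue(self.x_freqs, rng) for _ in range(2))
        if cls == "XQQ":
            return self._draw_residue(self.x_freqs, rng) + "QQ"
        if cls == "spacer":
            return self._draw_residue(self.spacer_freqs, rng)
        raise GrammarError(f"unknown motif class {cls!r}")

    # -- expectations (used for composition sanity checks) -----------

    def motif_length_expectation(self, cls: str) -> float:
        if cls == "polyA":
            return (self.polyA_len[0] + self.polyA_len[1]) / 2
        if cls == "GA":
            return 2 * (self.ga_dyads[0] + self.ga_dyads[1]) / 2
        return {"GGX": 3.0, "GPGXX": 5.0, "XQQ": 3.0, "spacer": 1.0}[cls]

    def motif_residue_expectation(self, cls: str, residue: str) -> float:
        """Expected count of `residue` in one emission of class `cls`."""

        def freq(d: dict[str, float], r: str) -> float:
            tot = sum(d.values())
            return d.get(r, 0.0) / tot

        x = freq(self.x_freqs, residue)
        s = freq(self.spacer_freqs, residue)
        if cls == "polyA":
            return self.motif_length_expectation(cls) if residue == "A" else 0.0
        if cls == "GA":
            half = self.motif_length_expectation(cls) / 2
            return half if residue in "GA" else 0.0
        if cls == "GGX":
            return (2.0 if residue == "G" else 0.0) + x
        if cls == "GPGXX":
            fixed = {"G": 2.0, "P": 1.0}.get(residue, 0.0)
            return fixed + 2 * x
        if cls == "XQQ":
            return (2.0 if residue == "Q" else 0.0) + x
        if cls == "spacer":
            return s
        raise GrammarError(f"unknown motif class {cls!r}")

    def expected_fraction(self, residue: str) -> float:
        """Renewal-reward expectation of the residue fraction in long units."""
        classes, p = self._classes_and_probs()
        num = sum(pi * self.motif_residue_expectation(c, residue) for c, pi in zip(classes, p))
        den = sum(pi * self.motif_length_expectation(c) for c, pi in zip(classes, p))
        return num / den


def make_repeat_unit(grammar: MotifGrammar, rng: np.random.Generator, max_tries: int = 1000) -> str:
    """Draw one repeat unit: motif emissions concatenated until the length
    falls inside ``grammar.unit_len`` (rejection-sampled on overshoot)."""
    lo, hi = grammar.unit_len
    classes, p = grammar._classes_and_probs()
    for _ in range(max_tries):
        parts: list[str] = []
        n = 0
        while n < lo:
            cls = classes[int(rng.choice(len(classes), p=p))]
            m = grammar.emit_motif(cls, rng)
            parts.append(m)
            n += len(m)
        if n <= hi:
            return "".join(parts)
    raise GrammarError(
        f"could not sample a unit within length bounds {grammar.unit_len} "
        f"in {max_tries} tries"
    )


# Per-family default grammars.  MaSp1 is GGX/poly-A dominated, MaSp2 carries
# the proline-rich GPGXX blocks, MiSp is (GA)n/GGX rich, FlSp is almost pure
# GPGXX, and the remaining families are more serine/glutamine rich with fewer
# canonical motifs — a caricature of the published repeat chemistries.
_BASE = MotifGrammar(weights={"spacer": 1.0})

DEFAULT_GRAMMARS: dict[str, MotifGrammar] = {
    "MaSp1": replace(_BASE, weights={"polyA": 0.22, "GA": 0.08, "GGX": 0.50, "XQQ": 0.05, "spacer": 0.15}),
    "MaSp2": replace(_BASE, weights={"polyA": 0.25, "GPGXX": 0.45, "GGX": 0.05, "XQQ": 0.10, "spacer": 0.15}),
    "MiSp": replace(_BASE, weights={"GA": 0.40, "GGX": 0.30, "polyA": 0.10, "spacer": 0.20}),
    "FlSp": replace(_BASE, weights={"GPGXX": 0.65, "GGX": 0.10, "XQQ": 0.05, "spacer": 0.20}),
    "TuSp": replace(_BASE, weights={"polyA": 0.10, "XQQ": 0.15, "spacer": 0.75},
                    spacer_freqs={"S": 3.0, "A": 2.0, "Q": 1.5, "T": 1.0, "V": 1.0}),
    "AgSp": replace(_BASE, weights={"XQQ": 0.25, "GGX": 0.10, "spacer": 0.65},
                    spacer_freqs={"G": 1.0, "S": 2.0, "Q": 2.0, "T": 1.5, "P": 1.0}),
    "AcSp": replace(_BASE, weights={"spacer": 0.85, "XQQ": 0.05, "polyA": 0.10},
                    spacer_freqs={"S": 2.5, "A": 1.5, "Q": 1.0, "L": 1.0, "T": 1.0, "V": 0.5}),
    "PySp": replace(_BASE, weights={"XQQ": 0.20, "polyA": 0.10, "spacer": 0.70},
                    spacer_freqs={"A": 2.0, "Q": 2.0, "S": 1.5, "P": 1.0, "E": 0.5}),
    "other": replace(_BASE, weights={"GGX": 0.20, "GPGXX": 0.15, "polyA": 0.10, "spacer": 0.55},
                     spacer_freqs={"G": 2.0, "P": 1.5, "S": 1.0, "Q": 1.0, "A": 1.0}),
}

#: canonical spidroin family names (truth-table vocabulary)
SPIDROIN_TYPES = tuple(DEFAULT_GRAMMARS)


def superfamily(sptype: str) -> str:
    """Collapse subtype names to their gland superfamily (MaSp1 -> MaSp)."""
    return sptype.rstrip("0123456789")
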