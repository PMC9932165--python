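"""Residue and nucleotide alphabets shared across the package."""

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# B/Z/X are accepted in alignment input and scored through the matrix.
AMBIGUOUS = "BZX"

PROTEIN_ALPHABET = frozenset(AMINO_ACIDS + AMBIGUOUS)

NUCLEOTIDES = frozenset("ACGTN")

STOP = "*"


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside its alphabet."""


def check_protein(seq: str, allow_stop: bool = False) -> str:
    allowed = PROTEIN_ALPHABET | {STOP} if allow_stop else PROTEIN_ALPHABET
    for ch in seq:
        if ch not in allowed:
            raise AlphabetError(f"invalid residue {ch!r} in protein sequence")
    return seq

def check_nucleotide(seq: str) -> str:
    for ch in seq:
        if ch not in NUCLEOTIDES:
            raise AlphabetError(f"invalid base {ch!r} in nucleotide sequence")
    return seq
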