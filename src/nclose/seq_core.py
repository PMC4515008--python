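"""Nucleotide-sequence primitives.

Sequences are plain Python strings over the uppercase nucleotide alphabet
``ACGTN`` plus the eleven IUPAC ambiguity codes.  K-mers are ACGT-only
strings; their strand-neutral identity is the *canonical* form, the
lexicographically smaller of a k-mer and its reverse complement.
"""

from __future__ import annotations

from typing import Iterator

#: IUPAC single-letter code -> the set of plain bases it denotes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Inverse of IUPAC_SETS: base set -> code.
_SET_TO_CODE: dict[frozenset[str], str] = {v: k for k, v in IUPAC_SETS.items()}

#: Complement table covering the full IUPAC alphabet (R<->Y, K<->M, S and W
#: are self-complementary, B<->V, D<->H, N<->N).
COMPLEMENT: dict[str, str] = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

_COMP_TABLE = str.maketrans(COMPLEMENT)

ALPHABET = frozenset(COMPLEMENT)

_ACGT = frozenset("ACGT")


class SequenceAlphabetError(ValueError):
    """A sequence contains a character outside the IUPAC nucleotide alphabet."""


def _check_alphabet(s: str) -> None:
    for i, c in enumerate(s):
        if c not in ALPHABET:
            raise SequenceAlphabetError(
                f"invalid nucleotide character {c!r} at position {i}"
            )


def reverse_complement(s: str) -> str:
    """Reverse complement of *s*; IUPAC codes map to their complements.

    Raises :class:`SequenceAlphabetError` naming the offending character and
    position if *s* contains anything outside the IUPAC alphabet.
    """
    if not _ACGT.issuperset(s):  # fast path: plain sequences skip the scan
        _check_alphabet(s)
    return s.translate(_COMP_TABLE)[::-1]


def canonical(kmer: str) -> str:
    """Strand-neutral form of an ACGT-only k-mer.

    Returns the lexicographically smaller of the k-mer and its reverse
    complement, so that ``canonical(x) == canonical(reverse_complement(x))``.
    """
    rc = reverse_complement(kmer)
    return kmer if kmer <= rc else rc


def extract_kmers(s: str, k: int) -> Iterator[str]:
    """Yield every length-*k* window of *s* made of plain A/C/G/T bases.

    Windows overlapping N or any ambiguity code are skipped.  Yields the
    stranded (non-canonical) form in left-to-right order; callers
    canonicalize as needed.  ``k > len(s)`` yields nothing.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    # `good` marks the next position at which a clean window could start.
    good = 0
    for i, c in enumerate(s):
        if c not in _ACGT:
            good = i + 1
        elif i - good + 1 >= k:
            yield s[i - k + 1 : i + 1]


def iupac_merge(bases: set[str] | frozenset[str]) -> str:
    """The unique IUPAC code whose base set equals *bases*.

    *bases* must be a non-empty subset of {A, C, G, T}; a singleton maps to
    the base itself and the full set maps to N.
    """
    key = frozenset(bases)
    if not key:
        raise ValueError("cannot merge an empty base set")
    if not key <= _ACGT:
        raise ValueError(f"base set {sorted(key)} is not a subset of ACGT")
    return _SET_TO_CODE[key]


def iupac_compatible(query: str, base: str) -> bool:
    """True if *base* is one of the nucleotides that *query* may stand for."""
    return base in IUPAC_SETS[query]
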