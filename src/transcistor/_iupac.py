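"""IUPAC degenerate nucleotide codes and small sequence helpers.

All sequences handled by this package are upper-case DNA over the 15
informative IUPAC codes (no gaps, no U, no X).
"""

from __future__ import annotations

from itertools import product
from typing import Iterable

#: code -> set of concrete bases it stands for
IUPAC_TO_BASES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "M": frozenset("AC"),
    "R": frozenset("AG"),
    "W": frozenset("AT"),
    "S": frozenset("CG"),
    "Y": frozenset("CT"),
    "K": frozenset("GT"),
    "V": frozenset("ACG"),
    "H": frozenset("ACT"),
    "D": frozenset("AGT"),
    "B": frozenset("CGT"),
    "N": frozenset("ACGT"),
}

#: minimal code covering exactly a base set
BASES_TO_IUPAC: dict[frozenset[str], str] = {v: k for k, v in IUPAC_TO_BASES.items()}

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}

CONCRETE = frozenset("ACGT")


def bases_of(code: str) -> frozenset[str]:
    """Concrete bases covered by a single IUPAC code character."""
    try:
        return IUPAC_TO_BASES[code]
    except KeyError:
        raise ValueError(f"invalid IUPAC nucleotide code {code!r}") from None


def iupac_for(bases: Iterable[str]) -> str:
    """The minimal IUPAC code covering exactly *bases* (e.g. {A,T} -> 'W')."""
    key = frozenset(bases)
    try:
        return BASES_TO_IUPAC[key]
    except KeyError:
        raise ValueError(f"no IUPAC code for base set {sorted(key)}") from None


def complement_base(base: str) -> str:
    return _COMPLEMENT[base]


def complement_code(code: str) -> str:
    """Complement of a possibly degenerate code (complement of its base set)."""
    return iupac_for(complement_base(b) for b in bases_of(code))


def reverse_complement(seq: str) -> str:
    """Reverse complement of an IUPAC (possibly degenerate) sequence."""
    return "".join(complement_code(c) for c in reversed(seq))


def expand(seq: str) -> list[str]:
    """All concrete A/C/G/T expansions of a degenerate sequence.

    Deterministic lexicographic order; the count is the product of the
    per-position code cardinalities.
    """
    pools = []
    for i, c in enumerate(seq):
        if c not in IUPAC_TO_BASES:
            raise ValueError(f"invalid IUPAC code {c!r} at position {i + 1}")
        pools.append(sorted(IUPAC_TO_BASES[c]))
    return ["".join(p) for p in product(*pools)]


def expansion_count(seq: str) -> int:
    n = 1
    for i, c in enumerate(seq):
        if c not in IUPAC_TO_BASES:
            raise ValueError(f"invalid IUPAC code {c!r} at position {i + 1}")
        n *= len(IUPAC_TO_BASES[c])
    return n


def matches(degenerate: str, concrete: str) -> bool:
    """True if *concrete* (A/C/G/T) is one expansion of *degenerate*."""
    if len(degenerate) != len(concrete):
        return False
    return all(b in bases_of(c) for c, b in zip(degenerate, concrete))


def compatible(code_a: str, code_b: str) -> bool:
    """True if two codes share at least one concrete base."""
    return bool(bases_of(code_a) & bases_of(code_b))
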