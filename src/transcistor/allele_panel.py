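"""Aligned allele panels: polymorphic-site discovery, consensus, haplotype matching.

The panel is a gap-free, equal-length alignment of known allele sequences for a
single highly polymorphic locus (the motivating case is exon 2 of the ovine MHC
class II *DRB1* gene, 237 bp, where a quarter or more of the columns vary).
All coordinates in the public interface are 1-based and inclusive.
"""

from __future__ import annotations

from collections.abc import Mapping
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._iupac import CONCRETE, iupac_for

__all__ = [
    "Allele",
    "AllelePanel",
    "PolymorphicSite",
    "MatchReport",
    "find_polymorphic_sites",
    "consensus_iupac",
    "match_haplotype",
]

#: value accepted wherever a haplotype is expected: a full-length sequence or a
#: site -> base mapping over (at least) the panel's polymorphic positions.
HaplotypeLike = Union[str, Mapping[int, str]]


@dataclass(frozen=True)
class Allele:
    """One named, aligned allele sequence (A/C/G/T only, no gaps)."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("allele name must be non-empty")
        bad = set(self.sequence) - CONCRETE
        if bad:
            raise ValueError(
                f"allele {self.name!r}: sequence may contain only A/C/G/T "
                f"(found {sorted(bad)}); gapped or ambiguous input is rejected"
            )


class AllelePanel:
    """An ordered collection of equal-length aligned alleles.

    Parameters
    ----------
    alleles:
        Alleles with identical sequence length and unique names.
    """

    def __init__(self, alleles: Iterable[Allele]):
        self.alleles: tuple[Allele, ...] = tuple(alleles)
        if not self.alleles:
            raise ValueError("empty allele panel")
        lengths = {len(a.sequence) for a in self.alleles}
        if len(lengths) != 1:
            raise ValueError(f"alleles are not aligned: lengths {sorted(lengths)}")
        names = [a.name for a in self.alleles]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate allele names: {dupes}")
        self.alignment_length: int = lengths.pop()
        self._by_name = {a.name: a for a in self.alleles}

    def __len__(self) -> int:
        return len(self.alleles)

    def __iter__(self):
        return iter(self.alleles)

    def __getitem__(self, name: str) -> Allele:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(a.name for a in self.alleles)

    def column(self, position: int) -> str:
        """Alignment column at 1-based *position*, one character per allele."""
        if not 1 <= position <= self.alignment_length:
            raise IndexError(
                f"position {position} outside alignment (1..{self.alignment_length})"
            )
        i = position - 1
        return "".join(a.sequence[i] for a in self.alleles)

    # ------------------------------------------------------------------ I/O
    @classmethod
    def from_fasta(cls, path: str | Path) -> "AllelePanel":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no FASTA records in {path}")
        return cls(Allele(r.id, str(r.seq).upper()) for r in records)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(a.sequence), id=a.name, description="") for a in self.alleles
        ]
        SeqIO.write(records, str(path), "fasta")

    # ------------------------------------------------------------- helpers
    def haplotype_of(self, name: str, sites: Sequence["PolymorphicSite"] | None = None
                     ) -> dict[int, str]:
        """Site -> base map of a panel allele over the panel's polymorphic sites."""
        if sites is None:
            sites = find_polymorphic_sites(self)
        seq = self._by_name[name].sequence
        return {s.position: seq[s.position - 1] for s in sites}


@dataclass(frozen=True)
class PolymorphicSite:
    """A variable alignment column: 2-4 observed bases and their IUPAC code."""

    position: int
    observed_bases: frozenset[str]
    iupac_code: str = field(compare=False, default="")

    def __post_init__(self) -> None:
        if len(self.observed_bases) < 2:
            raise ValueError(
                f"site {self.position}: needs >=2 observed bases, "
                f"got {sorted(self.observed_bases)}"
            )
        code = iupac_for(self.observed_bases)
        if not self.iupac_code:
            object.__setattr__(self, "iupac_code", code)
        elif self.iupac_code != code:
            raise ValueError(
                f"site {self.position}: code {self.iupac_code!r} does not cover "
                f"exactly {sorted(self.observed_bases)} (expected {code!r})"
            )


def find_polymorphic_sites(panel: AllelePanel) -> list[PolymorphicSite]:
    """All alignment columns where at least two distinct bases occur.

    Returns one :class:`PolymorphicSite` per variable column, sorted by
    position. Invariant columns are absent from the output.
    """
    sites = []
    for pos in range(1, panel.alignment_length + 1):
        bases = frozenset(panel.column(pos))
        if len(bases) >= 2:
            sites.append(PolymorphicSite(pos, bases))
    return sites


def consensus_iupac(panel: AllelePanel) -> str:
    """Per-column minimal IUPAC consensus over the panel.

    Invariant columns keep their base; variable columns get the smallest
    degenerate code covering all observed bases.
    """
    out = []
    for pos in range(1, panel.alignment_length + 1):
        out.append(iupac_for(frozenset(panel.column(pos))))
    return "".join(out)


@dataclass(frozen=True)
class MatchReport:
    """Result of matching an assembled haplotype against the known panel.

    status is ``"match"`` (unique known allele), ``"novel"`` (a new combination
    of known site variants), or ``"indistinct"`` (more than one panel allele is
    identical over the polymorphic sites — the panel cannot discriminate).
    """

    status: str
    allele: str | None = None
    candidates: tuple[str, ...] = ()


def _haplotype_map(panel: AllelePanel, haplotype: HaplotypeLike,
                   sites: Sequence[PolymorphicSite]) -> dict[int, str]:
    if isinstance(haplotype, str):
        if len(haplotype) == panel.alignment_length:
            return {s.position: haplotype[s.position - 1] for s in sites}
        if len(haplotype) == len(sites):
            return {s.position: b for s, b in zip(sites, haplotype)}
        raise ValueError(
            f"haplotype string length {len(haplotype)} matches neither the "
            f"alignment length ({panel.alignment_length}) nor the number of "
            f"polymorphic sites ({len(sites)})"
        )
    return dict(haplotype)


def match_haplotype(panel: AllelePanel, haplotype: HaplotypeLike) -> MatchReport:
    """Identify an assembled haplotype as a known allele or flag it novel.

    Novelty is defined over the panel's polymorphic sites only: invariant
    columns carry no identifying information, and new alleles at loci like MHC
    *DRB1* are typically new combinations of already-known site variants.

    The haplotype must assign a base to every polymorphic site; missing
    assignments raise ``ValueError`` listing the absent positions.
    """
    sites = find_polymorphic_sites(panel)
    hap = _haplotype_map(panel, haplotype, sites)
    missing = [s.position for s in sites if s.position not in hap]
    if missing:
        raise ValueError(f"haplotype missing assignments at positions {missing}")
    hits = []
    for allele in panel:
        if all(allele.sequence[s.position - 1] == hap[s.position] for s in sites):
            hits.append(allele.name)
    if not hits:
        return MatchReport("novel")
    if len(hits) == 1:
        return MatchReport("match", allele=hits[0], candidates=tuple(hits))
    return MatchReport("indistinct", candidates=tuple(hits))
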