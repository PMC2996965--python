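"""Seeded generators for allele panels, diploid cohorts and reaction layouts.

The generator emulates the study system — a short, highly polymorphic exon
(237 bp, 60 variable sites, bi- to tetra-allelic) carrying a skewed spectrum
of a few dozen alleles, sampled as Hardy-Weinberg diploids — without using
any real sequence. Every stage draws from its own stream derived from one
global integer seed by fixed offsets, so panel, cohort and assay noise are
independently reproducible.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from math import prod
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .allele_panel import Allele, AllelePanel, find_polymorphic_sites
from .assay_sim import (
    MAX_AMPLICON_MULTIPLEX,
    MAX_BEAD_CLASSES,
    HaplotypePair,
    ReactionLayout,
    TubeDesign,
)
from .primer_design import PrimerPanel

__all__ = [
    "CohortSpec",
    "TruthSet",
    "default_allele_spectrum",
    "generate_panel",
    "sample_cohort",
    "default_reaction_layout",
    "layout_is_connected",
]

_BASES = "ACGT"

#: sites are kept this far from the alignment edges so that a primer footprint
#: in either orientation always fits inside the alignment
_EDGE_PAD = 30


def default_allele_spectrum(n_alleles: int) -> tuple[float, ...]:
    """The published 33-allele frequency spectrum, renormalized.

    For fewer alleles the top of the spectrum is kept and renormalized; more
    than 33 requires explicit frequencies.
    """
    from .datasets import load_allele_frequencies

    freqs = load_allele_frequencies()["frequency_percent"].to_numpy(dtype=float)
    if n_alleles > len(freqs):
        raise ValueError(
            f"no default spectrum for {n_alleles} alleles (have {len(freqs)}); "
            "supply allele_freqs explicitly"
        )
    head = freqs[:n_alleles]
    return tuple(float(x) for x in head / head.sum())


@dataclass(frozen=True)
class CohortSpec:
    """Study-shaped generator settings.

    Defaults are the study conditions: a 237-bp alignment with 60 polymorphic
    sites, 33 alleles at the published skewed spectrum, 109 diploid
    individuals drawn under Hardy-Weinberg equilibrium. ``fraction_multiallelic``
    is the share of sites carrying 3-4 bases (the published panel reports a
    biallelic majority with a substantial tri/tetra-allelic minority; 0.25 is
    used as that share). ``mating="custom"`` draws allele pairs from
    ``pair_freqs`` (an n_alleles x n_alleles joint table), the hook for
    building cohorts that violate random mating.
    """

    seed: int
    n_alleles: int = 33
    alignment_length: int = 237
    n_polymorphic_sites: int = 60
    fraction_multiallelic: float = 0.25
    allele_freqs: tuple[float, ...] | None = None
    n_individuals: int = 109
    mating: str = "hwe"
    pair_freqs: tuple[tuple[float, ...], ...] | None = None

    def __post_init__(self) -> None:
        if self.n_polymorphic_sites > self.alignment_length:
            raise ValueError("more polymorphic sites than alignment columns")
        if not 0.0 <= self.fraction_multiallelic <= 1.0:
            raise ValueError("fraction_multiallelic must lie in [0, 1]")
        if self.mating not in ("hwe", "custom"):
            raise ValueError(f"unknown mating model {self.mating!r}")
        if self.allele_freqs is not None:
            total = sum(self.allele_freqs)
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"allele_freqs sum to {total}, expected 1")

    def resolved_freqs(self) -> tuple[float, ...]:
        if self.allele_freqs is not None:
            if len(self.allele_freqs) != self.n_alleles:
                raise ValueError(
                    f"{len(self.allele_freqs)} frequencies for "
                    f"{self.n_alleles} alleles"
                )
            return self.allele_freqs
        return default_allele_spectrum(self.n_alleles)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth for a simulated cohort: each individual's ordered pair of
    allele names (order is sampling noise, not information)."""

    entries: tuple[tuple[str, str, str], ...]  # (individual_id, allele1, allele2)
    panel: AllelePanel
    spec: CohortSpec

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def individual_ids(self) -> tuple[str, ...]:
        return tuple(e[0] for e in self.entries)

    def haplotype_pair(self, index: int) -> HaplotypePair:
        _, a1, a2 = self.entries[index]
        return HaplotypePair(self.panel[a1].sequence, self.panel[a2].sequence)

    def site_map_pair(self, index: int,
                      sites: Sequence[int] | None = None
                      ) -> tuple[dict[int, str], dict[int, str]]:
        if sites is None:
            sites = [s.position for s in find_polymorphic_sites(self.panel)]
        _, a1, a2 = self.entries[index]
        s1, s2 = self.panel[a1].sequence, self.panel[a2].sequence
        return ({p: s1[p - 1] for p in sites}, {p: s2[p - 1] for p in sites})

    def chromosome_counts(self) -> Counter:
        c: Counter = Counter()
        for _, a1, a2 in self.entries:
            c[a1] += 1
            c[a2] += 1
        return c

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            list(self.entries), columns=["individual_id", "allele1", "allele2"]
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path, panel: AllelePanel,
                 spec: CohortSpec) -> "TruthSet":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        entries = tuple(
            (r.individual_id, r.allele1, r.allele2)
            for r in df.itertuples(index=False)
        )
        return cls(entries, panel, spec)


# --------------------------------------------------------------------------
# panel generation
# --------------------------------------------------------------------------

def _site_cardinalities(rng: np.random.Generator, spec: CohortSpec) -> list[int]:
    n_multi = round(spec.fraction_multiallelic * spec.n_polymorphic_sites)
    cards = [2] * (spec.n_polymorphic_sites - n_multi)
    # among multiallelic sites, triallelic dominates tetra-allelic; a site can
    # never show more bases than there are alleles to carry them
    cap = min(4, spec.n_alleles)
    for _ in range(n_multi):
        k = int(rng.choice([3, 4], p=[0.7, 0.3]))
        cards.append(min(k, cap) if cap >= 3 else 2)
    rng.shuffle(cards)
    return cards


def generate_panel(spec: CohortSpec) -> AllelePanel:
    """A random invariant backbone plus the specified mutated columns.

    Post-conditions: the polymorphic-site count equals the spec exactly
    (every intended base is observed in at least one allele), alleles are
    pairwise distinct at the polymorphic sites, and the multiallelic share
    matches the spec within one site. Same seed, same panel.
    """
    rng = np.random.default_rng([spec.seed, 1])
    n_sites, n_all = spec.n_polymorphic_sites, spec.n_alleles
    lo, hi = _EDGE_PAD + 1, spec.alignment_length - _EDGE_PAD
    if hi - lo + 1 < n_sites:
        raise ValueError(
            f"cannot place {n_sites} sites in columns {lo}..{hi}; "
            "alignment too short for the edge padding primers need"
        )
    positions = np.sort(rng.choice(np.arange(lo, hi + 1), n_sites, replace=False))
    cards = _site_cardinalities(rng, spec)
    if prod(cards) < n_all:
        raise ValueError(
            f"{n_all} distinct alleles cannot exist over "
            f"{n_sites} sites with cardinalities {sorted(set(cards))}"
        )
    if max(cards) > n_all:
        raise ValueError(
            f"a {max(cards)}-allelic site cannot be covered by {n_all} alleles"
        )
    site_bases = [
        sorted(rng.choice(list(_BASES), k, replace=False)) for k in cards
    ]
    backbone = rng.choice(list(_BASES), spec.alignment_length)

    # allele x site base-index matrix; force full coverage of every site's
    # base set, then perturb duplicates until all alleles are distinct
    matrix = np.array(
        [[rng.integers(0, len(site_bases[j])) for j in range(n_sites)]
         for _ in range(n_all)]
    )
    for _ in range(200):
        for j, bases in enumerate(site_bases):
            present = set(matrix[:, j])
            missing = [i for i in range(len(bases)) if i not in present]
            if missing:
                rows = rng.choice(n_all, len(missing), replace=False)
                for row, base_idx in zip(rows, missing):
                    matrix[row, j] = base_idx
        seen: dict[tuple, int] = {}
        dupes = []
        for i in range(n_all):
            key = tuple(matrix[i])
            if key in seen:
                dupes.append(i)
            else:
                seen[key] = i
        if not dupes:
            break
        for i in dupes:
            j = int(rng.integers(0, n_sites))
            matrix[i, j] = rng.integers(0, len(site_bases[j]))
    else:
        raise ValueError("could not realize pairwise-distinct alleles; "
                         "spec too tight")

    alleles = []
    for i in range(n_all):
        seq = backbone.copy()
        for j, pos in enumerate(positions):
            seq[pos - 1] = site_bases[j][matrix[i, j]]
        alleles.append(Allele(f"SYN{i + 1:03d}", "".join(seq)))
    return AllelePanel(alleles)


# --------------------------------------------------------------------------
# cohort sampling
# --------------------------------------------------------------------------

def sample_cohort(panel: AllelePanel, spec: CohortSpec) -> TruthSet:
    """Draw each individual's two alleles.

    ``hwe`` mating draws the two chromosomes i.i.d. from the allele
    frequencies (random union of gametes); ``custom`` draws the ordered pair
    from ``spec.pair_freqs``. Chromosome order within an individual is
    exchangeable.
    """
    rng = np.random.default_rng([spec.seed, 2])
    names = panel.names
    if len(names) != spec.n_alleles:
        raise ValueError(
            f"panel has {len(names)} alleles but the spec says {spec.n_alleles}"
        )
    n = spec.n_individuals
    if spec.mating == "hwe":
        freqs = np.asarray(spec.resolved_freqs())
        idx = rng.choice(len(names), size=(n, 2), p=freqs)
    else:
        if spec.pair_freqs is None:
            raise ValueError("mating='custom' needs pair_freqs")
        joint = np.asarray(spec.pair_freqs, dtype=float)
        if joint.shape != (len(names), len(names)):
            raise ValueError(
                f"pair_freqs shape {joint.shape} does not match "
                f"{len(names)} alleles"
            )
        if abs(joint.sum() - 1.0) > 1e-9:
            raise ValueError("pair_freqs must sum to 1")
        flat = rng.choice(joint.size, size=n, p=joint.ravel())
        idx = np.column_stack(np.unravel_index(flat, joint.shape))
    entries = tuple(
        (f"IND{i + 1:04d}", names[idx[i, 0]], names[idx[i, 1]])
        for i in range(n)
    )
    return TruthSet(entries, panel, spec)


# --------------------------------------------------------------------------
# reaction layout
# --------------------------------------------------------------------------

def default_reaction_layout(panel: AllelePanel, primers: PrimerPanel,
                            max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX,
                            bead_cap: int = MAX_BEAD_CLASSES
                            ) -> ReactionLayout:
    """Chain-plus-skip site pairings, packed into tubes that cover all pairs.

    The designed pair list links every site to its nearest and next-nearest
    downstream partners — on three sites, the pairs (1,2), (2,3) and (1,3).
    Tube packing must do more than honour the bead-class cap: homozygous
    sites cannot relay phase, so two heterozygous sites are phaseable only if
    some tube tests them directly (all forward x reverse combinations in a
    tube co-amplify). Sites are therefore split into contiguous blocks and
    one tube built per block pair, which puts every pair of sites in at least
    one shared tube while every tube stays under the cap.

    Sites with no legal partner in either direction are listed as uncovered,
    not fatal.
    """
    fwd_sites = {p.site for p in primers.forwards()}
    rev_sites = {p.site for p in primers.reverses()}
    sites = sorted({p.site for p in primers})

    def span_ok(a: int, b: int) -> bool:
        f_lo = min(min(p.footprint) for p in primers.forwards() if p.site == a)
        r_hi = max(max(p.footprint) for p in primers.reverses() if p.site == b)
        return r_hi - f_lo + 1 <= max_amplicon_len

    designed: list[tuple[int, int]] = []
    for i, a in enumerate(sites):
        for j in (i + 1, i + 2):
            if j >= len(sites):
                continue
            b = sites[j]
            if a in fwd_sites and b in rev_sites and span_ok(a, b):
                designed.append((a, b))
    covered = {s for pair in designed for s in pair}
    uncovered = tuple(s for s in sites if s not in covered)

    site_labels = {
        s: [p.label for p in primers if p.site == s] for s in sites
    }
    total = sum(len(v) for v in site_labels.values())
    if total <= bead_cap:
        tubes = (TubeDesign("T01", tuple(primers.labels)),)
        return ReactionLayout(tubes, tuple(designed), uncovered)

    def block_tubes(n_blocks: int) -> list[tuple[str, ...]] | None:
        chunks = np.array_split(np.array(sites), n_blocks)
        blocks = [
            tuple(l for s in chunk for l in site_labels[int(s)])
            for chunk in chunks
        ]
        out = []
        for i in range(n_blocks):
            for j in range(i + 1, n_blocks):
                union = blocks[i] + blocks[j]
                if len(union) > bead_cap:
                    return None
                out.append(union)
        return out

    for n_blocks in range(2, len(sites) + 1):
        packed = block_tubes(n_blocks)
        if packed is not None:
            tubes = tuple(
                TubeDesign(f"T{i + 1:02d}", labels)
                for i, labels in enumerate(packed)
            )
            return ReactionLayout(tubes, tuple(designed), uncovered)
    raise ValueError(
        "cannot pack the primer panel under the bead-class cap: a single "
        "site pair already exceeds it"
    )


def layout_is_connected(layout: ReactionLayout,
                        sites: Iterable[int] | None = None) -> bool:
    """Is the designed pairing graph connected over the given sites?"""
    g = nx.Graph()
    g.add_edges_from(layout.designed_pairs)
    if sites is not None:
        g.add_nodes_from(sites)
    if g.number_of_nodes() <= 1:
        return True
    return nx.is_connected(g)
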