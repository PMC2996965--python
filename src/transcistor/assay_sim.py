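"""Mechanistic simulation of the two-phase solid-phase double-ARMS bead assay.

Phase 1: all forward and reverse allele-specific primers are present both in
solution and anchored on spectrally coded beads. Solution-phase PCR amplifies
every amplicon whose two allele-specific ends match the *same* chromosome
(cis-only — there is no chimeric template), and each amplicon is "kidnapped"
onto both its forward-anchored and reverse-anchored bead classes.

Phase 2: after washing, each aliquot is labeled by one round of primer
extension with a single fluorescent primer. A (bead class, label primer) cell
lights up when the bead's anchored primer and the label primer flank the same
amplicon species on opposite strands.

The simulator emits per-cell event counts and reporter/background ratios with
a configurable noise model; it does not model PCR kinetics or cytometer
channel mechanics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .allele_panel import AllelePanel
from .primer_design import ArmsPrimer, PrimerPanel, matches_template

__all__ = [
    "MAX_BEAD_CLASSES",
    "HaplotypePair",
    "Amplicon",
    "BeadClass",
    "AssayNoiseModel",
    "ReactionReadout",
    "TubeDesign",
    "ReactionLayout",
    "enumerate_amplicons",
    "count_amplicon_species",
    "count_positive_bead_populations",
    "simulate_readout",
]

#: spectral address space of the bead array (one anchored primer per class)
MAX_BEAD_CLASSES = 100

#: default maximum amplicon length by reaction mode, in bp
MAX_AMPLICON_MULTIPLEX = 3500
MAX_AMPLICON_SINGLEPLEX = 10000


@dataclass(frozen=True)
class HaplotypePair:
    """The two chromosome-level sequences of one diploid individual.

    ``hap1 == hap2`` for a homozygote. Chromosome order is arbitrary and
    carries no information; all downstream comparisons are unordered.
    """

    hap1: str
    hap2: str

    def __post_init__(self) -> None:
        if len(self.hap1) != len(self.hap2):
            raise ValueError("haplotypes differ in length; expected an aligned pair")

    @property
    def chromosomes(self) -> tuple[str, str]:
        return (self.hap1, self.hap2)


@dataclass(frozen=True)
class Amplicon:
    """One allele-specific product: which primer pair made it, from which
    chromosome, and the reference-sense variants at its two discriminated
    sites."""

    fwd_label: str
    rev_label: str
    source_chromosome: int  # 1 or 2
    span: tuple[int, int]
    fwd_base: str
    rev_base: str

    @property
    def species(self) -> tuple[str, str]:
        """Chromosome-collapsed identity of the product."""
        return (self.fwd_label, self.rev_label)


@dataclass(frozen=True)
class BeadClass:
    """A spectrally distinct bead set carrying one anchored primer."""

    bead_id: str
    anchored_primer_label: str
    beads_per_reaction: int = 2000


@dataclass(frozen=True)
class AssayNoiseModel:
    """Event-count noise for one reaction tube.

    Positive (template-present) cells draw from round(max(0, N(pos_mean,
    pos_sd))); background cells from the negative distribution. The defaults
    are the observed signal statistics of the assay: 195 +/- 12 events with
    template, 9 +/- 5 without. ``dropout_rate`` sends a true cell to the
    background distribution (a failed solid-phase reaction still shows
    background events); ``false_capture_rate`` promotes a background cell to
    the positive distribution. A seed is mandatory — every simulated readout
    is reproducible by contract.
    """

    pos_events_mean: float = 195.0
    pos_events_sd: float = 12.0
    neg_events_mean: float = 9.0
    neg_events_sd: float = 5.0
    false_capture_rate: float = 0.0
    dropout_rate: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.pos_events_mean < 0 or self.neg_events_mean < 0:
            raise ValueError("event-count means must be >= 0")
        for r in (self.false_capture_rate, self.dropout_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")

    def rng(self) -> np.random.Generator:
        if self.seed is None:
            raise ValueError(
                "AssayNoiseModel.seed is unset; simulated readouts must be seeded"
            )
        return np.random.default_rng(self.seed)


class ReactionReadout:
    """Dense per-tube readout: event counts and reporter ratios for every
    (bead class, label primer) cell.

    Internally a pair of (n_beads, n_labels) arrays; ``to_frame`` gives the
    long-format table used on disk.
    """

    def __init__(self, primer_labels: Sequence[str], events: np.ndarray,
                 reporter_ratio: np.ndarray, individual_id: str = "NA",
                 tube_id: str = "T1"):
        self.primer_labels = tuple(primer_labels)
        n = len(self.primer_labels)
        events = np.asarray(events)
        reporter_ratio = np.asarray(reporter_ratio, dtype=float)
        if events.shape != (n, n) or reporter_ratio.shape != (n, n):
            raise ValueError(
                f"expected dense ({n}, {n}) cell matrices, got {events.shape} "
                f"and {reporter_ratio.shape}"
            )
        if (events < 0).any():
            raise ValueError("negative event counts")
        self.events = events.astype(np.int64)
        self.reporter_ratio = reporter_ratio
        self.individual_id = individual_id
        self.tube_id = tube_id
        self._index = {l: i for i, l in enumerate(self.primer_labels)}
        self.bead_ids = tuple(f"B{i + 1:03d}" for i in range(n))

    @property
    def bead_classes(self) -> tuple[BeadClass, ...]:
        return tuple(
            BeadClass(bid, label)
            for bid, label in zip(self.bead_ids, self.primer_labels)
        )

    def index_of(self, label: str) -> int:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(
                f"primer {label!r} has no bead class in tube {self.tube_id}"
            ) from None

    def cell(self, anchored_label: str, label_primer: str) -> tuple[int, float]:
        i, j = self.index_of(anchored_label), self.index_of(label_primer)
        return int(self.events[i, j]), float(self.reporter_ratio[i, j])

    # ------------------------------------------------------------------ I/O
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, (bid, anchored) in enumerate(zip(self.bead_ids, self.primer_labels)):
            for j, label in enumerate(self.primer_labels):
                rows.append(
                    (self.individual_id, self.tube_id, bid, anchored, label,
                     int(self.events[i, j]), float(self.reporter_ratio[i, j]))
                )
        return pd.DataFrame(
            rows,
            columns=["individual", "tube", "bead_id", "anchored_primer",
                     "label_primer", "events", "reporter_ratio"],
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReactionReadout":
        individual = str(df["individual"].iloc[0])
        tube = str(df["tube"].iloc[0])
        labels = list(dict.fromkeys(df["anchored_primer"]))
        n = len(labels)
        idx = {l: i for i, l in enumerate(labels)}
        events = np.zeros((n, n), dtype=np.int64)
        ratio = np.zeros((n, n), dtype=float)
        seen = np.zeros((n, n), dtype=bool)
        for row in df.itertuples(index=False):
            i, j = idx[row.anchored_primer], idx[row.label_primer]
            events[i, j] = row.events
            ratio[i, j] = row.reporter_ratio
            seen[i, j] = True
        if not seen.all():
            raise ValueError(
                f"readout for {individual}/{tube} is not dense: "
                f"{int((~seen).sum())} missing cells"
            )
        return cls(labels, events, ratio, individual, tube)

    @classmethod
    def from_tsv(cls, path: str | Path) -> list["ReactionReadout"]:
        """Read one long-format file, returning one readout per
        (individual, tube) group."""
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
        return [
            cls.from_frame(g)
            for _, g in df.groupby(["individual", "tube"], sort=True)
        ]


# --------------------------------------------------------------------------
# reaction layout (tube design)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class TubeDesign:
    """One multiplexed reaction tube: which primers (hence bead classes) it
    contains. Every forward x reverse combination within a tube co-amplifies."""

    tube_id: str
    primer_labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.primer_labels) > MAX_BEAD_CLASSES:
            raise ValueError(
                f"tube {self.tube_id}: {len(self.primer_labels)} bead classes "
                f"requested; the array supports at most {MAX_BEAD_CLASSES}"
            )


@dataclass(frozen=True)
class ReactionLayout:
    """A set of tubes plus the designed site pairings they realize."""

    tubes: tuple[TubeDesign, ...]
    designed_pairs: tuple[tuple[int, int], ...] = ()
    uncovered_sites: tuple[int, ...] = ()

    def to_tsv(self, path: str | Path) -> None:
        rows = [(t.tube_id, l) for t in self.tubes for l in t.primer_labels]
        pd.DataFrame(rows, columns=["tube", "primer_label"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ReactionLayout":
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
        tubes = tuple(
            TubeDesign(tube_id, tuple(g["primer_label"]))
            for tube_id, g in df.groupby("tube", sort=True)
        )
        return cls(tubes)


# --------------------------------------------------------------------------
# amplicon enumeration (the cis-only truth model)
# --------------------------------------------------------------------------

def _primer_lists(panel: PrimerPanel | Iterable[ArmsPrimer]
                  ) -> tuple[list[ArmsPrimer], list[ArmsPrimer]]:
    primers = list(panel)
    return ([p for p in primers if p.orientation == "forward"],
            [p for p in primers if p.orientation == "reverse"])


def enumerate_amplicons(genotype: HaplotypePair,
                        panel: PrimerPanel | Iterable[ArmsPrimer],
                        max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX
                        ) -> list[Amplicon]:
    """All allele-specific products formed from a diploid template.

    An amplicon (f, r, chromosome c) forms iff both primers' 3' termini match
    chromosome c at their sites (and their wobbled footprints anneal), the
    forward footprint lies strictly upstream of the reverse footprint, and
    the product is no longer than ``max_amplicon_len``. Both ends must match
    the *same* chromosome: a double-ARMS product is a direct cis readout and
    no trans (chimeric) species ever forms.
    """
    forwards, reverses = _primer_lists(panel)
    out: list[Amplicon] = []
    for c, hap in enumerate(genotype.chromosomes, start=1):
        for f in forwards:
            if not matches_template(f, hap):
                continue
            f_lo, f_hi = f.footprint
            for r in reverses:
                r_lo, r_hi = r.footprint
                if f_hi >= r_lo:
                    continue
                if r_hi - f_lo + 1 > max_amplicon_len:
                    continue
                if not matches_template(r, hap):
                    continue
                out.append(
                    Amplicon(
                        fwd_label=f.label,
                        rev_label=r.label,
                        source_chromosome=c,
                        span=(f_lo, r_hi),
                        fwd_base=hap[f.site - 1],
                        rev_base=hap[r.site - 1],
                    )
                )
    return out


def count_amplicon_species(genotype: HaplotypePair,
                           fwd_pair: Iterable[ArmsPrimer],
                           rev_pair: Iterable[ArmsPrimer],
                           max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX) -> int:
    """Number of distinct products (chromosomes collapsed) for one reaction.

    A double heterozygote yields 2 species (the two cis products), a single
    heterozygote 2, a double homozygote 1.
    """
    amps = enumerate_amplicons(
        genotype, list(fwd_pair) + list(rev_pair), max_amplicon_len
    )
    return len({a.species for a in amps})


def count_positive_bead_populations(genotype: HaplotypePair,
                                    fwd_pair: Iterable[ArmsPrimer],
                                    rev_pair: Iterable[ArmsPrimer],
                                    max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX
                                    ) -> int:
    """Number of distinct bead classes carrying at least one captured product.

    Each amplicon is captured on both its forward- and reverse-anchored
    beads, so every expected reaction lights a minimum of two bead
    populations — the assay's built-in duplication QC. A double heterozygote
    lights 4 (two species x two anchoring beads, none shared).
    """
    amps = enumerate_amplicons(
        genotype, list(fwd_pair) + list(rev_pair), max_amplicon_len
    )
    beads: set[str] = set()
    for a in amps:
        beads.add(a.fwd_label)
        beads.add(a.rev_label)
    return len(beads)


# --------------------------------------------------------------------------
# readout simulation
# --------------------------------------------------------------------------

def truth_cell_matrix(labels: Sequence[str], species: Iterable[tuple[str, str]]
                      ) -> np.ndarray:
    """Boolean (bead, label) truth table from a set of (fwd, rev) species.

    Species (f, r) makes exactly two cells true: (bead f, label r) and
    (bead r, label f) — the duplicate representation of every product.
    """
    idx = {l: i for i, l in enumerate(labels)}
    truth = np.zeros((len(idx), len(idx)), dtype=bool)
    for f, r in species:
        i, j = idx[f], idx[r]
        truth[i, j] = True
        truth[j, i] = True
    return truth


def draw_readout_cells(truth: np.ndarray, noise: AssayNoiseModel,
                       rng: np.random.Generator
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Draw (events, reporter_ratio) matrices for a truth table.

    The reporter/background ratio is events over the background mean, clamped
    onto the correct side of the 4x rule for the distribution the cell was
    actually drawn from (>= 4 for positive-distribution cells, < 4
    otherwise), mirroring how gating separates the two fluorescence regimes.
    """
    shape = truth.shape
    dropout = rng.random(shape) < noise.dropout_rate
    promote = rng.random(shape) < noise.false_capture_rate
    pos_draw = rng.normal(noise.pos_events_mean, noise.pos_events_sd, shape)
    neg_draw = rng.normal(noise.neg_events_mean, noise.neg_events_sd, shape)
    positive_cell = (truth & ~dropout) | (~truth & promote)
    events = np.where(positive_cell, pos_draw, neg_draw)
    events = np.rint(np.maximum(events, 0.0)).astype(np.int64)
    background = max(noise.neg_events_mean, 1.0)
    raw_ratio = events / background
    ratio = np.where(positive_cell,
                     np.maximum(raw_ratio, 4.0),
                     np.minimum(raw_ratio, 3.99))
    return events, ratio


def simulate_readout(genotype: HaplotypePair, panel: PrimerPanel,
                     noise: AssayNoiseModel,
                     max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX,
                     individual_id: str = "NA", tube_id: str = "T1"
                     ) -> ReactionReadout:
    """Simulate one multiplexed tube for one individual.

    The truth table comes from cis-only amplicon enumeration plus capture
    duplication; event counts and reporter ratios are then drawn from the
    noise model (which must carry a seed — identical seed and inputs give an
    identical readout). With zero sds and zero rates, true cells read exactly
    the positive mean and all others the background mean.
    """
    labels = [p.label for p in panel]
    if len(labels) > MAX_BEAD_CLASSES:
        raise ValueError(
            f"{len(labels)} bead classes requested; the array supports at "
            f"most {MAX_BEAD_CLASSES} per tube — split the panel into tubes"
        )
    rng = noise.rng()
    amps = enumerate_amplicons(genotype, panel, max_amplicon_len)
    truth = truth_cell_matrix(labels, {a.species for a in amps})
    events, ratio = draw_readout_cells(truth, noise, rng)
    return ReactionReadout(labels, events, ratio, individual_id, tube_id)
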