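"""End-to-end cohort runs: simulate every tube for every individual, decode,
and score against ground truth.

This is the same model as :func:`transcistor.assay_sim.simulate_readout` and
:func:`transcistor.phase_decoder.decode_individual`, specialized for whole
cohorts: primer-vs-allele matching is computed once per tube (every simulated
chromosome is a panel allele), and positivity is evaluated on the cell
matrices directly. Per-(individual, tube) noise streams derive from one base
seed by fixed offsets, so any single readout can be regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterator, Mapping, Sequence

import numpy as np

from .allele_panel import AllelePanel, find_polymorphic_sites
from .assay_sim import (
    MAX_AMPLICON_MULTIPLEX,
    AssayNoiseModel,
    ReactionLayout,
    ReactionReadout,
    draw_readout_cells,
)
from .phase_decoder import (
    DecodedResult,
    PositivityRule,
    assemble_haplotypes,
    extract_constraints,
    genotype_from_positives,
)
from .primer_design import PrimerPanel, matches_template
from .synthetic_cohort import TruthSet

__all__ = [
    "ZERO_NOISE",
    "CohortRun",
    "run_cohort",
    "simulate_cohort_readouts",
    "recovery_rate",
]

#: degenerate noise model: exact means, no dropout, no false capture
ZERO_NOISE = AssayNoiseModel(pos_events_sd=0.0, neg_events_sd=0.0)


def _derived_noise(noise: AssayNoiseModel, base_seed: int,
                   ind_index: int, tube_index: int) -> AssayNoiseModel:
    seed = int(
        np.random.SeedSequence([base_seed, 3, ind_index, tube_index])
        .generate_state(1)[0]
    )
    return replace(noise, seed=seed)


class _TubeModel:
    """Per-tube precomputation: primer geometry and allele-match matrix."""

    def __init__(self, tube_id: str, labels: Sequence[str],
                 primers: PrimerPanel, panel: AllelePanel,
                 max_amplicon_len: int):
        self.tube_id = tube_id
        self.labels = list(labels)
        self.primers = [primers[l] for l in self.labels]
        self.sub_panel = PrimerPanel(self.primers, reference=None)
        n = len(self.labels)
        self.fwd_pos = [i for i, p in enumerate(self.primers)
                        if p.orientation == "forward"]
        self.rev_pos = [i for i, p in enumerate(self.primers)
                        if p.orientation == "reverse"]
        fwd = [self.primers[i] for i in self.fwd_pos]
        rev = [self.primers[i] for i in self.rev_pos]
        self.geometry = np.zeros((len(fwd), len(rev)), dtype=bool)
        for a, f in enumerate(fwd):
            f_lo, f_hi = f.footprint
            for b, r in enumerate(rev):
                r_lo, r_hi = r.footprint
                self.geometry[a, b] = (
                    f_hi < r_lo and (r_hi - f_lo + 1) <= max_amplicon_len
                )
        # match[k, i]: does primer i anneal to panel allele k (3' included)?
        self.match = np.array(
            [[matches_template(p, a.sequence) for p in self.primers]
             for a in panel],
            dtype=bool,
        )
        self.allele_index = {name: k for k, name in enumerate(panel.names)}
        self.n = n

    def truth_matrix(self, allele1: str, allele2: str) -> np.ndarray:
        """Dense (bead, label) truth table for one diploid individual."""
        species = np.zeros_like(self.geometry)
        for name in (allele1, allele2):
            row = self.match[self.allele_index[name]]
            species |= np.outer(row[self.fwd_pos], row[self.rev_pos])
        species &= self.geometry
        truth = np.zeros((self.n, self.n), dtype=bool)
        truth[np.ix_(self.fwd_pos, self.rev_pos)] = species
        return truth | truth.T

    def positives(self, events: np.ndarray, ratio: np.ndarray,
                  rule: PositivityRule) -> list[tuple[str, str]]:
        ok = (events >= rule.min_events) & (ratio >= rule.min_reporter_ratio)
        a = ok[np.ix_(self.fwd_pos, self.rev_pos)]
        b = ok[np.ix_(self.rev_pos, self.fwd_pos)].T
        hit = (a & b) if rule.require_both_beads else (a | b)
        hit &= self.geometry
        return [
            (self.labels[self.fwd_pos[i]], self.labels[self.rev_pos[j]])
            for i, j in np.argwhere(hit)
        ]


def _tube_models(truth: TruthSet, primers: PrimerPanel, layout: ReactionLayout,
                 max_amplicon_len: int) -> list[_TubeModel]:
    return [
        _TubeModel(t.tube_id, t.primer_labels, primers, truth.panel,
                   max_amplicon_len)
        for t in layout.tubes
    ]


@dataclass(frozen=True)
class CohortRun:
    """Decoded cohort plus everything needed to score it."""

    decoded: Mapping[str, DecodedResult]
    truth: TruthSet
    site_positions: tuple[int, ...]

    def recovery_rate(self) -> float:
        return recovery_rate(self.decoded, self.truth, self.site_positions)

    def status_counts(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for r in self.decoded.values():
            out[r.status] = out.get(r.status, 0) + 1
        return out


def run_cohort(truth: TruthSet, primers: PrimerPanel, layout: ReactionLayout,
               noise: AssayNoiseModel = ZERO_NOISE,
               rule: PositivityRule | None = None,
               base_seed: int | None = None,
               max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX,
               *, min_base_support: int = 2,
               strict: bool = False) -> CohortRun:
    """Simulate and decode a whole cohort, streaming tube by tube.

    ``base_seed`` defaults to the truth set's generator seed; per-readout
    streams are derived from it by fixed offsets. Cohort decoding demands
    two independent positive reactions per called base
    (``min_base_support=2``): the default layouts test every site against
    many partners, so genuine variants are supported many times over while
    isolated false captures are rejected.
    """
    rule = rule or PositivityRule()
    if base_seed is None:
        base_seed = truth.spec.seed
    models = _tube_models(truth, primers, layout, max_amplicon_len)
    positions = tuple(
        s.position for s in find_polymorphic_sites(truth.panel)
    )
    decoded: dict[str, DecodedResult] = {}
    for i, (ind_id, a1, a2) in enumerate(truth.entries):
        positives: list[tuple[str, str]] = []
        for t, model in enumerate(models):
            tube_noise = _derived_noise(noise, base_seed, i, t)
            rng = tube_noise.rng()
            events, ratio = draw_readout_cells(
                model.truth_matrix(a1, a2), tube_noise, rng
            )
            positives.extend(model.positives(events, ratio, rule))
        calls = genotype_from_positives(positives, primers, min_base_support)
        constraints = extract_constraints(positives, primers)
        decoded[ind_id] = assemble_haplotypes(constraints, calls, strict=strict)
    return CohortRun(decoded, truth, positions)


def simulate_cohort_readouts(truth: TruthSet, primers: PrimerPanel,
                             layout: ReactionLayout,
                             noise: AssayNoiseModel = ZERO_NOISE,
                             base_seed: int | None = None,
                             max_amplicon_len: int = MAX_AMPLICON_MULTIPLEX
                             ) -> Iterator[ReactionReadout]:
    """Yield every (individual, tube) readout, for writing to disk.

    Identical streams to :func:`run_cohort`: decoding written files gives the
    same result as the in-memory run.
    """
    models = _tube_models(truth, primers, layout, max_amplicon_len)
    for i, (ind_id, a1, a2) in enumerate(truth.entries):
        for t, model in enumerate(models):
            tube_noise = _derived_noise(
                noise, base_seed if base_seed is not None else truth.spec.seed,
                i, t,
            )
            rng = tube_noise.rng()
            events, ratio = draw_readout_cells(
                model.truth_matrix(a1, a2), tube_noise, rng
            )
            yield ReactionReadout(model.labels, events, ratio,
                                  individual_id=ind_id, tube_id=model.tube_id)


def recovery_rate(decoded: Mapping[str, DecodedResult], truth: TruthSet,
                  site_positions: Sequence[int]) -> float:
    """Fraction of individuals whose decode is status-ok and equals the true
    haplotype pair (unordered) over the polymorphic sites."""
    from collections import Counter

    ok = 0
    ids = truth.individual_ids
    for i, ind_id in enumerate(ids):
        result = decoded.get(ind_id)
        if result is None or result.status != "ok":
            continue
        t1, t2 = truth.site_map_pair(i, site_positions)
        truth_key = frozenset(
            Counter(
                (tuple(sorted(t1.items())), tuple(sorted(t2.items())))
            ).items()
        )
        if result.unordered_pair() == truth_key:
            ok += 1
    return ok / len(ids)
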