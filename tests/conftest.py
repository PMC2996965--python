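"""Shared fixtures: programmatically built toy assays and study-scale
synthetic cohorts (all text-free; everything is generated at test time)."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pytest
from hypothesis import settings

from transcistor.allele_panel import Allele, AllelePanel
from transcistor.assay_sim import AssayNoiseModel, HaplotypePair
from transcistor.pipeline import CohortRun, run_cohort
from transcistor.primer_design import ArmsPrimer, PrimerPanel, design_full_panel
from transcistor.synthetic_cohort import (
    CohortSpec,
    TruthSet,
    default_reaction_layout,
    generate_panel,
    sample_cohort,
)

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@dataclass(frozen=True)
class ToyAssay:
    """A two-site, four-allele toy locus with split primers at both sites.

    Site A (position 40) carries A/G, site B (position 80) carries C/T; the
    four alleles cover every two-site haplotype, so any diploid genotype can
    be built with :meth:`genotype`.
    """

    panel: AllelePanel
    primers: PrimerPanel
    backbone: str
    site_a: int
    site_b: int

    def sequence(self, base_a: str, base_b: str) -> str:
        s = list(self.backbone)
        s[self.site_a - 1] = base_a
        s[self.site_b - 1] = base_b
        return "".join(s)

    def genotype(self, hap1: tuple[str, str], hap2: tuple[str, str]
                 ) -> HaplotypePair:
        return HaplotypePair(self.sequence(*hap1), self.sequence(*hap2))

    @property
    def fwd_pair(self) -> list[ArmsPrimer]:
        return [p for p in self.primers.forwards() if p.site == self.site_a]

    @property
    def rev_pair(self) -> list[ArmsPrimer]:
        return [p for p in self.primers.reverses() if p.site == self.site_b]


def build_toy_assay(seed: int = 3) -> ToyAssay:
    rng = np.random.default_rng(seed)
    backbone = "".join(rng.choice(list("ACGT"), 120))
    site_a, site_b = 40, 80
    def mk(a, b):
        s = list(backbone)
        s[site_a - 1], s[site_b - 1] = a, b
        return "".join(s)
    panel = AllelePanel([
        Allele("A1B1", mk("A", "C")),
        Allele("A2B2", mk("G", "T")),
        Allele("A1B2", mk("A", "T")),
        Allele("A2B1", mk("G", "C")),
    ])
    return ToyAssay(panel, design_full_panel(panel), backbone, site_a, site_b)


@pytest.fixture(scope="session")
def toy() -> ToyAssay:
    return build_toy_assay()


@dataclass(frozen=True)
class World:
    """A generated locus with designed primers, layout and sampled cohort."""

    spec: CohortSpec
    panel: AllelePanel
    primers: PrimerPanel
    layout: object
    truth: TruthSet


def build_world(spec: CohortSpec) -> World:
    panel = generate_panel(spec)
    primers = design_full_panel(panel)
    layout = default_reaction_layout(panel, primers)
    truth = sample_cohort(panel, spec)
    return World(spec, panel, primers, layout, truth)


@pytest.fixture(scope="session")
def small_world() -> World:
    """Ten-site, twelve-allele locus with a 200-individual cohort (one tube)."""
    return build_world(
        CohortSpec(seed=5, n_alleles=12, n_polymorphic_sites=10,
                   n_individuals=200)
    )


@pytest.fixture(scope="session")
def eight_site_world() -> World:
    """Eight biallelic sites in one tube, for the exhaustive phase oracle."""
    return build_world(
        CohortSpec(seed=8, n_alleles=10, n_polymorphic_sites=8,
                   fraction_multiallelic=0.0, n_individuals=10,
                   alignment_length=200)
    )


@pytest.fixture(scope="session")
def study_world() -> World:
    """Study-scale conditions: 237 bp, 60 sites, 33 alleles at the published
    skewed spectrum, 109 individuals under Hardy-Weinberg sampling."""
    return build_world(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def study_run_zero(study_world: World) -> CohortRun:
    return run_cohort(study_world.truth, study_world.primers,
                      study_world.layout)


@pytest.fixture(scope="session")
def study_run_noisy(study_world: World) -> CohortRun:
    noise = AssayNoiseModel(dropout_rate=0.005, false_capture_rate=0.005)
    return run_cohort(study_world.truth, study_world.primers,
                      study_world.layout, noise=noise)


@pytest.fixture(scope="session")
def robustness_world() -> World:
    """Ten-site locus with a 1,000-individual cohort for noise-robustness
    and decoder-contract checks."""
    return build_world(
        CohortSpec(seed=17, n_alleles=12, n_polymorphic_sites=10,
                   n_individuals=1000)
    )


@pytest.fixture(scope="session")
def robustness_run(robustness_world: World) -> CohortRun:
    noise = AssayNoiseModel(dropout_rate=0.01, false_capture_rate=0.01)
    return run_cohort(robustness_world.truth, robustness_world.primers,
                      robustness_world.layout, noise=noise)
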