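"""Positivity rules, cis-constraint extraction, haplotype assembly, and the
exhaustive phase oracle."""

from collections import Counter

import numpy as np
import pytest

from transcistor.assay_sim import AssayNoiseModel, ReactionReadout, simulate_readout
from transcistor.phase_decoder import (
    GenotypeCalls,
    PhaseConstraint,
    PositivityRule,
    assemble_haplotypes,
    brute_force_oracle,
    call_positive,
    decode_individual,
    extract_constraints,
    genotype_from_positives,
)

ZERO = dict(pos_events_sd=0.0, neg_events_sd=0.0)


def manual_readout(toy, cells):
    """Dense background readout with selected (anchored, label) cells set to
    (events, ratio)."""
    labels = list(toy.primers.labels)
    n = len(labels)
    events = np.full((n, n), 9)
    ratio = np.full((n, n), 1.0)
    idx = {l: i for i, l in enumerate(labels)}
    for (anchored, label), (e, q) in cells.items():
        events[idx[anchored], idx[label]] = e
        ratio[idx[anchored], idx[label]] = q
    return ReactionReadout(labels, events, ratio)


class TestCallPositive:
    def test_both_duplicate_cells_passing_scores_positive(self, toy):
        ro = manual_readout(toy, {
            ("F40 a", "R80 g"): (195, 10.0),
            ("R80 g", "F40 a"): (195, 10.0),
        })
        assert call_positive(ro, PositivityRule(), toy.primers) == {
            ("F40 a", "R80 g")
        }

    def test_background_cells_score_negative(self, toy):
        ro = manual_readout(toy, {})
        assert call_positive(ro, PositivityRule(), toy.primers) == set()

    def test_one_failing_bead_vetoes_the_reaction(self, toy):
        ro = manual_readout(toy, {("F40 a", "R80 g"): (195, 10.0)})
        assert call_positive(ro, PositivityRule(), toy.primers) == set()
        # relaxing the both-beads rule admits it
        relaxed = PositivityRule(require_both_beads=False)
        assert call_positive(ro, relaxed, toy.primers) == {("F40 a", "R80 g")}

    def test_thresholds_are_inclusive(self, toy):
        ro = manual_readout(toy, {
            ("F40 a", "R80 g"): (100, 4.0),
            ("R80 g", "F40 a"): (100, 4.0),
        })
        assert call_positive(ro, PositivityRule(), toy.primers) == {
            ("F40 a", "R80 g")
        }

    def test_raising_min_events_only_shrinks_the_positive_set(self, toy):
        g = toy.genotype(("A", "C"), ("G", "T"))
        ro = simulate_readout(g, toy.primers, AssayNoiseModel(seed=3))
        previous = None
        for min_events in (50, 100, 150, 200, 250):
            rule = PositivityRule(min_events=min_events)
            current = call_positive(ro, rule, toy.primers)
            if previous is not None:
                assert current <= previous
            previous = current


class TestGenotypeFromPositives:
    def test_homozygote_calls_single_bases(self, toy):
        g = toy.genotype(("A", "C"), ("A", "C"))
        ro = simulate_readout(g, toy.primers, AssayNoiseModel(seed=1, **ZERO))
        pos = call_positive(ro, PositivityRule(), toy.primers)
        calls = genotype_from_positives(pos, toy.primers)
        assert calls.calls == {40: ("A",), 80: ("C",)}
        assert calls.missing == ()

    def test_double_het_calls_two_bases_per_site(self, toy):
        g = toy.genotype(("A", "C"), ("G", "T"))
        ro = simulate_readout(g, toy.primers, AssayNoiseModel(seed=1, **ZERO))
        pos = call_positive(ro, PositivityRule(), toy.primers)
        calls = genotype_from_positives(pos, toy.primers)
        assert calls.calls == {40: ("A", "G"), 80: ("C", "T")}

    def test_low_support_bases_filtered_when_demanded(self, toy):
        positives = [("F40 a", "R80 g"), ("F40 a", "R80 g")]
        strict = genotype_from_positives(positives, toy.primers,
                                         min_base_support=2)
        assert strict.calls == {40: ("A",), 80: ("C",)}
        lax = genotype_from_positives([("F40 a", "R80 g")], toy.primers,
                                      min_base_support=2)
        assert lax.calls == {}
        assert set(lax.missing) == {40, 80}


class TestAssembly:
    def test_fully_homozygous_gives_one_haplotype(self):
        calls = GenotypeCalls({10: ("A",), 20: ("C",)})
        result = assemble_haplotypes([], calls)
        assert result.status == "ok"
        assert result.haplotypes == ({10: "A", 20: "C"},)

    def test_double_het_phases_from_single_constraint(self):
        calls = GenotypeCalls({10: ("A", "G"), 20: ("C", "T")})
        cis = [PhaseConstraint(10, 20, "A", "T", support=2)]
        result = assemble_haplotypes(cis, calls)
        assert result.status == "ok"
        assert set(result.haplotype_strings([10, 20])) == {"AT", "GC"}

    def test_spiked_false_reactions_tie_votes_and_conflict(self, toy):
        g = toy.genotype(("A", "C"), ("G", "T"))
        ro = simulate_readout(g, toy.primers, AssayNoiseModel(seed=1, **ZERO))
        pos = set(call_positive(ro, PositivityRule(), toy.primers))
        pos.add(("F40 g", "R80 g"))  # spike: asserts C at site 80 again, G at 40
        pos.add(("F40 a", "R80 a"))  # spike: asserts T at 80 with A at 40
        calls = genotype_from_positives(pos, toy.primers)
        result = assemble_haplotypes(extract_constraints(pos, toy.primers), calls)
        # calls stay <=2 bases here, but phase votes now tie -> conflicted
        assert result.status == "conflicted"

    def test_overcalled_site_is_conflicted(self):
        calls = GenotypeCalls({10: ("A", "C", "G"), 20: ("C",)})
        result = assemble_haplotypes([], calls)
        assert result.status == "conflicted"
        assert "3 bases" in result.diagnostics[0]

    def test_unconnected_het_sites_are_ambiguous(self):
        calls = GenotypeCalls({10: ("A", "G"), 20: ("C", "T"), 30: ("A", "T")})
        cis = [PhaseConstraint(10, 20, "A", "C", support=1)]
        result = assemble_haplotypes(cis, calls)
        assert result.status == "ambiguous"
        assert "[30]" in result.diagnostics[-1]

    def test_majority_support_overrides_minority_conflict(self):
        calls = GenotypeCalls({10: ("A", "G"), 20: ("C", "T")})
        cis = [
            PhaseConstraint(10, 20, "A", "C", support=3),
            PhaseConstraint(10, 20, "A", "T", support=1),
        ]
        result = assemble_haplotypes(cis, calls)
        assert result.status == "ok"
        assert set(result.haplotype_strings([10, 20])) == {"AC", "GT"}

    def test_tied_support_is_conflicted(self):
        calls = GenotypeCalls({10: ("A", "G"), 20: ("C", "T")})
        cis = [
            PhaseConstraint(10, 20, "A", "C", support=2),
            PhaseConstraint(10, 20, "A", "T", support=2),
        ]
        assert assemble_haplotypes(cis, calls).status == "conflicted"

    def test_strict_mode_refuses_any_conflict(self):
        calls = GenotypeCalls({10: ("A", "G"), 20: ("C", "T")})
        cis = [
            PhaseConstraint(10, 20, "A", "C", support=3),
            PhaseConstraint(10, 20, "A", "T", support=1),
        ]
        assert assemble_haplotypes(cis, calls, strict=True).status == "conflicted"

    def test_never_more_than_two_haplotypes(self, small_world):
        from transcistor.pipeline import run_cohort

        run = run_cohort(small_world.truth, small_world.primers,
                         small_world.layout)
        assert all(len(r.haplotypes) <= 2 for r in run.decoded.values())


def _random_genotype(world, rng):
    """A random diploid phase configuration over the world's sites (not
    necessarily a pair of panel alleles)."""
    from transcistor.allele_panel import find_polymorphic_sites
    from transcistor.assay_sim import HaplotypePair

    sites = find_polymorphic_sites(world.panel)
    backbone = list(world.panel.alleles[0].sequence)
    h1, h2 = backbone[:], backbone[:]
    for s in sites:
        bases = sorted(s.observed_bases)
        if rng.random() < 0.5:  # heterozygous
            b1, b2 = rng.choice(bases, 2, replace=False)
        else:
            b1 = b2 = rng.choice(bases)
        h1[s.position - 1], h2[s.position - 1] = b1, b2
    return HaplotypePair("".join(h1), "".join(h2))


class TestOracle:
    def test_no_het_sites_single_trivial_survivor(self, toy):
        g = toy.genotype(("A", "C"), ("A", "C"))
        ro = simulate_readout(g, toy.primers, AssayNoiseModel(seed=1, **ZERO))
        pos = call_positive(ro, PositivityRule(), toy.primers)
        calls = genotype_from_positives(pos, toy.primers)
        survivors = brute_force_oracle(calls, pos, toy.primers)
        assert len(survivors) == 1

    def test_double_het_unique_survivor_matches_truth(self, toy):
        g = toy.genotype(("A", "C"), ("G", "T"))
        ro = simulate_readout(g, toy.primers, AssayNoiseModel(seed=1, **ZERO))
        pos = call_positive(ro, PositivityRule(), toy.primers)
        calls = genotype_from_positives(pos, toy.primers)
        survivors = brute_force_oracle(calls, pos, toy.primers)
        assert len(survivors) == 1
        (pair,) = survivors
        haps = {tuple(sorted(dict(h).items())) for h, _ in pair}
        assert haps == {((40, "A"), (80, "C")), ((40, "G"), (80, "T"))}

    def test_guard_refuses_large_het_counts(self, toy):
        calls = GenotypeCalls({i: ("A", "G") for i in range(1, 14)})
        with pytest.raises(ValueError, match="12"):
            brute_force_oracle(calls, set(), toy.primers)

    def test_decoder_agrees_with_oracle_on_random_genotypes(
        self, eight_site_world
    ):
        """On 500 seeded random diploids (<=8 het sites, full pairwise
        coverage), the decoder's ok-status answers are exactly the oracle's
        unique survivors."""
        world = eight_site_world
        rng = np.random.default_rng(2024)
        rule = PositivityRule()
        noise = AssayNoiseModel(seed=0, **ZERO)
        for _ in range(500):
            g = _random_genotype(world, rng)
            ro = simulate_readout(g, world.primers, noise)
            pos = call_positive(ro, rule, world.primers)
            calls = genotype_from_positives(pos, world.primers)
            decoded = assemble_haplotypes(
                extract_constraints(pos, world.primers), calls
            )
            survivors = brute_force_oracle(calls, pos, world.primers)
            if decoded.status == "ok":
                assert len(survivors) == 1
                assert next(iter(survivors)) == decoded.unordered_pair()
            else:
                assert len(survivors) != 1
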