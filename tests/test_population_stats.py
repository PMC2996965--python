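"""Frequency tables, carrier counts, composite vs direct LD."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from transcistor.allele_panel import find_polymorphic_sites
from transcistor.datasets import allele_frequency_table
from transcistor.phase_decoder import DecodedResult, GenotypeCalls
from transcistor.population_stats import (
    FrequencyTable,
    carriers_by_count,
    composite_ld,
    direct_ld,
    frequency_table,
    ld_compare,
    top_k_cumulative,
)


def _ok_result(hap1, hap2):
    calls = {s: tuple(sorted({hap1[s], hap2[s]})) for s in hap1}
    haps = (hap1,) if hap1 == hap2 else (hap1, hap2)
    return DecodedResult("ok", haps, GenotypeCalls(calls))


class TestFrequencyTable:
    def test_two_identical_homozygotes_give_100_percent(self, small_world):
        panel = small_world.panel
        sites = [s.position for s in
                 find_polymorphic_sites(panel)]
        hap = {p: panel.alleles[0].sequence[p - 1] for p in sites}
        cohort = {"I1": _ok_result(hap, hap), "I2": _ok_result(hap, hap)}
        table = frequency_table(cohort, panel)
        assert table.n_alleles == 1
        assert table.table.frequency_percent.iloc[0] == 100.0
        assert table.table.allele_name.iloc[0] == panel.alleles[0].name

    def test_chromosome_conservation_is_exact(self, study_run_zero, study_world):
        table = frequency_table(study_run_zero.decoded, study_world.panel)
        assert int(table.table.chromosome_count.sum()) == table.n_chromosomes

    def test_failed_individuals_are_excluded_and_n_adjusted(self, small_world):
        panel = small_world.panel
        sites = [s.position for s in
                 find_polymorphic_sites(panel)]
        hap = {p: panel.alleles[0].sequence[p - 1] for p in sites}
        cohort = {
            "I1": _ok_result(hap, hap),
            "I2": DecodedResult("conflicted", (), GenotypeCalls({})),
        }
        table = frequency_table(cohort, panel)
        assert table.excluded == ("I2",)
        assert table.n_individuals == 1

    def test_frequency_sum_validation(self):
        import pandas as pd

        df = pd.DataFrame({
            "allele_name": ["x", "y"],
            "chromosome_count": [3, 1],
            "frequency_percent": [75.0, 20.0],  # sums to 95
        })
        with pytest.raises(ValueError, match="sum"):
            FrequencyTable(df, 2)


class TestPublishedSpectrum:
    def test_carrier_counts(self):
        table = allele_frequency_table()
        assert carriers_by_count(table, 1) == 11
        assert carriers_by_count(table, 2) == 7

    def test_count_conservation_within_rounding(self):
        table = allele_frequency_table()
        total = sum(
            k * carriers_by_count(table, k)
            for k in sorted(set(table.table.chromosome_count))
        )
        assert abs(total - table.n_chromosomes) <= 2  # printed 1-decimal drift

    def test_top_k(self):
        table = allele_frequency_table()
        assert top_k_cumulative(table, 1) == 23.1
        assert top_k_cumulative(table, 33) == pytest.approx(100.3)
        with pytest.raises(ValueError):
            top_k_cumulative(table, 34)


def _composite_oracle(na, nb):
    """Independent recount of the composite coefficient over the 9 genotype
    classes."""
    na, nb = np.asarray(na), np.asarray(nb)
    n = len(na)
    classes = {
        (i, j): int(((na == i) & (nb == j)).sum())
        for i in (0, 1, 2) for j in (0, 1, 2)
    }
    p_a = na.mean() / 2
    p_b = nb.mean() / 2
    delta = (
        2 * classes[(2, 2)] + classes[(2, 1)] + classes[(1, 2)]
        + 0.5 * classes[(1, 1)]
    ) / n - 2 * p_a * p_b
    return delta


class TestCompositeLD:
    def test_perfect_coupling_population(self):
        # half AABB, half aabb
        na = [2] * 10 + [0] * 10
        nb = [2] * 10 + [0] * 10
        result = composite_ld(na, nb)
        assert result.D == pytest.approx(0.5)
        assert result.r == pytest.approx(1.0)

    def test_independent_sites_have_near_zero_r(self):
        rng = np.random.default_rng(0)
        na = rng.binomial(2, 0.5, 20000)
        nb = rng.binomial(2, 0.5, 20000)
        assert abs(composite_ld(na, nb).r) < 0.05

    @given(st.integers(0, 2**31 - 1))
    def test_delta_matches_class_recount_oracle(self, seed):
        rng = np.random.default_rng(seed)
        na = rng.integers(0, 3, 50)
        nb = rng.integers(0, 3, 50)
        if len(set(na)) == 1 or len(set(nb)) == 1:
            return
        result = composite_ld(na, nb)
        assert result.D == pytest.approx(_composite_oracle(na, nb))

    @given(st.integers(0, 2**31 - 1))
    def test_r_bounded_and_sign_symmetric(self, seed):
        rng = np.random.default_rng(seed)
        na = rng.integers(0, 3, 40)
        nb = rng.integers(0, 3, 40)
        if len(set(na)) == 1 or len(set(nb)) == 1:
            return
        result = composite_ld(na, nb)
        assert -1 - 1e-9 <= result.r <= 1 + 1e-9
        flipped = composite_ld(2 - na, nb)
        assert flipped.r == pytest.approx(-result.r)
        assert flipped.D == pytest.approx(-result.D)

    def test_monomorphic_site_is_an_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            composite_ld([2, 2, 2], [0, 1, 2])


class TestDirectLD:
    def test_complete_coupling(self):
        xa = [1] * 10 + [0] * 10
        xb = [1] * 10 + [0] * 10
        result = direct_ld(xa, xb)
        assert result.D == pytest.approx(0.25)
        assert result.r == pytest.approx(1.0)
        assert result.p_AB == pytest.approx(0.5)

    def test_constructed_equilibrium_gives_zero(self):
        # chromosomes AB, Ab, aB, ab in equal number: p_AB = p_A p_B exactly
        xa = [1, 1, 0, 0] * 5
        xb = [1, 0, 1, 0] * 5
        result = direct_ld(xa, xb)
        assert result.D == pytest.approx(0.0)
        assert result.r == pytest.approx(0.0)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(1)
        xa = rng.integers(0, 2, 100)
        xb = rng.integers(0, 2, 100)
        r1 = direct_ld(xa, xb)
        r2 = direct_ld(1 - xa, xb)
        assert r2.r == pytest.approx(-r1.r)
        assert r2.D == pytest.approx(-r1.D)

    def test_monomorphic_site_is_an_error(self):
        with pytest.raises(ValueError, match="monomorphic"):
            direct_ld([1, 1, 1], [0, 1, 0])


def _excess_coupling_cohort(n_double_het=640, n_random=960):
    """Deterministic two-site cohort where gametic (direct) LD is strong but
    the composite estimator sees none of it: an excess of AB/ab double
    heterozygotes over an otherwise equilibrium background (every ordered
    gamete pair equally often)."""
    cohort = [("AB", "ab")] * n_double_het
    gametes = ["AB", "Ab", "aB", "ab"]
    per = n_random // 16
    for g1 in gametes:
        for g2 in gametes:
            cohort += [(g1, g2)] * per
    return cohort


class TestLDCompare:
    def test_monomorphic_site_propagates_error(self):
        cohort = [("AB", "AB"), ("Ab", "Ab")]
        with pytest.raises(ValueError, match="monomorphic"):
            ld_compare(cohort, 1, 2, "A", "B")

    def test_hwe_violation_separates_the_estimators(self):
        """Excess double-het coupling inflates direct LD relative to the
        composite estimate, in the direction the construction dictates."""
        cohort = _excess_coupling_cohort()
        report = ld_compare(cohort, 1, 2, "A", "B")
        q = 640 / 1600  # fraction of forced AB/ab individuals
        assert report.direct.r == pytest.approx(q, abs=1e-9)
        assert report.composite.r == pytest.approx(0.0, abs=1e-9)
        assert report.direct.r > report.composite.r
        assert report.modal_haplotype in {"AB", "ab"}

    def test_random_mating_estimators_agree(self):
        """Under random union of gametes the composite estimator recovers the
        gametic D; at n=10,000 the two r's sit within Monte-Carlo error."""
        rng = np.random.default_rng(42)
        n = 10_000
        # gamete pool with built-in D = 0.1
        pool = ["AB"] * 35 + ["Ab"] * 15 + ["aB"] * 15 + ["ab"] * 35
        draws = rng.choice(pool, size=(n, 2))
        cohort = [tuple(row) for row in draws]
        report = ld_compare(cohort, 1, 2, "A", "B")
        mc_se = (1 - report.direct.r**2) / np.sqrt(n)
        assert abs(report.composite.r - report.direct.r) <= 3 * mc_se
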