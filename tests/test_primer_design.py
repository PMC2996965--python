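"""ARMS primer design: degenerate expansion, Tm, screens, TSV dialect."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from transcistor._iupac import IUPAC_TO_BASES, reverse_complement
from transcistor.allele_panel import find_polymorphic_sites
from transcistor.datasets import load_published_primers, table2_path
from transcistor.primer_design import (
    ArmsPrimer,
    DesignConstraints,
    complementarity_screen,
    design_allele_specific_primers,
    expand_degenerate,
    matches_template,
    read_primer_table,
    tm_estimate,
    write_primer_table,
)


class TestExpandDegenerate:
    @pytest.mark.parametrize(
        "seq, expected",
        [
            ("ACGT", ["ACGT"]),
            ("ARY", ["AAC", "AAT", "AGC", "AGT"]),
        ],
    )
    def test_expansion_values(self, seq, expected):
        assert expand_degenerate(seq) == expected

    def test_published_fourfold_wobble_primer_expands_to_16(self):
        primers = load_published_primers()
        assert len(expand_degenerate(primers["F1 c/t"])) == 16  # R,M,R,Y

    def test_invalid_code_names_position(self):
        with pytest.raises(ValueError, match="position 3"):
            expand_degenerate("ACXT")

    @given(st.text(alphabet=sorted(IUPAC_TO_BASES), min_size=1, max_size=8))
    def test_count_is_product_of_cardinalities(self, seq):
        expected = math.prod(len(IUPAC_TO_BASES[c]) for c in seq)
        exps = expand_degenerate(seq)
        assert len(exps) == expected
        assert exps == sorted(exps)  # deterministic lexicographic order


class TestTmEstimate:
    def test_gc_raises_tm_at_fixed_length(self):
        assert tm_estimate("A" * 16) < tm_estimate("G" * 16)

    def test_wallace_rule_exact(self):
        # 2(A+T) + 4(G+C) on a 12-mer with 6 GC
        assert tm_estimate("ACGTACGTACGT", "wallace") == 36.0

    @pytest.mark.parametrize("method", ["nn", "wallace"])
    def test_reverse_complement_symmetry(self, method):
        seq = "ACGTTGCAGGTCAT"
        rc = reverse_complement(seq)
        assert tm_estimate(seq, method) == pytest.approx(
            tm_estimate(rc, method), abs=1e-9
        )

    def test_short_sequence_rejected(self):
        with pytest.raises(ValueError, match="short"):
            tm_estimate("ACGTACG")


class TestDesign:
    def test_biallelic_site_gives_two_primers_differing_at_3prime(self, toy):
        primers = design_allele_specific_primers(toy.panel, toy.site_a,
                                                 "forward")
        assert len(primers) == 2
        a, b = primers
        assert a.sequence[:-1] == b.sequence[:-1]
        assert a.sequence[-1] != b.sequence[-1]
        assert {p.template_base for p in primers} == {"A", "G"}

    def test_triallelic_site_gives_three_primers(self, small_world):
        multi = [s for s in find_polymorphic_sites(small_world.panel)
                 if len(s.observed_bases) >= 3]
        assert multi, "small world should carry a multiallelic site"
        primers = design_allele_specific_primers(
            small_world.panel, multi[0], "forward", fallback_closest=True,
        )
        assert len(primers) == len(multi[0].observed_bases)

    def test_designed_footprints_match_a_panel_allele(self, small_world):
        for s in find_polymorphic_sites(small_world.panel):
            for orientation in ("forward", "reverse"):
                for p in design_allele_specific_primers(
                    small_world.panel, s, orientation, fallback_closest=True,
                ):
                    assert any(
                        matches_template(p, a.sequence)
                        for a in small_world.panel
                    ), p.label

    def test_no_shared_3prime_base_per_site_orientation(self, small_world):
        for s in find_polymorphic_sites(small_world.panel):
            primers = design_allele_specific_primers(
                small_world.panel, s, "forward", fallback_closest=True
            )
            termini = [p.sequence[-1] for p in primers]
            assert len(set(termini)) == len(termini)

    def test_unreachable_tm_window_yields_empty_not_exception(self, toy):
        impossible = DesignConstraints(tm_target_c=150.0, tm_tolerance_c=0.1,
                                       min_length=14, max_length=16)
        out = design_allele_specific_primers(toy.panel, toy.site_a, "forward",
                                             impossible)
        assert out == []

    def test_designed_tm_lands_in_window(self, toy):
        constraints = DesignConstraints()
        for p in design_allele_specific_primers(toy.panel, toy.site_a,
                                                "forward", constraints):
            tm = tm_estimate(p.sequence)
            assert abs(tm - constraints.tm_target_c) <= constraints.tm_tolerance_c


class TestComplementarityScreen:
    def test_perfect_dimer_fails(self):
        seq = "ACGTTGCAGGTCA"
        report = complementarity_screen(seq, reverse_complement(seq))
        assert not report.passed
        assert report.max_run == len(seq)

    def test_poly_a_primers_pass(self):
        report = complementarity_screen("A" * 18, "A" * 18)
        assert report.passed
        assert report.max_run == 0

    def test_three_prime_anchored_run_fails_even_when_short(self):
        # 6-nt 3'-anchored complement exceeds the 4-nt limit but not the
        # 8-nt overall pair limit
        p = "AAAAAAAAGGGCCC"
        q = "TTTTTTTTGGGCCC"  # 3' GGGCCC pairs with p's 3' GGGCCC
        report = complementarity_screen(p, q)
        assert not report.passed
        assert report.three_prime_run >= 6

    def test_published_panel_screen_completes(self):
        primers = load_published_primers()
        reports = {
            (f.label, r.label): complementarity_screen(f, r)
            for f in primers.forwards()
            for r in primers.reverses()
        }
        assert len(reports) == len(primers.forwards()) * len(primers.reverses())
        assert all(r.max_run >= 0 for r in reports.values())


class TestPrimerTable:
    def test_published_rows_load_with_coordinates_as_printed(self):
        panel = load_published_primers()
        f1 = panel["F1 c/t"]
        assert (f1.ref_start, f1.ref_end, f1.length) == (13, 30, 18)
        r1 = panel["R1 g/a/t"]
        assert r1.orientation == "reverse"
        assert (r1.ref_start, r1.ref_end, r1.length) == (172, 157, 16)
        assert r1.discriminating_bases == frozenset("GAT")

    def test_span_length_invariant_holds_on_loaded_panel(self):
        for p in load_published_primers():
            assert abs(p.ref_end - p.ref_start) + 1 == p.length

    def test_strict_policy_raises_naming_the_row(self):
        with pytest.raises(ValueError, match="F4"):
            read_primer_table(table2_path(), coord_policy="strict")

    def test_span_sequence_mismatch_is_a_load_error(self, tmp_path):
        bad = tmp_path / "bad.tsv"
        bad.write_text(
            "label\torientation\tsequence\tref_start\tref_end\n"
            "P1 a\tforward\tACGTACGTACGT\t1\t10\n"
        )
        with pytest.raises(ValueError, match="P1 a"):
            read_primer_table(bad)

    def test_round_trip_identity(self, tmp_path):
        panel = load_published_primers()
        out = tmp_path / "primers.tsv"
        write_primer_table(panel, out)
        back = read_primer_table(out)
        assert back.labels == panel.labels
        for label in panel.labels:
            assert back[label] == panel[label]


def test_arms_primer_validates_span():
    with pytest.raises(ValueError, match="span"):
        ArmsPrimer("bad", "forward", "ACGT", 1, 6, frozenset("T"))
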