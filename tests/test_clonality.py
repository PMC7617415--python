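"""Purity-VAF-copy-number algebra, allele assignment and clonality calls."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rasco.clonality import (
    AlleleCopyContext,
    AssignmentStatus,
    ClonalityCall,
    assign_mutant_copy_number,
    corrected_allele_fraction,
    expected_vaf,
    solve_purity,
    test_pair_clonality as pair_clonality,
)


class TestExpectedVaf:
    def test_pure_diploid_heterozygote(self):
        assert expected_vaf(1.0, 1, 1) == 0.5

    def test_diploid_closed_form_is_half_purity(self):
        for p in np.linspace(0.05, 1.0, 20):
            assert expected_vaf(p, 1, 1) == pytest.approx(p / 2, abs=1e-15)

    def test_direct_evaluation_and_binomial_cross_check(self):
        v = expected_vaf(0.6, 2, 1)
        assert v == pytest.approx(1.2 / 2.6, abs=1e-12)
        rng = np.random.default_rng(11)
        emp = rng.binomial(10**6, v) / 10**6
        assert emp == pytest.approx(v, abs=3 * math.sqrt(v * (1 - v) / 10**6))

    def test_assignment_swap_changes_vaf(self):
        assert expected_vaf(0.5, 2, 1) == pytest.approx(0.4)
        assert expected_vaf(0.5, 1, 2) == pytest.approx(0.2)

    def test_no_mutant_copies_gives_zero(self):
        assert expected_vaf(0.7, 0, 2) == 0.0

    def test_purity_contract(self):
        with pytest.raises(ValueError):
            expected_vaf(0.0, 1, 1)
        with pytest.raises(ValueError):
            expected_vaf(1.2, 1, 1)

    @given(
        st.floats(0.05, 1.0), st.integers(1, 3), st.integers(0, 2),
    )
    @settings(max_examples=200, deadline=None)
    def test_monotone_in_purity_and_copies(self, p, m, w):
        v = expected_vaf(p, m, w)
        if p <= 0.99:
            assert expected_vaf(min(p + 0.01, 1.0), m, w) > v
        if w > 0 or p <= 0.99:  # saturated at VAF 1 when the tumor is pure and LOH-only
            assert expected_vaf(p, m + 1, w) > v
        assert expected_vaf(p, m, w + 1) < v


class TestSolvePurity:
    def test_inverse_of_pure_diploid_het(self):
        purity, valid = solve_purity(0.5, 1, 1)
        assert purity == pytest.approx(1.0) and valid

    def test_round_trip_of_expected_vaf(self):
        purity, valid = solve_purity(expected_vaf(0.6, 2, 1), 2, 1)
        assert purity == pytest.approx(0.6, abs=1e-12) and valid

    def test_impossible_vaf_flagged_invalid(self):
        purity, valid = solve_purity(0.9, 1, 1)
        assert purity == pytest.approx(1.8)
        assert not valid

    def test_zero_vaf_no_solution(self):
        _, valid = solve_purity(0.0, 1, 1)
        assert not valid

    def test_round_trip_identity_grid(self):
        """solve_purity o expected_vaf is the identity over the full grid."""
        for p in np.arange(0.1, 1.0001, 0.1):
            for m in (1, 2, 3):
                for w in (0, 1, 2):
                    implied, valid = solve_purity(expected_vaf(p, m, w), m, w)
                    assert valid
                    assert implied == pytest.approx(p, abs=1e-9)


class TestAssignment:
    def test_prefers_assignment_matching_sample_purity(self):
        asg = assign_mutant_copy_number(0.4, 0.5, (2, 1))
        assert (asg.n_mut, asg.n_wt_cancer) == (2, 1)
        assert asg.status is AssignmentStatus.unique
        assert asg.implied_purity == pytest.approx(0.5)

    def test_equal_copy_pair_unique_by_symmetry(self):
        asg = assign_mutant_copy_number(0.25, 0.5, (1, 1))
        assert (asg.n_mut, asg.n_wt_cancer) == (1, 1)
        assert asg.status is AssignmentStatus.unique

    def test_subclonal_signal_yields_no_fit(self):
        asg = assign_mutant_copy_number(0.05, 0.8, (1, 1))
        assert asg.status is AssignmentStatus.no_fit
        assert asg.implied_purity == pytest.approx(0.1, abs=0.01)

    def test_recovery_on_simulated_unambiguous_cases(self):
        """At depth >= 500 the generating assignment is recovered >= 99%."""
        from rasco.simulate import ReadSimConfig, generate_read_counts

        truth = generate_read_counts(
            ReadSimConfig(n_mutations=600, depth_low=500, depth_high=1500), seed=123
        )
        hits = total = 0
        for _, row in truth.iterrows():
            if row["major_cn"] == row["minor_cn"] or row["mutant_reads"] == 0:
                continue
            asg = assign_mutant_copy_number(
                row["mutant_reads"] / row["total_reads"],
                row["purity"],
                (int(row["major_cn"]), int(row["minor_cn"])),
            )
            if asg.status is not AssignmentStatus.unique:
                continue  # ambiguous/no-fit are abstentions, not errors
            total += 1
            hits += (asg.n_mut, asg.n_wt_cancer) == (int(row["n_mut"]), int(row["n_wt"]))
        assert total > 200
        assert hits / total >= 0.99


class TestCorrectedFraction:
    def test_clonal_mutation_near_one(self):
        rng = np.random.default_rng(5)
        v = expected_vaf(0.8, 1, 1)
        reads = rng.binomial(100000, v)
        ctx = AlleleCopyContext(0.8, 1, 1, reads, 100000)
        assert corrected_allele_fraction(ctx) == pytest.approx(1.0, abs=0.02)

    def test_half_clonal_mutation(self):
        rng = np.random.default_rng(6)
        v = 0.5 * expected_vaf(0.8, 1, 1)
        reads = rng.binomial(100000, v)
        ctx = AlleleCopyContext(0.8, 1, 1, reads, 100000)
        assert corrected_allele_fraction(ctx) == pytest.approx(0.5, abs=0.02)

    def test_no_fit_propagates(self):
        ctx = AlleleCopyContext(0.8, 1, 1, 5, 100, no_fit=True)
        assert math.isnan(corrected_allele_fraction(ctx))


class TestPairClonality:
    def test_coclonal_pair(self):
        # purity 0.8, both diploid het: expected VAF 0.4; 400/1000 reads each
        a = AlleleCopyContext(0.8, 1, 1, 400, 1000, "A")
        b = AlleleCopyContext(0.8, 1, 1, 400, 1000, "B")
        res = pair_clonality(a, b)
        assert res.call is ClonalityCall.co_clonal
        assert res.p_binomial[0] > 0.05 and res.p_binomial[1] > 0.05

    def test_subclonal_partner_not_coclonal(self):
        a = AlleleCopyContext(0.8, 1, 1, 400, 1000, "A")
        b = AlleleCopyContext(0.8, 1, 1, 150, 1000, "B")
        res = pair_clonality(a, b)
        assert res.call in (ClonalityCall.nested, ClonalityCall.distinct)
        assert res.p_binomial[1] < 1e-6

    def test_identical_contexts_chi2_zero(self):
        a = AlleleCopyContext(0.7, 1, 1, 300, 900, "A")
        b = AlleleCopyContext(0.7, 1, 1, 300, 900, "B")
        res = pair_clonality(a, b)
        assert res.chi2_statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_chi2 == pytest.approx(1.0)

    def test_zero_depth_rejected(self):
        a = AlleleCopyContext(0.7, 1, 1, 0, 0, "A")
        b = AlleleCopyContext(0.7, 1, 1, 10, 100, "B")
        with pytest.raises(ValueError):
            pair_clonality(a, b)


def test_pair_table_driver_roundtrip(tmp_path):
    """TSV-level clonality driver reproduces the direct API calls."""
    import pandas as pd
    from rasco.clonality import run_pair_table

    reads = pd.DataFrame(
        {
            "sample_id": ["T1", "T1"],
            "mutation_id": ["BRAF_D594G", "KRAS_L19F"],
            "mutant_reads": [400, 395],
            "total_reads": [1000, 1010],
        }
    )
    purity = pd.DataFrame({"sample_id": ["T1"], "purity": [0.8]})
    pairs = pd.DataFrame(
        {"sample_id": ["T1"], "mutation_a": ["BRAF_D594G"], "mutation_b": ["KRAS_L19F"]}
    )
    cn_map = pd.DataFrame(
        {
            "sample_id": ["T1", "T1"],
            "mutation_id": ["BRAF_D594G", "KRAS_L19F"],
            "major_cn": [1, 1],
            "minor_cn": [1, 1],
        }
    )
    out = run_pair_table(reads, purity, pairs, cn_map=cn_map)
    assert len(out) == 1
    assert out.loc[0, "call"] == "co_clonal"
    assert out.loc[0, "n_mut_a"] == 1 and out.loc[0, "n_wt_b"] == 1
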