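"""First-year decision-tree economics: unit costs, arm costs, break-even."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from otocost import (
    ArmProbabilities,
    BatchCostModel,
    CostInputs,
    NoBreakEvenError,
    batch_effect,
    break_even_cohort,
    calibrate_variable_saving,
    cohort_cost_table,
    expected_cost_conventional,
    expected_cost_genotyped,
    genotyping_unit_cost,
    per_patient_difference,
)

AMORT = 7_668.0


def probs_at_medians(**overrides) -> ArmProbabilities:
    base = dict(
        p1_high_risk=0.42,
        p2_dropout_cddp=0.03,
        p3_dropout_docetaxel=0.02,
        p4_oto_conventional=0.35,
        p5_oto_lowrisk_cddp=0.18,
        p6_oto_docetaxel=0.09,
    )
    base.update(overrides)
    return ArmProbabilities(**base)


class TestGenotypingUnitCost:
    def test_lookup_defaults(self):
        costs = CostInputs()
        assert genotyping_unit_cost(3, costs.genotyping_unit_usd_by_batch) == 26.27
        assert genotyping_unit_cost(5, costs.genotyping_unit_usd_by_batch) == 17.12

    def test_parametric_model_reproduces_lookup(self):
        model = BatchCostModel()
        assert model.unit_cost(3) == pytest.approx(26.27, abs=0.005)
        assert model.unit_cost(5) == pytest.approx(17.12, abs=0.005)

    def test_zero_cost_model(self):
        model = BatchCostModel(
            reagent_usd_per_test=0, control_tests_per_batch=0, labor_usd_per_batch=0
        )
        assert genotyping_unit_cost(4, model) == 0.0

    def test_unit_cost_non_increasing_in_batch_size(self):
        model = BatchCostModel()
        costs = [model.unit_cost(b) for b in range(1, 13)]
        assert all(a >= b for a, b in zip(costs, costs[1:]))

    def test_missing_batch_size_raises(self):
        with pytest.raises(KeyError):
            genotyping_unit_cost(7, {3: 26.27})


class TestArmCosts:
    def test_conventional_without_oto_cost_is_chemo_only(self):
        costs = CostInputs(first_year_oto_usd=0.0)
        assert expected_cost_conventional(probs_at_medians(), costs) == 307.02
        assert expected_cost_conventional(
            probs_at_medians(p4_oto_conventional=0.0),
            CostInputs(first_year_oto_usd=500.0),
        ) == 307.02

    def test_conventional_symbolic_expansion(self):
        h = 180.0
        costs = CostInputs(first_year_oto_usd=h)
        expected = 307.02 + 0.97 * 0.35 * h
        assert expected_cost_conventional(probs_at_medians(), costs) == pytest.approx(
            expected
        )

    def test_genotyped_symbolic_expansion(self):
        h = 200.0
        costs = CostInputs(first_year_oto_usd=h)
        got = expected_cost_genotyped(probs_at_medians(), costs, batch_size=3, cohort_n=500)
        oto_inc = 0.58 * 0.97 * 0.18 + 0.42 * 0.98 * 0.09
        expected = 26.27 + AMORT / 500 + 0.42 * 270.29 + 0.58 * 307.02 + oto_inc * h
        assert got == pytest.approx(expected)

    def test_degenerate_tree_reduces_to_conventional(self):
        """With no carriers, free testing and no amortization, the genotyped
        arm is the conventional arm with P5 in place of P4."""
        costs = CostInputs(
            genotyping_unit_usd_by_batch={3: 0.0},
            equipment_usd=0.0,
            annual_amortization_usd=0.0,
            first_year_oto_usd=321.0,
        )
        p = probs_at_medians(p1_high_risk=0.0)
        geno = expected_cost_genotyped(p, costs, batch_size=3, cohort_n=100)
        conv_with_p5 = expected_cost_conventional(
            probs_at_medians(p1_high_risk=0.0, p4_oto_conventional=p.p5_oto_lowrisk_cddp),
            costs,
        )
        assert geno == pytest.approx(conv_with_p5)

    def test_amortization_share_vanishes_for_large_cohorts(self):
        costs = CostInputs(
            cddp_course_usd=0,
            docetaxel_course_usd=0,
            genotyping_unit_usd_by_batch={3: 0.0},
            hearing_annual_usd=0,
            first_year_oto_usd=0.0,
        )
        got = expected_cost_genotyped(probs_at_medians(), costs, 3, cohort_n=10**9)
        assert got == pytest.approx(0.0, abs=1e-4)

    def test_cost_decreases_with_cheaper_assay(self):
        costs_hi = CostInputs(first_year_oto_usd=100.0)
        p = probs_at_medians()
        hi = expected_cost_genotyped(p, costs_hi, 3, 500)
        lo = expected_cost_genotyped(p, costs_hi, 5, 500)
        assert lo < hi

    def test_requires_oto_cost(self):
        with pytest.raises(ValueError, match="first_year_oto_usd"):
            expected_cost_conventional(probs_at_medians(), CostInputs())


class TestDifferenceCalibration:
    def test_calibration_from_reference_row(self):
        assert calibrate_variable_saving(14.01, AMORT, 500) == pytest.approx(29.346)
        assert calibrate_variable_saving(0, 0, 100) == 0
        assert calibrate_variable_saving(23.16, AMORT, 500) == pytest.approx(38.496)

    # the full published difference column (cohort size -> USD difference)
    REPORTED_DIFFS = {
        25: -277.37, 50: -124.01, 75: -72.89, 100: -47.33, 125: -32.00,
        150: -21.77, 175: -14.47, 200: -8.99, 225: -4.73, 250: -1.32,
        275: 1.46, 300: 3.79, 325: 5.75, 350: 7.44, 375: 8.90,
        400: 10.18, 425: 11.31, 450: 12.31, 475: 13.20, 500: 14.01,
    }

    @pytest.mark.parametrize("n, reported", sorted(REPORTED_DIFFS.items()))
    def test_single_calibration_reproduces_entire_column(self, n, reported):
        """K from the 500-patient row alone regenerates every difference to a cent."""
        k = calibrate_variable_saving(14.01, AMORT, 500)
        assert per_patient_difference(k, AMORT, n) == pytest.approx(reported, abs=0.01)

    def test_difference_without_amortization_is_constant(self):
        assert per_patient_difference(12.5, 0.0, 25) == per_patient_difference(
            12.5, 0.0, 2500
        )

    @given(
        k=st.floats(0.01, 1000),
        amort=st.floats(0, 50_000),
        n=st.integers(1, 10_000),
    )
    @settings(deadline=None, max_examples=100)
    def test_strictly_increasing_in_cohort_and_bounded_by_k(self, k, amort, n):
        d_n = per_patient_difference(k, amort, n)
        d_next = per_patient_difference(k, amort, n + 1)
        assert d_n <= d_next <= k
        # strictness needs A/N - A/(N+1) to be representable, so skip
        # vanishingly small amortizations
        if amort > 1e-3:
            assert d_n < d_next


class TestBreakEven:
    def test_reported_break_even_three_samples(self):
        k = calibrate_variable_saving(14.01, AMORT, 500)
        assert break_even_cohort(k, AMORT, step=25) == 275

    def test_reported_break_even_five_samples(self):
        k5 = calibrate_variable_saving(23.16, AMORT, 500)
        assert break_even_cohort(k5, AMORT, step=25) == 200

    def test_zero_amortization_breaks_even_immediately(self):
        assert break_even_cohort(5.0, 0.0, step=25) == 25

    def test_nonpositive_saving_signalled(self):
        with pytest.raises(NoBreakEvenError):
            break_even_cohort(0.0, AMORT, step=25)
        with pytest.raises(NoBreakEvenError):
            break_even_cohort(-3.0, AMORT, step=25)

    def test_exact_grid_boundary_requires_strict_saving(self):
        # K - A/N == 0 exactly at N = 100: not yet a saving, so 125 breaks even
        assert break_even_cohort(1.0, 100.0, step=25) == 125


class TestBatchEffect:
    def test_reported_unit_cost_gap(self):
        assert batch_effect(14.01, 26.27, 17.12) == pytest.approx(23.16)
        assert batch_effect(-277.37, 26.27, 17.12) == pytest.approx(-268.22)

    def test_equal_unit_costs_leave_difference_unchanged(self):
        assert batch_effect(14.01, 20.0, 20.0) == 14.01


class TestCohortCostTable:
    def test_grid_rows_and_monotone_difference(self):
        costs = CostInputs(first_year_oto_usd=180.0)
        table = cohort_cost_table(
            probs_at_medians(), costs, 3, range(25, 501, 25)
        )
        assert len(table) == 20
        diffs = table["difference"].to_numpy()
        assert np.all(np.diff(diffs) > 0)
        assert table["conventional_cost"].nunique() == 1

    def test_break_even_flag_marks_first_sign_change(self):
        costs = CostInputs(first_year_oto_usd=200.0)
        table = cohort_cost_table(probs_at_medians(), costs, 3, range(25, 2001, 25))
        flags = table["break_even"]
        if flags.any():
            i = int(np.argmax(flags.to_numpy()))
            assert table["difference"].iloc[i] > 0
            assert (table["difference"].iloc[:i] <= 0).all()

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            cohort_cost_table(probs_at_medians(), CostInputs(first_year_oto_usd=1.0), 3, [])


class TestCostInputsValidation:
    def test_amortization_consistency_enforced(self):
        with pytest.raises(ValueError, match="amortization"):
            CostInputs(equipment_usd=1000.0, amortization_rate=0.2,
                       annual_amortization_usd=500.0)

    def test_negative_cost_rejected(self):
        with pytest.raises(ValueError):
            CostInputs(cddp_course_usd=-1.0)
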