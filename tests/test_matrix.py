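"""Deterministic matrix engine: fecundity arithmetic, eigen-analysis with
brute-force perturbation oracles, stable-stage allocation, break-even."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

import deerpop as dp
from deerpop.matrix import STRUCTURAL_ENTRIES

survival_st = st.floats(min_value=0.05, max_value=1.0)
fecundity_st = st.floats(min_value=0.01, max_value=3.0)
matrix_st = st.builds(
    dp.assemble, S_f=survival_st, S_y=survival_st, S_a=survival_st,
    F_y=fecundity_st, F_a=fecundity_st,
)


def characteristic_lambda(S_f, S_y, S_a, F_y, F_a):
    """Independent oracle: dominant root of the characteristic cubic
    λ³ = S_a λ² + S_f F_y λ + S_f (F_a S_y − F_y S_a), by bisection."""
    poly = lambda l: l**3 - S_a * l**2 - S_f * F_y * l - S_f * (F_a * S_y - F_y * S_a)
    return brentq(poly, 1e-9, 5.0, xtol=1e-12)


def finite_difference_sensitivities(A, h=1e-6):
    out = {}
    for name, (i, j) in STRUCTURAL_ENTRIES.items():
        Ap, Am = A.copy(), A.copy()
        Ap[i, j] += h
        Am[i, j] -= h
        out[name] = (dp.dominant_eigen(Ap).lam - dp.dominant_eigen(Am).lam) / (2 * h)
    return out


class TestFecundity:
    @pytest.mark.parametrize(
        "birth_rate, survival, expected",
        [(1.43, 0.835, 0.597), (1.09, 0.952, 0.519), (1.43, 0.857, 0.613), (0.0, 0.9, 0.0)],
    )
    def test_half_of_birth_times_survival(self, birth_rate, survival, expected):
        assert round(dp.fecundity(birth_rate, survival), 3) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dp.fecundity(-1.0, 0.5)
        with pytest.raises(ValueError):
            dp.fecundity(1.0, 1.5)


class TestMatrixAssembly:
    def test_observed_rates_matrix(self, base_matrix, base_vitals):
        expected = np.array([[0, 0.519, 0.597], [0.157, 0, 0], [0, 0.952, 0.835]])
        np.testing.assert_allclose(base_matrix, expected)
        # the same matrix from vital rates, fecundities derived (3 dp match)
        built = dp.build_matrix(base_vitals)
        np.testing.assert_allclose(np.round(built, 3), expected)

    def test_nonhunting_adult_fecundity(self):
        vitals = dp.StageVitalRates(
            S_f=0.157, S_f_bounds=(0.091, 0.273),
            S_y=0.952, S_y_bounds=(0.866, 1.000),
            S_a=0.857, S_a_bounds=(0.772, 0.950),
        )
        assert round(dp.build_matrix(vitals)[0, 2], 3) == 0.613

    def test_pattern_violations_rejected(self):
        with pytest.raises(ValueError):
            dp.assemble(-0.1, 0.9, 0.8, 0.5, 0.6)
        bad = np.ones((3, 3))
        with pytest.raises(ValueError):
            dp.dominant_eigen(bad * np.array([[1, 1, 1], [1, 1, 0], [0, 1, 1]]))


class TestProjectionStep:
    def test_reads_first_column(self, base_matrix):
        np.testing.assert_allclose(
            dp.project_one_step(base_matrix, [1, 0, 0]), [0, 0.157, 0]
        )

    def test_zero_vector_fixed_point(self, base_matrix):
        np.testing.assert_allclose(dp.project_one_step(base_matrix, [0, 0, 0]), 0)

    def test_stable_stage_vector_is_eigenvector(self, base_matrix):
        eig = dp.dominant_eigen(base_matrix)
        lam_oracle = characteristic_lambda(0.157, 0.952, 0.835, 0.519, 0.597)
        np.testing.assert_allclose(
            dp.project_one_step(base_matrix, eig.w), lam_oracle * eig.w, atol=1e-10
        )


class TestEigenAnalysis:
    def test_dominant_lambda_matches_characteristic_root(self, base_matrix):
        lam_oracle = characteristic_lambda(0.157, 0.952, 0.835, 0.519, 0.597)
        eig = dp.dominant_eigen(base_matrix)
        assert eig.lam == pytest.approx(lam_oracle, abs=1e-10)
        assert eig.lam == pytest.approx(0.9450, abs=5e-5)

    def test_eigen_pair_residuals(self, base_matrix):
        eig = dp.dominant_eigen(base_matrix)
        np.testing.assert_allclose(base_matrix @ eig.w, eig.lam * eig.w, atol=1e-9)
        np.testing.assert_allclose(eig.v @ base_matrix, eig.lam * eig.v, atol=1e-9)
        assert eig.w.sum() == pytest.approx(1.0)
        assert eig.v[0] == pytest.approx(1.0)

    def test_midpoint_matrix_metrics_match_finite_differences(self):
        # survivals at CI midpoints, fecundities at observed values
        A = dp.assemble(0.182, 0.933, 0.8395, 0.519, 0.597)
        eig = dp.dominant_eigen(A)
        fd = finite_difference_sensitivities(A)
        assert eig.by_parameter("sensitivity")["S_a"] == pytest.approx(fd["S_a"], abs=1e-5)
        assert eig.by_parameter("sensitivity")["S_a"] == pytest.approx(0.7795, abs=5e-4)
        assert eig.by_parameter("elasticity")["S_a"] == pytest.approx(0.6805, abs=5e-4)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(A=matrix_st)
    def test_sensitivities_agree_with_perturbation(self, A):
        eig = dp.dominant_eigen(A)
        fd = finite_difference_sensitivities(A)
        for name in STRUCTURAL_ENTRIES:
            assert eig.by_parameter("sensitivity")[name] == pytest.approx(
                fd[name], abs=1e-5
            )

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(A=matrix_st)
    def test_elasticity_conservation_identities(self, A):
        e = dp.dominant_eigen(A).elasticity
        assert e.sum() == pytest.approx(1.0, abs=1e-9)
        # loop conservation: row sums equal column sums stage by stage
        np.testing.assert_allclose(e.sum(axis=1), e.sum(axis=0), atol=1e-9)
        # equivalently: fawn-survival inflow equals total fecundity outflow
        by = dp.dominant_eigen(A).by_parameter("elasticity")
        assert by["S_f"] == pytest.approx(by["F_y"] + by["F_a"], abs=1e-9)

    @settings(max_examples=100, derandomize=True, deadline=None)
    @given(
        A=matrix_st,
        entry=st.sampled_from(sorted(STRUCTURAL_ENTRIES)),
        bump=st.floats(min_value=1e-4, max_value=0.5),
    )
    def test_lambda_monotone_in_entries(self, A, entry, bump):
        i, j = STRUCTURAL_ENTRIES[entry]
        Ap = A.copy()
        Ap[i, j] += bump
        assert dp.dominant_eigen(Ap).lam >= dp.dominant_eigen(A).lam - 1e-12

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(dp.DegenerateMatrixError):
            dp.dominant_eigen(np.zeros((3, 3)))


class TestStableStageAllocation:
    def test_observed_rates_give_printed_allocation(self, base_matrix):
        np.testing.assert_array_equal(
            dp.stable_stage_abundances(base_matrix, 500), [192, 32, 276]
        )

    def test_zero_total(self, base_matrix):
        np.testing.assert_array_equal(dp.stable_stage_abundances(base_matrix, 0), 0)

    def test_allocation_scales_and_sums(self, base_matrix):
        n1000 = dp.stable_stage_abundances(base_matrix, 1000)
        assert n1000.sum() == 1000
        w = dp.dominant_eigen(base_matrix).w
        np.testing.assert_allclose(n1000, w * 1000, atol=1.0)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(A=matrix_st, total=st.integers(min_value=1, max_value=10_000))
    def test_sum_is_exact_for_any_total(self, A, total):
        assert dp.stable_stage_abundances(A, total).sum() == total


class TestDerivedQuantities:
    def test_breakeven_fawn_survival(self, base_vitals):
        # closed form (1 − S_a) / (F_y + F_a S_y − F_y S_a) evaluated
        # independently of the bisection route
        F_y, F_a = base_vitals.F_y, base_vitals.F_a
        closed = (1 - 0.835) / (F_y + F_a * 0.952 - F_y * 0.835)
        thr = dp.fawn_survival_threshold(base_vitals)
        assert thr == pytest.approx(closed, abs=1e-5)
        assert thr == pytest.approx(0.2523, abs=5e-4)
        # and the matrix at the threshold is stationary
        A = dp.assemble(thr, 0.952, 0.835, F_y, F_a)
        assert dp.dominant_eigen(A).lam == pytest.approx(1.0, abs=1e-5)

    def test_breakeven_zero_when_adults_persist(self, base_vitals):
        vitals = dp.StageVitalRates(
            S_f=0.157, S_f_bounds=(0.091, 0.273),
            S_y=0.952, S_y_bounds=(0.866, 1.000),
            S_a=1.0, S_a_bounds=(1.0, 1.0),
        )
        assert dp.fawn_survival_threshold(vitals) == 0.0

    def test_breakeven_unattainable_without_reproduction(self, base_vitals):
        vitals = dp.StageVitalRates(
            S_f=0.157, S_f_bounds=(0.091, 0.273),
            S_y=0.952, S_y_bounds=(0.866, 1.000),
            S_a=0.835, S_a_bounds=(0.748, 0.931),
            F_y_override=0.0, F_a_override=0.0,
        )
        assert np.isnan(dp.fawn_survival_threshold(vitals))

    @pytest.mark.parametrize(
        "birth_rate, fawn_survival, expected",
        [(1.43, 0.157, 0.22), (1.2, 0.0, 0.0), (1.43, 1.0, 1.43)],
    )
    def test_recruitment_rate(self, birth_rate, fawn_survival, expected):
        assert round(dp.recruitment_rate(birth_rate, fawn_survival), 2) == expected
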