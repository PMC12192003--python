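import math

import numpy as np
import pytest
from scipy import integrate

from ipdrep import (
    IncomeCurve,
    ModelParams,
    PayoffMatrix,
    closed_form_income_case1,
    closed_form_income_case2,
    defector_income,
    expected_game_payoff,
    expected_income_first,
    expected_income_second,
    find_extrema,
    income_curve,
    make_distribution,
    max_reputation_density,
    society_summary,
    total_income,
)

UNIFORM = make_distribution("uniform")
LIN_INC = make_distribution("linear_increasing")
LIN_DEC = make_distribution("linear_decreasing")
EXP5 = make_distribution("exp_decreasing", a=5.0)


def brute_force_income(q, params):
    """Independent oracle: nested adaptive quadrature of the defining integrals."""
    dist, n, pm = params.dist, params.n, params.payoffs
    i1, _ = integrate.quad(
        lambda x: float(max_reputation_density(dist, n, x))
        * float(expected_game_payoff(q, x, pm)),
        0, 1, limit=200,
    )
    i2, _ = integrate.quad(
        lambda x: float(dist.pdf(x)) * float(expected_game_payoff(q, x, pm)),
        0, 1, limit=200,
    )
    return i1 + n * float(dist.cdf(q)) ** (n - 1) * i2


class TestOrderStatisticDensity:
    def test_uniform_n3_is_3x_squared(self):
        xs = np.linspace(0, 1, 11)
        np.testing.assert_allclose(
            max_reputation_density(UNIFORM, 3, xs), 3 * xs**2, atol=1e-12
        )

    def test_n1_reduces_to_the_density_itself(self, builtin_dist):
        xs = np.linspace(0, 1, 101)
        np.testing.assert_allclose(
            max_reputation_density(builtin_dist, 1, xs), builtin_dist.pdf(xs), atol=1e-12
        )

    @pytest.mark.parametrize("n", range(1, 11))
    def test_normalisation_for_all_cases(self, builtin_dist, n):
        total, _ = integrate.quad(
            lambda x: float(max_reputation_density(builtin_dist, n, x)), 0, 1, limit=200
        )
        assert total == pytest.approx(1.0, abs=1e-8)

    def test_subunit_group_rejected(self):
        with pytest.raises(ValueError):
            max_reputation_density(UNIFORM, 0, 0.5)


class TestIncomeComponents:
    @pytest.mark.parametrize("n", [2, 3, 5, 10])
    def test_first_player_income_of_defector_uniform(self, n):
        params = ModelParams(n=n, dist=UNIFORM)
        assert expected_income_first(0.0, params) == pytest.approx((1 + 5 * n) / (1 + n), abs=1e-10)

    @pytest.mark.parametrize("n", [2, 3, 5, 10])
    def test_first_player_income_of_defector_linear_increasing(self, n):
        params = ModelParams(n=n, dist=LIN_INC)
        assert expected_income_first(0.0, params) == pytest.approx(
            (1 + 10 * n) / (1 + 2 * n), abs=1e-10
        )

    def test_first_player_income_exponential_half_of_total(self):
        # at n=1 both roles face the same opponent density, so I1 = I/2
        params = ModelParams(n=1, dist=EXP5)
        assert expected_income_first(0.0, params) == pytest.approx(3.460 / 2, abs=0.001)

    @pytest.mark.parametrize(
        "dist,expected",
        [(UNIFORM, 3.0), (LIN_DEC, 7 / 3)],  # both are int p(x)(4x+1) dx
    )
    def test_second_player_income_of_defector(self, dist, expected):
        params = ModelParams(n=4, dist=dist)
        assert expected_income_second(0.0, params) == pytest.approx(expected, abs=1e-10)

    def test_flat_payoffs_give_constant_component(self, builtin_dist):
        flat = PayoffMatrix(T=2, R=2, P=2, S=2, strict=False)
        params = ModelParams(n=3, dist=builtin_dist, payoffs=flat)
        for q in (0.0, 0.3, 1.0):
            assert expected_income_second(q, params) == pytest.approx(2.0, abs=1e-10)

    @pytest.mark.parametrize("n", [1, 2, 5])
    @pytest.mark.parametrize("q", [0.0, 0.25, 0.7, 1.0])
    def test_components_agree_with_brute_force_quadrature(self, builtin_dist, n, q):
        params = ModelParams(n=n, dist=builtin_dist)
        i1, _ = integrate.quad(
            lambda x: float(max_reputation_density(builtin_dist, n, x))
            * float(expected_game_payoff(q, x)),
            0, 1, limit=200,
        )
        assert expected_income_first(q, params) == pytest.approx(i1, abs=1e-8)


class TestTotalIncome:
    @pytest.mark.parametrize(
        "dist,n,q,expected,tol",
        [
            (UNIFORM, 1, 0.0, 6.0, 1e-10),
            (UNIFORM, 3, 1.0, 6.75, 1e-10),
            (LIN_DEC, 1, 0.0, 14 / 3, 1e-10),
            (EXP5, 1, 0.0, 3.460, 1e-3),
        ],
    )
    def test_reference_values(self, dist, n, q, expected, tol):
        params = ModelParams(n=n, dist=dist)
        assert total_income(q, params) == pytest.approx(expected, abs=tol)

    def test_n1_total_is_twice_first_component(self, builtin_dist):
        params = ModelParams(n=1, dist=builtin_dist)
        qs = np.linspace(0, 1, 21)
        np.testing.assert_allclose(
            total_income(qs, params), 2 * expected_income_first(qs, params), atol=1e-12
        )

    @pytest.mark.parametrize("n", range(1, 11))
    def test_uniform_closed_form_oracle(self, n):
        params = ModelParams(n=n, dist=UNIFORM)
        qs = np.linspace(0, 1, 101)
        np.testing.assert_allclose(
            total_income(qs, params), closed_form_income_case1(qs, n), atol=1e-8
        )

    @pytest.mark.parametrize("n", range(1, 11))
    def test_linear_increasing_closed_form_oracle(self, n):
        params = ModelParams(n=n, dist=LIN_INC)
        qs = np.linspace(0, 1, 101)
        np.testing.assert_allclose(
            total_income(qs, params), closed_form_income_case2(qs, n), atol=1e-8
        )

    def test_closed_forms_hold_for_general_payoffs(self):
        other = PayoffMatrix(T=6, R=4, P=2, S=1)
        qs = np.linspace(0, 1, 51)
        for n in (1, 2, 4):
            np.testing.assert_allclose(
                total_income(qs, ModelParams(n=n, dist=UNIFORM, payoffs=other)),
                closed_form_income_case1(qs, n, other),
                atol=1e-8,
            )
            np.testing.assert_allclose(
                total_income(qs, ModelParams(n=n, dist=LIN_INC, payoffs=other)),
                closed_form_income_case2(qs, n, other),
                atol=1e-8,
            )

    @pytest.mark.parametrize("n", [1, 2, 5])
    def test_degenerate_payoffs_closed_form(self, builtin_dist, n):
        # all payoffs equal c: I(q) = c (1 + n F(q)^(n-1)) exactly
        c = 2.5
        flat = PayoffMatrix(T=c, R=c, P=c, S=c, strict=False)
        params = ModelParams(n=n, dist=builtin_dist, payoffs=flat)
        qs = np.linspace(0, 1, 21)
        F = np.asarray(builtin_dist.cdf(qs), dtype=float)
        np.testing.assert_allclose(
            total_income(qs, params), c * (1 + n * F ** (n - 1)), atol=1e-10
        )

    @pytest.mark.parametrize("q", [0.0, 0.4, 1.0])
    def test_against_nested_quadrature_oracle(self, builtin_dist, q):
        params = ModelParams(n=3, dist=builtin_dist)
        assert total_income(q, params) == pytest.approx(
            brute_force_income(q, params), abs=1e-8
        )

    def test_income_curve_invariants(self):
        curve = income_curve(ModelParams(n=2, dist=UNIFORM), grid_size=101)
        assert curve.grid[0] == 0.0 and curve.grid[-1] == 1.0
        assert np.all(np.diff(curve.grid) > 0)
        with pytest.raises(ValueError, match="strictly increasing"):
            IncomeCurve(params=curve.params, grid=np.array([0.5, 0.2]), values=np.array([1.0, 1.0]))


class TestDefectorIncome:
    @pytest.mark.parametrize("n,expected", [(2, 11 / 3), (10, 51 / 11)])
    def test_uniform_values(self, n, expected):
        assert defector_income(ModelParams(n=n, dist=UNIFORM)) == pytest.approx(expected, abs=1e-10)

    def test_linear_increasing_value(self):
        assert defector_income(ModelParams(n=2, dist=LIN_INC)) == pytest.approx(21 / 5, abs=1e-10)

    def test_equals_total_income_at_zero(self, builtin_dist):
        params = ModelParams(n=3, dist=builtin_dist)
        assert defector_income(params) == pytest.approx(float(total_income(0.0, params)), abs=1e-12)

    @pytest.mark.parametrize("dist", [UNIFORM, LIN_INC])
    def test_grows_with_subgroup_size(self, dist):
        incomes = [defector_income(ModelParams(n=n, dist=dist)) for n in range(2, 12)]
        assert np.all(np.diff(incomes) > 0)

    def test_single_candidate_rejected(self):
        with pytest.raises(ValueError, match="n >= 2"):
            defector_income(ModelParams(n=1, dist=UNIFORM))


class TestExtrema:
    def test_uniform_n2_interior_maximum(self):
        reports = find_extrema(ModelParams(n=2, dist=UNIFORM))
        interior = [r for r in reports if r.placement == "interior"]
        assert len(interior) == 1
        assert interior[0].kind == "maximum"
        assert interior[0].location == pytest.approx(13 / 18, abs=1e-6)

    def test_uniform_n3_interior_minimum(self):
        reports = find_extrema(ModelParams(n=3, dist=UNIFORM))
        minima = [r for r in reports if r.placement == "interior" and r.kind == "minimum"]
        assert len(minima) == 1
        assert minima[0].location == pytest.approx((12 - math.sqrt(102)) / 18, abs=1e-6)

    def test_exponential_n2_maximum(self):
        reports = find_extrema(ModelParams(n=2, dist=EXP5))
        maxima = [r for r in reports if r.placement == "interior" and r.kind == "maximum"]
        assert len(maxima) == 1
        assert maxima[0].location == pytest.approx(0.297, abs=0.002)
        assert maxima[0].value == pytest.approx(3.897, abs=0.005)

    def test_monotone_curve_has_boundary_extrema_only(self):
        # n=1 income is strictly decreasing: best at q=0, worst at q=1
        reports = find_extrema(ModelParams(n=1, dist=UNIFORM))
        assert all(r.placement == "boundary" for r in reports)
        by_loc = {r.location: r for r in reports}
        assert by_loc[0.0].kind == "maximum" and by_loc[0.0].value == pytest.approx(6.0)
        assert by_loc[1.0].kind == "minimum" and by_loc[1.0].value == pytest.approx(3.0)

    def test_coarse_grid_rejected(self):
        with pytest.raises(ValueError, match="grid_size"):
            find_extrema(ModelParams(n=2, dist=UNIFORM), grid_size=50)


class TestSocietySummary:
    def test_uniform_n1_exact(self):
        s = society_summary(ModelParams(n=1, dist=UNIFORM))
        assert s.expected_income == pytest.approx(4.5, abs=1e-9)
        assert s.dispersion == pytest.approx(math.sqrt(3) / 2, abs=1e-9)

    def test_linear_increasing_n2(self):
        s = society_summary(ModelParams(n=2, dist=LIN_INC))
        assert s.expected_income == pytest.approx(16 / 3, abs=1e-9)

    def test_dispersion_nonnegative(self, builtin_dist):
        s = society_summary(ModelParams(n=5, dist=builtin_dist))
        assert s.dispersion >= 0
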