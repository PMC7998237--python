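"""Component functions, log fitness, and closed-form selection gradients."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from anisogame import (
    INVIABLE,
    DomainError,
    GameteSizePair,
    ModelParams,
    UnsupportedVariantError,
    fitness,
    gamete_number,
    gamete_survival,
    gradient_jacobian,
    log_fitness,
    reparametrise_tradeoff,
    selection_gradient,
    zygote_survival,
)
from conftest import assert_close, fd_gradient, fd_jacobian


class TestTradeoff:
    @pytest.mark.parametrize(
        "x,M,k,expected",
        [(1.0, 100.0, 1.0, 100.0), (4.0, 100.0, 2.0, 5.0), (7.0, 7.0, 3.0, 1.0)],
    )
    def test_gamete_number_examples(self, x, M, k, expected):
        params = ModelParams(M=M, k=k, delta=1e-4)
        assert_close(gamete_number(x, params), expected)

    def test_gamete_number_strictly_decreasing(self):
        params = ModelParams(M=50.0, k=1.7)
        sizes = [0.01, 0.1, 1.0, 10.0, 50.0]
        numbers = [gamete_number(x, params) for x in sizes]
        assert all(a > b for a, b in zip(numbers, numbers[1:]))

    @pytest.mark.parametrize("bad", [0.0, -1.0, 101.0])
    def test_gamete_number_domain_errors_name_value(self, bad):
        with pytest.raises(DomainError, match=str(bad)):
            gamete_number(bad, ModelParams(M=100.0))

    @pytest.mark.parametrize(
        "k,d,M,q,n,x",
        [
            (1.0, 3, 8.0, 1.0, 8.0, 1.0),  # lossless halving
            (2.0, 1, 8.0, 0.5, 2.0, 2.0),  # half the resource lost per division
            (2.0, 2, 8.0, 0.5, 4.0, 0.5),  # consistency with x = M / n**k
        ],
    )
    def test_reparametrisation_examples(self, k, d, M, q, n, x):
        r = reparametrise_tradeoff(k, d, M)
        assert_close(r.q, q)
        assert_close(r.n, n)
        assert_close(r.gamete_size, x)
        assert_close(r.gamete_size, M / r.n**k)  # division view matches trade-off

    @given(st.floats(min_value=1.0, max_value=20.0))
    def test_reparametrisation_round_trip(self, k):
        r = reparametrise_tradeoff(k, 4, 10.0)
        assert math.isclose(r.k, k, rel_tol=0, abs_tol=1e-14)
        assert (r.q == 1.0) == (k == 1.0)

    def test_reparametrisation_rejects_efficient_k(self):
        with pytest.raises(DomainError):
            reparametrise_tradeoff(0.5, 2, 1.0)


class TestSurvival:
    def test_gamete_survival_exponential(self):
        params = ModelParams(alpha=2.5)
        assert_close(gamete_survival(2.5, params), math.exp(-1.0))
        assert gamete_survival(17.0, ModelParams(alpha=0.0)) == 1.0
        # strictly increasing in size
        assert gamete_survival(1.0, params) < gamete_survival(2.0, params)

    def test_gamete_survival_threshold_step(self):
        params = ModelParams(delta=0.2, gamete_survival_form="threshold")
        assert gamete_survival(0.2 * 0.99, params) == 0.0
        assert gamete_survival(0.2, params) == 1.0

    def test_zygote_survival_exponential(self):
        params = ModelParams(beta=3.0)
        assert_close(zygote_survival(1.0, 2.0, params), math.exp(-1.0))
        assert zygote_survival(0.5, 0.5, ModelParams(beta=0.0)) == 1.0
        assert zygote_survival(1.0, 1.0, params) < zygote_survival(2.0, 1.0, params)

    def test_zygote_survival_power_uncapped(self):
        params = ModelParams(c=1.0, h=1.0, zygote_survival_form="power")
        assert_close(zygote_survival(1.2, 0.8, params), 2.0)  # a factor, not a probability

    @pytest.mark.parametrize("fn", [gamete_survival])
    def test_survival_domain_error(self, fn):
        with pytest.raises(DomainError):
            fn(-1.0, ModelParams())


class TestLogFitness:
    def test_direct_composition_value(self):
        # independent evaluation: ln(M/x) - alpha/x - beta/(x+y)
        params = ModelParams(M=1.0, alpha=1.0, beta=2.0, k=1.0, delta=1e-4)
        expected = math.log(1.0 / 1.5) - 1.0 / 1.5 - 2.0 / 3.0
        assert_close(log_fitness(1.5, 1.5, params), expected, tol=1e-12)
        assert_close(expected, -1.738799, tol=1e-6)

    @given(
        st.floats(min_value=0.1, max_value=5.0),
        st.floats(min_value=0.1, max_value=5.0),
        st.floats(min_value=1.0, max_value=4.0),
    )
    def test_budget_doubling_adds_ln2_over_k(self, a, b, k):
        params = ModelParams(M=10.0, alpha=1.0, beta=2.0, k=k)
        doubled = params.replace(M=20.0)
        assert_close(
            log_fitness(a, b, doubled) - log_fitness(a, b, params),
            math.log(2.0) / k,
            tol=1e-12,
        )

    @given(
        st.floats(min_value=0.05, max_value=8.0),
        st.floats(min_value=0.05, max_value=8.0),
    )
    def test_role_symmetry(self, a, b):
        # one function serves both mating types with the arguments swapped,
        # so swapping the strategy point swaps the gradient components
        params = ModelParams(M=10.0, alpha=0.7, beta=3.0)
        g = selection_gradient(GameteSizePair(a, b), params)
        gs = selection_gradient(GameteSizePair(b, a), params)
        assert g[0] == gs[1] and g[1] == gs[0]

    def test_inviable_sentinel_is_not_an_error(self):
        params = ModelParams(
            delta=0.5, gamete_survival_form="threshold", zygote_survival_form="power"
        )
        assert log_fitness(0.4, 0.6, params) == INVIABLE
        assert fitness(0.4, 0.6, params) == 0.0

    def test_nonpositive_sizes_are_domain_errors(self):
        with pytest.raises(DomainError):
            log_fitness(-1.0, 1.0, ModelParams())


class TestSelectionGradient:
    def test_vanishes_at_isogamous_equilibrium(self):
        params = ModelParams(M=10.0, alpha=1.0, beta=2.0)
        g = selection_gradient(GameteSizePair(1.5, 1.5), params)
        assert max(map(abs, g)) < 1e-12

    def test_vanishes_at_anisogamous_equilibrium(self):
        params = ModelParams(M=10.0, alpha=1.0, beta=8.0)
        g = selection_gradient(GameteSizePair(6.828427124746190, 1.171572875253810), params)
        assert max(map(abs, g)) < 1e-10

    @pytest.mark.parametrize("m", [0.3, 1.0, 2.5])
    @pytest.mark.parametrize("h", [0.8, 1.5, 2.0])
    def test_power_form_diagonal_closed_form(self, m, h):
        # hand differentiation: -1/m + h/(2m) = (h - 2) / (2m) on the diagonal
        params = ModelParams(
            M=10.0, h=h, delta=1e-3,
            gamete_survival_form="threshold", zygote_survival_form="power",
        )
        g = selection_gradient(GameteSizePair(m, m), params)
        assert_close(g[0], (h - 2.0) / (2.0 * m), tol=1e-12)
        assert_close(g[1], (h - 2.0) / (2.0 * m), tol=1e-12)

    @given(
        st.floats(min_value=0.2, max_value=6.0),
        st.floats(min_value=0.2, max_value=6.0),
        st.floats(min_value=0.1, max_value=3.0),
        st.floats(min_value=0.1, max_value=12.0),
        st.floats(min_value=1.0, max_value=3.0),
    )
    def test_matches_finite_difference_oracle(self, x, y, alpha, beta, k):
        params = ModelParams(M=50.0, alpha=alpha, beta=beta, k=k)
        point = GameteSizePair(x, y)
        g = selection_gradient(point, params)
        fd = fd_gradient(point, params)
        assert math.isclose(g[0], fd[0], rel_tol=1e-5, abs_tol=1e-6)
        assert math.isclose(g[1], fd[1], rel_tol=1e-5, abs_tol=1e-6)

    @given(
        st.floats(min_value=0.2, max_value=6.0),
        st.floats(min_value=0.2, max_value=6.0),
        st.floats(min_value=1.0, max_value=4.0),
    )
    def test_k_scaling_bracket_identity(self, x, y, k):
        """Gradients of the (alpha*k, beta*k, k=1) model are k times the k-model's."""
        alpha, beta = 0.8, 5.0
        point = GameteSizePair(x, y)
        g_k = selection_gradient(point, ModelParams(M=50.0, alpha=alpha, beta=beta, k=k))
        g_1 = selection_gradient(
            point, ModelParams(M=50.0, alpha=alpha * k, beta=beta * k, k=1.0)
        )
        assert_close(g_1[0], k * g_k[0], tol=1e-12)
        assert_close(g_1[1], k * g_k[1], tol=1e-12)

    def test_absolute_and_log_fitness_share_equilibria(self):
        """d w/dx = w * d ln w/dx, so both residuals vanish where fitness > 0."""
        params = ModelParams(M=100.0, alpha=1.0, beta=8.0)
        for pt in (
            GameteSizePair(3.0, 3.0),  # isogamous root of this parameter set
            GameteSizePair(6.828427124746190, 1.171572875253810),
        ):
            glog = selection_gradient(pt, params)
            wx = fitness(pt.x, pt.y, params)
            wy = fitness(pt.y, pt.x, params)
            gabs = (wx * glog[0], wy * glog[1])
            assert max(map(abs, glog)) < 1e-8
            assert max(map(abs, gabs)) < 1e-8

    def test_unsupported_variant_error(self):
        params = ModelParams()
        object.__setattr__(params, "zygote_survival_form", "sigmoid")
        with pytest.raises(UnsupportedVariantError):
            selection_gradient(GameteSizePair(1.0, 1.0), params)


class TestGradientJacobian:
    @pytest.mark.parametrize(
        "x,y,alpha,beta,k",
        [(1.5, 1.5, 1.0, 2.0, 1.0), (6.0, 1.2, 1.0, 8.0, 1.0), (2.0, 5.0, 0.5, 3.0, 2.0)],
    )
    def test_matches_finite_difference_oracle(self, x, y, alpha, beta, k):
        params = ModelParams(M=50.0, alpha=alpha, beta=beta, k=k)
        point = GameteSizePair(x, y)
        jac = gradient_jacobian(point, params)
        fd = fd_jacobian(point, params)
        for i in range(2):
            for j in range(2):
                assert math.isclose(jac[i][j], fd[i][j], rel_tol=1e-4, abs_tol=1e-5)
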