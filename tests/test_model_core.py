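import math

import numpy as np
import pytest
from scipy import integrate, stats

import betabym as bb
from betabym.data_io import DomainError
from betabym.model_core import ParameterState

from _oracles import reference_log_posterior


class TestLink:
    def test_inv_logit_symmetry(self):
        assert bb.inv_logit(0.0) == 0.5

    def test_logit_value(self):
        assert bb.logit(0.682) == pytest.approx(math.log(0.682 / 0.318), abs=1e-12)
        assert round(bb.logit(0.682), 4) == 0.7630

    def test_round_trip(self):
        p = np.linspace(0.001, 0.999, 101)
        assert np.allclose(bb.inv_logit(bb.logit(p)), p, atol=1e-12)

    def test_no_underflow_in_tails(self):
        assert bb.inv_logit(-40.0) > 0.0
        assert bb.inv_logit(-700.0) >= 0.0 and np.isfinite(bb.inv_logit(700.0))

    @pytest.mark.parametrize("bad", [0.0, 1.0, -0.1, 1.1])
    def test_logit_domain(self, bad):
        with pytest.raises(DomainError):
            bb.logit(bad)


class TestBetaLogDensity:
    def test_uniform_case(self):
        # mu=0.5, phi=2 gives Beta(1,1): log density 0 everywhere
        assert bb.beta_log_density(0.3, 0.5, 2.0) == pytest.approx(0.0, abs=1e-12)

    def test_matches_reference_beta_pdf(self):
        # mu=0.7, phi=50 -> Beta(35, 15)
        expected = stats.beta.logpdf(0.7, 35, 15)
        assert bb.beta_log_density(0.7, 0.7, 50.0) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("mu,phi", [(0.3, 5.0), (0.68, 200.0), (0.9, 20.0)])
    def test_normalization(self, mu, phi):
        val, _ = integrate.quad(lambda y: math.exp(bb.beta_log_density(y, mu, phi)), 0, 1)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            bb.beta_log_density(1.0, 0.5, 2.0)
        with pytest.raises(DomainError):
            bb.beta_log_density(0.5, 0.5, -1.0)

    def test_mean_precision_parameterization(self):
        # samples drawn with (mu, phi) must have mean mu and variance
        # mu(1-mu)/(1+phi)
        rng = np.random.default_rng(5)
        n = 100_000
        for mu, phi in [(0.3, 10.0), (0.68, 200.0), (0.85, 50.0)]:
            y = rng.beta(mu * phi, (1 - mu) * phi, size=n)
            var = mu * (1 - mu) / (1 + phi)
            se_mean = math.sqrt(var / n)
            assert abs(y.mean() - mu) < 3 * se_mean
            # SE of the sample variance ~ sqrt(2/n) * var for near-normal; use 4x margin
            assert abs(y.var() - var) < 4 * math.sqrt(2.0 / n) * var


class TestIcarLogDensity:
    def test_zero_field_maximizes_kernel(self, toy_graph):
        w0 = np.zeros(4)
        base = bb.icar_log_density(w0, toy_graph, 1.0)
        w = np.array([0.5, -0.5, 0.5, -0.5])
        assert bb.icar_log_density(w, toy_graph, 1.0) < base

    def test_path_kernel_by_hand(self):
        g = bb.graph_from_edgelist(3, [(0, 1), (1, 2)])
        w = np.array([-1.0, 0.0, 1.0])
        # edges (0,1) and (1,2): (w0-w1)^2 + (w1-w2)^2 = 1 + 1 = 2 -> kernel -1.0
        val = bb.icar_log_density(w, g, 1.0)
        # rank = n - c = 2, so the sigma term vanishes at sigma_w2=1
        assert val == pytest.approx(-1.0, abs=1e-12)

    def test_sigma_scaling_identity(self):
        g = bb.graph_from_edgelist(3, [(0, 1), (1, 2)])
        w = np.array([-1.0, 0.0, 1.0])
        s2 = 0.37
        lhs = bb.icar_log_density(w, g, 2 * s2) - bb.icar_log_density(w, g, s2)
        S = 2.0  # pairwise sum for this w
        rank = 2
        assert lhs == pytest.approx(S / (4 * s2) - rank / 2 * math.log(2), abs=1e-12)

    def test_constraint_violation_raises(self, toy_graph):
        with pytest.raises(DomainError, match="sum-to-zero"):
            bb.icar_log_density(np.array([1.0, 1.0, 1.0, 1.0]), toy_graph, 1.0)


class TestLogPosterior:
    def _state(self, table, graph, rng):
        from betabym.synthetic import sample_icar_field

        w = sample_icar_field(graph, 0.02, rng)
        return ParameterState(
            beta0=float(rng.normal(0.7, 0.1)),
            beta=rng.normal(0.02, 0.01, table.n_covariates),
            w=w,
            v=rng.normal(0, 0.05, table.n_areas),
            sigma_w2=float(rng.uniform(0.01, 0.1)),
            sigma_v2=float(rng.uniform(0.005, 0.05)),
            phi=float(rng.uniform(50, 300)),
        )

    def test_reduces_to_iid_beta_at_null_state(self, toy_table, toy_graph):
        ybar = toy_table.y.mean()
        state = ParameterState(
            beta0=bb.logit(ybar), beta=np.zeros(1), w=np.zeros(4), v=np.zeros(4),
            sigma_w2=0.02, sigma_v2=0.01, phi=150.0,
        )
        lp = bb.log_posterior(state, toy_table, toy_graph, bb.PriorSpec())
        lik = float(np.sum(bb.beta_log_density(toy_table.y, ybar, 150.0)))
        # subtracting the likelihood leaves only prior terms, which must not
        # depend on the data
        state2 = ParameterState(
            beta0=bb.logit(ybar), beta=np.zeros(1), w=np.zeros(4), v=np.zeros(4),
            sigma_w2=0.02, sigma_v2=0.01, phi=150.0,
        )
        lp_nolik = bb.log_posterior(
            state2, toy_table, toy_graph, bb.PriorSpec(), include_likelihood=False
        )
        assert lp - lp_nolik == pytest.approx(lik, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_differences_match_independent_expansion(self, toy_table, toy_graph, seed):
        rng = np.random.default_rng(seed)
        priors = bb.PriorSpec()
        s1 = self._state(toy_table, toy_graph, rng)
        s2 = self._state(toy_table, toy_graph, rng)
        d_pkg = bb.log_posterior(s1, toy_table, toy_graph, priors) - bb.log_posterior(
            s2, toy_table, toy_graph, priors
        )
        d_ref = reference_log_posterior(s1, toy_table, toy_graph, priors) - reference_log_posterior(
            s2, toy_table, toy_graph, priors
        )
        assert d_pkg == pytest.approx(d_ref, abs=1e-10)

    def test_concentration_in_phi_at_perfect_fit(self, toy_graph):
        # with y_i = mu_i exactly, larger phi concentrates the likelihood
        y = np.array([0.6, 0.68, 0.72])
        g = bb.graph_from_edgelist(3, [(0, 1), (1, 2)])
        table = bb.CountyTable(["a", "b", "c"], ["a", "b", "c"], y, np.zeros((3, 0)))
        eta = bb.logit(y)

        def lik(phi):
            return float(np.sum(bb.beta_log_density(y, bb.inv_logit(eta), phi)))

        assert lik(50) < lik(100) < lik(500)

    def test_misaligned_dimensions_raise(self, toy_table):
        g5 = bb.graph_from_edgelist(5, [(0, 1), (1, 2), (2, 3), (3, 4)])
        state = ParameterState(0.7, np.zeros(1), np.zeros(5), np.zeros(5), 0.02, 0.01, 150.0)
        with pytest.raises(bb.data_io.IntegrityError):
            bb.log_posterior(state, toy_table, g5, bb.PriorSpec())

    def test_slice_normalizer_consistency(self, toy_table, toy_graph):
        # integrating exp(log_posterior) along a 1-D slice in beta0 must give
        # the same normalizer on a direct grid and on a translated grid
        priors = bb.PriorSpec()

        def f(b0):
            state = ParameterState(b0, np.array([0.02]), np.zeros(4), np.zeros(4),
                                   0.02, 0.01, 150.0)
            return math.exp(bb.log_posterior(state, toy_table, toy_graph, priors))

        xs = np.linspace(-1.0, 2.5, 3501)
        direct = integrate.trapezoid([f(x) for x in xs], xs)
        shifted = integrate.trapezoid([f(x) for x in xs + 0.37 * (xs[1] - xs[0])],
                                      xs + 0.37 * (xs[1] - xs[0]))
        assert shifted == pytest.approx(direct, rel=1e-6)
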