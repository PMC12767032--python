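import dataclasses

import numpy as np
import pytest

import betabym as bb
from betabym.synthetic import CovariateSpec, sample_icar_field


class TestLatticeGraph:
    def test_2x2_edge_counts(self):
        assert bb.lattice_graph(2, 2, "rook").n_edges == 4
        assert bb.lattice_graph(2, 2, "queen").n_edges == 6

    @pytest.mark.parametrize("r,c", [(2, 3), (3, 3), (4, 6), (6, 5)])
    def test_rook_edge_count_formula(self, r, c):
        # brute-force count of lattice adjacencies vs r(c-1) + c(r-1)
        g = bb.lattice_graph(r, c, "rook")
        brute = sum(
            1
            for a in range(r * c)
            for b in range(a + 1, r * c)
            if (abs(a // c - b // c) + abs(a % c - b % c)) == 1
        )
        assert g.n_edges == brute == r * (c - 1) + c * (r - 1)

    def test_1x5_is_path(self):
        g = bb.lattice_graph(1, 5, "rook")
        assert list(g.degree) == [1, 2, 2, 2, 1]

    def test_polygon_adjacency_matches_lattice(self):
        polys = bb.lattice_polygons(3, 4)
        g_poly = bb.build_queen_adjacency(polys, rule="rook")
        g_lat = bb.lattice_graph(3, 4, "rook")
        assert g_poly.neighbors == g_lat.neighbors


class TestSampleIcarField:
    def test_component_sums_vanish(self):
        g = bb.graph_from_edgelist(7, [(0, 1), (1, 2), (3, 4), (4, 5)])  # area 6 isolated
        w = sample_icar_field(g, 0.5, seed=3)
        labels = g.component_labels
        for c in np.unique(labels):
            members = np.flatnonzero(labels == c)
            assert abs(w[members].sum()) < 1e-10
        assert w[6] == 0.0

    def test_determinism(self):
        g = bb.lattice_graph(3, 3, "rook")
        assert np.array_equal(sample_icar_field(g, 0.1, 5), sample_icar_field(g, 0.1, 5))

    def test_covariance_matches_pseudo_inverse(self):
        # empirical covariance of many draws vs sigma_w2 * Q^+ entrywise
        g = bb.lattice_graph(3, 3, "rook")
        sigma_w2 = 0.3
        n_draws = 10_000
        rng = np.random.default_rng(17)
        draws = np.stack([sample_icar_field(g, sigma_w2, rng) for _ in range(n_draws)])
        emp = np.cov(draws.T)
        target = sigma_w2 * np.linalg.pinv(bb.icar_precision(g).Q)
        # SE of a covariance entry ~ sqrt((Cii Cjj + Cij^2)/n)
        d = np.diag(target)
        se = np.sqrt((np.outer(d, d) + target**2) / n_draws)
        assert np.all(np.abs(emp - target) < 3.5 * se)


class TestGenerateDataset:
    def test_degenerate_limit_concentrates(self):
        cfg = bb.GeneratorConfig(
            rows=4, cols=4, beta0=float(bb.logit(0.68)), beta=(0.0,),
            covariates=(CovariateSpec(),), sigma_w2=1e-8, sigma_v2=1e-8,
            phi=1e6, seed=1,
        )
        ds = bb.generate_dataset(cfg)
        assert np.all(np.abs(ds.table.y - 0.68) < 0.01)

    def test_default_fixture_centered_near_068(self):
        means = [
            bb.generate_dataset(bb.GeneratorConfig(seed=s)).table.y.mean()
            for s in range(20190401, 20190409)
        ]
        assert abs(np.mean(means) - 0.68) < 0.05

    def test_conditional_variance_matches_closed_form(self):
        # many outcome replicates at fixed mu: Var(y|mu) = mu(1-mu)/(1+phi)
        cfg = bb.default_fixture_config()
        ds = bb.generate_dataset(cfg)
        mu = bb.inv_logit(
            ds.truth.beta0 + ds.table.X @ ds.truth.beta + ds.truth.w + ds.truth.v
        )
        rng = np.random.default_rng(2)
        reps = rng.beta(mu * cfg.phi, (1 - mu) * cfg.phi, size=(4000, len(mu)))
        target = mu * (1 - mu) / (1 + cfg.phi)
        ratio = reps.var(axis=0) / target
        assert abs(ratio.mean() - 1) < 0.05

    def test_saturation_error(self):
        cfg = bb.GeneratorConfig(beta0=10.0, beta=(0.0,), seed=0)
        with pytest.raises(ValueError, match="saturated"):
            bb.generate_dataset(cfg)

    def test_truth_satisfies_constraint_and_interior_y(self):
        ds = bb.generate_dataset()
        labels = ds.graph.component_labels
        for c in np.unique(labels):
            assert abs(ds.truth.w[labels == c].sum()) < 1e-10
        assert np.all((ds.table.y > 0) & (ds.table.y < 1))

    def test_bundle_round_trips_end_to_end(self, tmp_path):
        ds = bb.generate_dataset(bb.GeneratorConfig(rows=3, cols=3, seed=4))
        ds.write_bundle(tmp_path)
        table = bb.read_county_table(
            tmp_path / "counties.csv", id_col="area_id", outcome_col="y",
            covariate_cols=["sedentary_pct"], name_col="area_name",
            outcome_unit="proportion",
        )
        graph = bb.read_edgelist(tmp_path / "adjacency.tsv", table.area_id)
        polys = bb.read_polygons(tmp_path / "areas.geojson", "area_id")
        assert graph.neighbors == ds.graph.neighbors
        assert len(polys) == 9

    def test_score_identity_for_beta(self):
        # at the true parameters, the finite-difference gradient of the log
        # posterior in beta is centered near zero across replicates
        cfg = bb.GeneratorConfig(rows=4, cols=4, seed=100)
        priors = bb.PriorSpec()
        eps = 1e-4
        scores = []
        for r in range(50):
            ds = bb.generate_dataset(dataclasses.replace(cfg, seed=cfg.seed + r))
            hi = ds.truth.copy()
            hi.beta = hi.beta + eps
            lo = ds.truth.copy()
            lo.beta = lo.beta - eps
            g = (
                bb.log_posterior(hi, ds.table, ds.graph, priors)
                - bb.log_posterior(lo, ds.table, ds.graph, priors)
            ) / (2 * eps)
            scores.append(g)
        scores = np.array(scores)
        se = scores.std(ddof=1) / np.sqrt(len(scores))
        assert abs(scores.mean()) < 3 * se


class TestRecoveryExperiment:
    def test_single_replicate_report_shape(self):
        cfg = bb.GeneratorConfig(rows=4, cols=4, seed=7)
        mcmc = bb.MCMCConfig(n_chains=2, n_iterations=1500, n_burnin=700, thin=2, seed=1)
        rep = bb.recovery_experiment(1, cfg, mcmc)
        assert rep.n_replicates == 1
        assert set(rep.coverage) == {
            "beta0", "beta[sedentary_pct]", "sigma_w2", "sigma_v2", "phi",
        }
        assert all(v in (0.0, 1.0) for v in rep.coverage.values())

    def test_rmse_shrinks_with_lattice_size(self):
        mcmc = bb.MCMCConfig(n_chains=2, n_iterations=3000, n_burnin=1500, thin=3, seed=2)
        small = bb.recovery_experiment(
            4, bb.GeneratorConfig(rows=6, cols=6, sigma_w2=0.01, sigma_v2=0.005, seed=50),
            mcmc,
        )
        large = bb.recovery_experiment(
            4, bb.GeneratorConfig(rows=10, cols=10, sigma_w2=0.01, sigma_v2=0.005, seed=50),
            mcmc,
        )
        assert large.rmse["beta[sedentary_pct]"] < small.rmse["beta[sedentary_pct]"]
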