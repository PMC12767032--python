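"""Adaptive Metropolis-within-Gibbs sampling for the beta-BYM model.

Update scheme per iteration:

* scalar Gaussian random-walk updates for beta0, each beta_j, log sigma_w^2,
  log sigma_v^2 and log phi;
* single-site random-walk updates for the structured effects w_i, vectorized
  over the color classes of a proper graph coloring (sites within a class are
  never adjacent, so their Metropolis decisions are conditionally independent);
* single-site updates for every v_i, vectorized in one block;
* joint rescale moves (w, sigma_w^2) -> (c w, c^2 sigma_w^2) and likewise for
  (v, sigma_v^2), which traverse the small-variance funnel that single-site
  updates cannot cross;
* after every w sweep, w is recentered to the per-component sum-to-zero
  constraint and the removed level is folded into beta0 (exact for a connected
  graph under a flat intercept prior).

Proposal scales adapt by Robbins-Monro during burn-in only (frozen afterward,
keeping the retained chain Markovian), targeting an acceptance rate of 0.44
for every scalar / single-site update.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import arviz as az
import numpy as np
import pandas as pd
from scipy import sparse
from scipy.special import expit, gammaln

from .data_io import CountyTable
from .model_core import PriorSpec, logit
from .spatial_graph import SpatialGraph

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "DiagnosticsReport",
    "ParameterSummary",
    "run_sampler",
    "diagnostics",
    "summarize_posterior",
]


@dataclass
class MCMCConfig:
    """Chain schedule and model-restriction switches.

    The fix_* fields pin a hyperparameter at a constant (no update step);
    include_v / include_likelihood switch off the unstructured effect or the
    data term entirely (used for reduced-model oracles and prior-recovery
    checks).
    """

    n_chains: int = 4
    n_iterations: int = 20_000
    n_burnin: int = 10_000
    thin: int = 5
    seed: int = 0
    adapt_until: int | None = None  # default: n_burnin
    target_accept: float = 0.44
    target_accept_block: float = 0.23  # retained for multi-site block proposals
    fix_phi: float | None = None
    fix_sigma_w2: float | None = None
    fix_sigma_v2: float | None = None
    include_v: bool = True
    include_likelihood: bool = True

    def __post_init__(self) -> None:
        if self.n_chains < 1:
            raise ValueError("need at least one chain")
        if not (0 < self.n_burnin < self.n_iterations):
            raise ValueError("require 0 < n_burnin < n_iterations")
        if self.adapt_until is None:
            self.adapt_until = self.n_burnin
        if self.adapt_until > self.n_burnin:
            raise ValueError("adapt_until must not exceed n_burnin")


@dataclass
class PosteriorSamples:
    """Retained post-burn-in draws, pooled across chains with a chain_id column."""

    beta0: np.ndarray  # (d,)
    beta: np.ndarray  # (d, k)
    w: np.ndarray  # (d, n)
    v: np.ndarray  # (d, n)
    sigma_w2: np.ndarray
    sigma_v2: np.ndarray
    phi: np.ndarray
    mu: np.ndarray  # (d, n)
    chain_id: np.ndarray
    acceptance_rates: dict[str, float]
    config: MCMCConfig
    covariate_names: list[str] = field(default_factory=list)
    area_id: list[str] = field(default_factory=list)

    @property
    def n_draws(self) -> int:
        return len(self.beta0)

    @property
    def n_chains(self) -> int:
        return len(np.unique(self.chain_id))

    def scalar_names(self) -> list[str]:
        k = self.beta.shape[1]
        covs = self.covariate_names or [f"x{j}" for j in range(k)]
        return ["beta0"] + [f"beta[{c}]" for c in covs] + ["sigma_w2", "sigma_v2", "phi"]

    def scalar_draws(self) -> dict[str, np.ndarray]:
        names = self.scalar_names()
        k = self.beta.shape[1]
        out = {"beta0": self.beta0}
        for j in range(k):
            out[names[1 + j]] = self.beta[:, j]
        out["sigma_w2"] = self.sigma_w2
        out["sigma_v2"] = self.sigma_v2
        out["phi"] = self.phi
        return out

    def by_chain(self, draws: np.ndarray) -> np.ndarray:
        """Reshape pooled draws to (n_chains, draws_per_chain)."""
        chains = np.unique(self.chain_id)
        return np.stack([draws[self.chain_id == c] for c in chains])

    def to_frame(self) -> pd.DataFrame:
        """One row per retained draw, one column per scalar (CSV-exportable)."""
        data = {"chain": self.chain_id, **self.scalar_draws()}
        for i in range(self.w.shape[1]):
            aid = self.area_id[i] if self.area_id else str(i)
            data[f"w[{aid}]"] = self.w[:, i]
            data[f"v[{aid}]"] = self.v[:, i]
            data[f"mu[{aid}]"] = self.mu[:, i]
        return pd.DataFrame(data)


@dataclass
class DiagnosticsReport:
    rhat: dict[str, float]
    ess: dict[str, float]
    acceptance_rates: dict[str, float]
    converged: bool


@dataclass
class ParameterSummary:
    """Posterior mean / sd / central 95% interval per scalar parameter."""

    table: pd.DataFrame  # index: parameter; columns: mean, sd, q2.5, q97.5

    def row(self, name: str) -> pd.Series:
        return self.table.loc[name]


# ---------------------------------------------------------------- sampler ---


def _greedy_coloring(graph: SpatialGraph) -> list[np.ndarray]:
    """Proper coloring of non-isolated sites; returns index arrays per color."""
    import networkx as nx

    g = nx.Graph()
    active = [i for i in range(graph.n) if graph.neighbors[i]]
    g.add_nodes_from(active)
    g.add_edges_from((i, j) for i, j in graph.edges)
    coloring = nx.greedy_color(g, strategy="largest_first")
    n_colors = max(coloring.values(), default=-1) + 1
    return [
        np.array(sorted(i for i, c in coloring.items() if c == col), dtype=int)
        for col in range(n_colors)
    ]


class _Model:
    """Precomputed quantities shared by all chains."""

    def __init__(self, table: CountyTable, graph: SpatialGraph, priors: PriorSpec, config: MCMCConfig, likelihood_mask=None):
        self.y = table.y
        self.X = table.X
        # the chain runs on mean-centered covariates: beta0 and beta_j are
        # nearly uncorrelated there, which the single-site random walk needs;
        # the intercept is mapped back to the original scale on retention
        self.xbar = table.X.mean(axis=0) if table.n_covariates else np.zeros(0)
        self.Xc = table.X - self.xbar
        self.k = table.n_covariates
        self.n = table.n_areas
        self.log_y = np.log(self.y)
        self.log_1my = np.log1p(-self.y)
        self.graph = graph
        self.priors = priors
        self.config = config
        self.edges = graph.edges
        self.deg = graph.degree.astype(float)
        self.active = graph.degree > 0
        self.colors = _greedy_coloring(graph)
        # components restricted to non-isolated sites, for recentring and rank
        labels = graph.component_labels
        self.comps = [
            np.flatnonzero((labels == c) & self.active)
            for c in range(graph.n_components)
        ]
        self.comps = [c for c in self.comps if len(c) > 0]
        self.icar_rank = int(self.active.sum()) - len(self.comps)
        self.n_active = int(self.active.sum())
        # sparse adjacency for neighbor sums
        e = self.edges
        data = np.ones(2 * len(e))
        rows = np.concatenate([e[:, 0], e[:, 1]]) if len(e) else np.empty(0, int)
        cols = np.concatenate([e[:, 1], e[:, 0]]) if len(e) else np.empty(0, int)
        self._A = sparse.csr_matrix((data[: len(rows)], (rows, cols)), shape=(self.n, self.n))
        if likelihood_mask is None:
            self.mask = np.ones(self.n, bool)
        else:
            self.mask = np.asarray(likelihood_mask, bool).copy()
        if not config.include_likelihood:
            self.mask = np.zeros(self.n, bool)

    def loglik_vec(self, eta: np.ndarray, phi: float) -> np.ndarray:
        mu = expit(eta)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * self.log_y
            + (b - 1.0) * self.log_1my
        )
        return np.where(self.mask, ll, 0.0)

    def loglik_at(self, idx: np.ndarray, eta_idx: np.ndarray, phi: float) -> np.ndarray:
        mu = expit(eta_idx)
        a = mu * phi
        b = (1.0 - mu) * phi
        ll = (
            gammaln(phi)
            - gammaln(a)
            - gammaln(b)
            + (a - 1.0) * self.log_y[idx]
            + (b - 1.0) * self.log_1my[idx]
        )
        return np.where(self.mask[idx], ll, 0.0)

    def neighbor_sum(self, w: np.ndarray) -> np.ndarray:
        return self._A @ w


class _Scales:
    """Per-block Robbins-Monro adapted log proposal scales."""

    def __init__(self, n: int, k: int):
        self.beta0 = 0.1
        self.beta = np.full(k, 0.02)
        self.w = np.full(n, 0.3)
        self.v = np.full(n, 0.3)
        self.log_sw2 = 0.5
        self.log_sv2 = 0.5
        self.log_phi = 0.3
        self.rescale_w = 0.3
        self.rescale_v = 0.3


def _rm_gain(t: int) -> float:
    return 1.0 / (10.0 + t) ** 0.6


def _run_chain(model: _Model, config: MCMCConfig, seed_seq: np.random.SeedSequence, chain_id: int):
    rng = np.random.default_rng(seed_seq)
    n, k = model.n, model.k
    priors = model.priors
    a_prec, b_prec = priors.precision_prior
    a_phi, b_phi = priors.phi_prior
    target = config.target_accept

    # --- initialization: overdispersed across chains ---
    y_for_init = model.y[model.mask] if model.mask.any() else model.y
    beta0 = float(logit(np.clip(np.mean(y_for_init), 1e-3, 1 - 1e-3))) + rng.normal(0, 0.5)
    beta = rng.normal(0, 0.005, size=k)
    w = np.zeros(n)
    v = np.zeros(n)
    sw2 = config.fix_sigma_w2 if config.fix_sigma_w2 is not None else float(
        np.exp(rng.uniform(np.log(0.005), np.log(0.5)))
    )
    sv2 = config.fix_sigma_v2 if config.fix_sigma_v2 is not None else float(
        np.exp(rng.uniform(np.log(0.005), np.log(0.5)))
    )
    phi = config.fix_phi if config.fix_phi is not None else float(
        np.exp(rng.uniform(np.log(20.0), np.log(500.0)))
    )
    x_sw2, x_sv2, x_phi = math.log(sw2), math.log(sv2), math.log(phi)

    eta = beta0 + model.Xc @ beta + w + v
    ll_vec = model.loglik_vec(eta, phi)
    if not np.all(np.isfinite(ll_vec)):
        bad = np.flatnonzero(~np.isfinite(ll_vec))
        raise RuntimeError(
            f"non-finite log likelihood at initialization for areas {bad.tolist()}"
        )

    scales = _Scales(n, k)
    acc = {
        name: [0, 0]
        for name in ("beta0", "beta", "w", "v", "sigma_w2", "sigma_v2", "phi",
                     "rescale_w", "rescale_v")
    }

    n_ret = (config.n_iterations - config.n_burnin) // config.thin
    out = {
        "beta0": np.empty(n_ret),
        "beta": np.empty((n_ret, k)),
        "w": np.empty((n_ret, n)),
        "v": np.empty((n_ret, n)),
        "sigma_w2": np.empty(n_ret),
        "sigma_v2": np.empty(n_ret),
        "phi": np.empty(n_ret),
        "mu": np.empty((n_ret, n)),
    }
    ret = 0

    def prior_beta0(b0):
        sd = priors.beta0_sd
        return 0.0 if math.isinf(sd) else -0.5 * b0 * b0 / (sd * sd)

    for t in range(1, config.n_iterations + 1):
        adapting = t <= config.adapt_until
        gain = _rm_gain(t) if adapting else 0.0

        # ---- beta0 ----
        prop = beta0 + scales.beta0 * rng.standard_normal()
        eta_p = eta + (prop - beta0)
        ll_p = model.loglik_vec(eta_p, phi)
        logr = ll_p.sum() - ll_vec.sum() + prior_beta0(prop) - prior_beta0(beta0)
        a_prob = min(1.0, math.exp(min(0.0, logr)))
        if rng.random() < a_prob:
            beta0, eta, ll_vec = prop, eta_p, ll_p
            acc["beta0"][0] += 1
        acc["beta0"][1] += 1
        if adapting:
            scales.beta0 *= math.exp(gain * (a_prob - target))

        # ---- each beta_j ----
        for j in range(k):
            prop = beta[j] + scales.beta[j] * rng.standard_normal()
            eta_p = eta + model.Xc[:, j] * (prop - beta[j])
            ll_p = model.loglik_vec(eta_p, phi)
            dprior = -0.5 * (prop**2 - beta[j] ** 2) / priors.beta_sd**2
            logr = ll_p.sum() - ll_vec.sum() + dprior
            a_prob = min(1.0, math.exp(min(0.0, logr)))
            if rng.random() < a_prob:
                beta[j], eta, ll_vec = prop, eta_p, ll_p
                acc["beta"][0] += 1
            acc["beta"][1] += 1
            if adapting:
                scales.beta[j] *= math.exp(gain * (a_prob - target))

        # ---- w sweep (even iterations) ----
        if model.colors:
            for block in model.colors:
                nbr_sum = model.neighbor_sum(w)[block]
                w_old = w[block]
                delta = scales.w[block] * rng.standard_normal(len(block))
                w_new = w_old + delta
                ll_old = ll_vec[block]
                ll_new = model.loglik_at(block, eta[block] + delta, phi)
                dkern = -0.5 / sw2 * (
                    model.deg[block] * (w_new**2 - w_old**2)
                    - 2.0 * nbr_sum * (w_new - w_old)
                )
                logr = ll_new - ll_old + dkern
                a_prob = np.exp(np.minimum(0.0, logr))
                accept = rng.random(len(block)) < a_prob
                idx = block[accept]
                w[idx] = w_new[accept]
                eta[idx] += delta[accept]
                ll_vec[idx] = ll_new[accept]
                acc["w"][0] += int(accept.sum())
                acc["w"][1] += len(block)
                if adapting:
                    scales.w[block] *= np.exp(gain * (a_prob - target))
            # recenter per component; fold the (size-weighted) level into beta0
            shift = 0.0
            for comp in model.comps:
                m = w[comp].mean()
                w[comp] -= m
                shift += m * len(comp) / model.n_active
            if model.comps:
                beta0 += shift
                eta = beta0 + model.Xc @ beta + w + v
                ll_vec = model.loglik_vec(eta, phi)

        # ---- v sweep (odd iterations) ----
        if config.include_v:
            delta = scales.v * rng.standard_normal(n)
            v_new = v + delta
            ll_new = model.loglik_vec(eta + delta, phi)
            dprior = -0.5 * (v_new**2 - v**2) / sv2
            logr = ll_new - ll_vec + dprior
            a_prob = np.exp(np.minimum(0.0, logr))
            accept = rng.random(n) < a_prob
            v[accept] = v_new[accept]
            eta[accept] += delta[accept]
            ll_vec[accept] = ll_new[accept]
            acc["v"][0] += int(accept.sum())
            acc["v"][1] += n
            if adapting:
                scales.v *= np.exp(gain * (a_prob - target))

        # ---- log sigma_w2 ----
        if config.fix_sigma_w2 is None:
            e = model.edges
            S = float(np.sum((w[e[:, 0]] - w[e[:, 1]]) ** 2)) if len(e) else 0.0

            def lp_sw(x):
                # ICAR kernel + Gamma(a,b) prior on precision, density over x=log s2
                return -0.5 * S * math.exp(-x) - 0.5 * model.icar_rank * x - a_prec * x - b_prec * math.exp(-x)

            prop = x_sw2 + scales.log_sw2 * rng.standard_normal()
            logr = lp_sw(prop) - lp_sw(x_sw2)
            a_prob = min(1.0, math.exp(min(0.0, logr)))
            if rng.random() < a_prob:
                x_sw2 = prop
                sw2 = math.exp(x_sw2)
                acc["sigma_w2"][0] += 1
            acc["sigma_w2"][1] += 1
            if adapting:
                scales.log_sw2 *= math.exp(gain * (a_prob - target))

        # ---- log sigma_v2 ----
        if config.fix_sigma_v2 is None and config.include_v:
            Sv = float(v @ v)

            def lp_sv(x):
                return -0.5 * Sv * math.exp(-x) - 0.5 * n * x - a_prec * x - b_prec * math.exp(-x)

            prop = x_sv2 + scales.log_sv2 * rng.standard_normal()
            logr = lp_sv(prop) - lp_sv(x_sv2)
            a_prob = min(1.0, math.exp(min(0.0, logr)))
            if rng.random() < a_prob:
                x_sv2 = prop
                sv2 = math.exp(x_sv2)
                acc["sigma_v2"][0] += 1
            acc["sigma_v2"][1] += 1
            if adapting:
                scales.log_sv2 *= math.exp(gain * (a_prob - target))

        # ---- joint rescale of (w, sigma_w2): funnel traversal ----
        # proposes w' = c w, sigma_w2' = c^2 sigma_w2, which leaves the ICAR
        # kernel invariant and lets the chain cross the small-variance funnel;
        # Jacobian c^(rank+2) since w moves on the constrained subspace
        if config.fix_sigma_w2 is None and model.colors:
            logc = scales.rescale_w * rng.standard_normal()
            c = math.exp(logc)
            eta_p = eta + (c - 1.0) * w
            ll_p = model.loglik_vec(eta_p, phi)
            sw2_p = c * c * sw2
            logr = (
                ll_p.sum() - ll_vec.sum()
                - model.icar_rank * logc
                - 2.0 * (a_prec + 1.0) * logc
                - b_prec * (1.0 / sw2_p - 1.0 / sw2)
                + (model.icar_rank + 2.0) * logc
            )
            a_prob = min(1.0, math.exp(min(0.0, logr)))
            if rng.random() < a_prob:
                w = c * w
                eta, ll_vec = eta_p, ll_p
                sw2, x_sw2 = sw2_p, x_sw2 + 2.0 * logc
                acc["rescale_w"][0] += 1
            acc["rescale_w"][1] += 1
            if adapting:
                scales.rescale_w *= math.exp(gain * (a_prob - target))

        # ---- joint rescale of (v, sigma_v2) ----
        if config.fix_sigma_v2 is None and config.include_v:
            logc = scales.rescale_v * rng.standard_normal()
            c = math.exp(logc)
            eta_p = eta + (c - 1.0) * v
            ll_p = model.loglik_vec(eta_p, phi)
            sv2_p = c * c * sv2
            logr = (
                ll_p.sum() - ll_vec.sum()
                - n * logc
                - 2.0 * (a_prec + 1.0) * logc
                - b_prec * (1.0 / sv2_p - 1.0 / sv2)
                + (n + 2.0) * logc
            )
            a_prob = min(1.0, math.exp(min(0.0, logr)))
            if rng.random() < a_prob:
                v = c * v
                eta, ll_vec = eta_p, ll_p
                sv2, x_sv2 = sv2_p, x_sv2 + 2.0 * logc
                acc["rescale_v"][0] += 1
            acc["rescale_v"][1] += 1
            if adapting:
                scales.rescale_v *= math.exp(gain * (a_prob - target))

        # ---- log phi ----
        if config.fix_phi is None:
            prop = x_phi + scales.log_phi * rng.standard_normal()
            phi_p = math.exp(prop)
            ll_p = model.loglik_vec(eta, phi_p)
            # Gamma(a,b) prior on phi with log-scale Jacobian: a*x - b*e^x
            dprior = (a_phi * prop - b_phi * phi_p) - (a_phi * x_phi - b_phi * phi)
            logr = ll_p.sum() - ll_vec.sum() + dprior
            a_prob = min(1.0, math.exp(min(0.0, logr)))
            if rng.random() < a_prob:
                x_phi, phi, ll_vec = prop, phi_p, ll_p
                acc["phi"][0] += 1
            acc["phi"][1] += 1
            if adapting:
                scales.log_phi *= math.exp(gain * (a_prob - target))

        # ---- retain ----
        if t > config.n_burnin and (t - config.n_burnin) % config.thin == 0:
            out["beta0"][ret] = beta0 - model.xbar @ beta
            out["beta"][ret] = beta
            out["w"][ret] = w
            out["v"][ret] = v
            out["sigma_w2"][ret] = sw2
            out["sigma_v2"][ret] = sv2
            out["phi"][ret] = phi
            out["mu"][ret] = expit(eta)
            ret += 1

    rates = {name: (c[0] / c[1] if c[1] else float("nan")) for name, c in acc.items()}
    return out, rates


def run_sampler(
    table: CountyTable,
    graph: SpatialGraph,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    *,
    likelihood_mask: np.ndarray | None = None,
) -> PosteriorSamples:
    """Draw from the beta-BYM posterior; deterministic given config.seed.

    ``likelihood_mask`` (boolean per area) excludes areas from the data term
    while keeping their random effects in the priors — the basis of
    leave-one-out validation.
    """
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    model = _Model(table, graph, priors, config, likelihood_mask)

    seqs = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    all_out, all_rates = [], []
    for c, sq in enumerate(seqs):
        out, rates = _run_chain(model, config, sq, c)
        all_out.append(out)
        all_rates.append(rates)

    n_ret = len(all_out[0]["beta0"])
    pooled = {
        key: np.concatenate([o[key] for o in all_out], axis=0)
        for key in all_out[0]
    }
    chain_id = np.repeat(np.arange(config.n_chains), n_ret)
    mean_rates = {
        name: float(np.mean([r[name] for r in all_rates]))
        for name in all_rates[0]
        if not math.isnan(all_rates[0][name])
    }
    return PosteriorSamples(
        beta0=pooled["beta0"],
        beta=pooled["beta"],
        w=pooled["w"],
        v=pooled["v"],
        sigma_w2=pooled["sigma_w2"],
        sigma_v2=pooled["sigma_v2"],
        phi=pooled["phi"],
        mu=pooled["mu"],
        chain_id=chain_id,
        acceptance_rates=mean_rates,
        config=config,
        covariate_names=list(table.covariate_names),
        area_id=list(table.area_id),
    )


# ---------------------------------------------------------- diagnostics ---


def diagnostics(samples: PosteriorSamples, rhat_threshold: float = 1.05) -> DiagnosticsReport:
    """Rank-normalized split-Rhat and bulk ESS per scalar parameter (via arviz)."""
    if samples.n_chains < 2:
        raise ValueError("diagnostics require at least 2 chains")
    per_chain = samples.n_draws // samples.n_chains
    if per_chain < 100:
        raise ValueError("diagnostics require at least 100 retained draws per chain")
    rhat: dict[str, float] = {}
    ess: dict[str, float] = {}
    items = dict(samples.scalar_draws())
    for i in range(samples.mu.shape[1]):
        aid = samples.area_id[i] if samples.area_id else str(i)
        items[f"mu[{aid}]"] = samples.mu[:, i]
    fixed = {
        "sigma_w2": samples.config.fix_sigma_w2,
        "sigma_v2": samples.config.fix_sigma_v2,
        "phi": samples.config.fix_phi,
    }
    for name, draws in items.items():
        if fixed.get(name) is not None or np.ptp(draws) == 0:
            continue  # constants carry no convergence information
        arr = samples.by_chain(draws)
        rhat[name] = float(az.rhat(arr))
        ess[name] = float(az.ess(arr))
    converged = all(r < rhat_threshold for r in rhat.values())
    return DiagnosticsReport(rhat, ess, samples.acceptance_rates, converged)


def summarize_posterior(samples: PosteriorSamples) -> ParameterSummary:
    """Pooled posterior mean, sd and central 95% interval per scalar parameter."""
    if samples.n_draws == 0:
        raise ValueError("no retained draws to summarize")
    rows = {}
    for name, draws in samples.scalar_draws().items():
        rows[name] = {
            "mean": float(np.mean(draws)),
            "sd": float(np.std(draws, ddof=1)) if len(draws) > 1 else 0.0,
            "q2.5": credible_quantile(draws, 0.025),
            "q97.5": credible_quantile(draws, 0.975),
        }
    return ParameterSummary(pd.DataFrame(rows).T[["mean", "sd", "q2.5", "q97.5"]])


def credible_quantile(draws, q):
    """Median-unbiased empirical quantile, the package-wide CrI convention."""
    return float(np.quantile(np.asarray(draws, float), q, method="median_unbiased"))
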