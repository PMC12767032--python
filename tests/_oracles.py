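"""Independent reference implementations used only as test oracles.

Everything here is written against scipy.stats / dense linear algebra and
deliberately shares no code with the package: a fully expanded log posterior
for difference checks, and dense-grid numerical integration of a reduced
beta-BYM model (v collapsed, phi and sigma_w2 fixed, w expressed in an
orthonormal basis of the sum-to-zero subspace) giving posterior means and
quantiles of beta0 and beta1 without any Monte Carlo.
"""

from __future__ import annotations

import numpy as np
from scipy import stats


def reference_log_posterior(state, table, graph, priors) -> float:
    """Fully expanded joint log posterior (independent of the package path).

    Matches betabym.log_posterior up to a state-independent constant, so
    differences between two states must agree exactly.
    """
    y, X = table.y, table.X
    eta = state.beta0 + X @ state.beta + state.w + state.v
    mu = 1.0 / (1.0 + np.exp(-eta))
    a = mu * state.phi
    b = (1.0 - mu) * state.phi
    lp = float(np.sum(stats.beta.logpdf(y, a, b)))

    # ICAR: pairwise-difference kernel + rank-based normalizer
    S = 0.0
    for i, nbrs in enumerate(graph.neighbors):
        for j in nbrs:
            if j > i:
                S += (state.w[i] - state.w[j]) ** 2
    deg = graph.degree
    active = deg > 0
    n_active_comps = len(np.unique(graph.component_labels[active])) if active.any() else 0
    rank = int(active.sum()) - n_active_comps
    lp += -0.5 * S / state.sigma_w2 - 0.5 * rank * np.log(state.sigma_w2)

    lp += float(np.sum(stats.norm.logpdf(state.v, 0.0, np.sqrt(state.sigma_v2))))

    if np.isfinite(priors.beta0_sd):
        lp += float(stats.norm.logpdf(state.beta0, 0.0, priors.beta0_sd))
    lp += float(np.sum(stats.norm.logpdf(state.beta, 0.0, priors.beta_sd)))
    ap, bp = priors.precision_prior
    # gamma prior on each precision, with the change-of-variables to sigma^2
    for s2 in (state.sigma_w2, state.sigma_v2):
        lp += float(stats.gamma.logpdf(1.0 / s2, ap, scale=1.0 / bp)) - 2.0 * np.log(s2)
    aphi, bphi = priors.phi_prior
    lp += float(stats.gamma.logpdf(state.phi, aphi, scale=1.0 / bphi))
    return lp


def _weighted_quantile(x: np.ndarray, weights: np.ndarray, q: float) -> float:
    # midpoint-CDF convention: treat each grid atom as mass spread over its
    # cell, so the CDF is evaluated at cell centers (removes the half-cell bias)
    w = weights / weights.sum()
    cdf = np.cumsum(w) - 0.5 * w
    return float(np.interp(q, cdf, x))


def grid_posterior_reduced(
    y: np.ndarray,
    x: np.ndarray,
    Q: np.ndarray,
    phi: float,
    sigma_w2: float,
    beta_sd: float,
    b0_grid: np.ndarray,
    b1_grid: np.ndarray,
    n_z: int = 17,
    z_half_width_sd: float = 5.0,
) -> dict:
    """Dense-grid posterior of (beta0, beta1) in the reduced beta-BYM model.

    Model: y_i ~ Beta(mu_i phi, (1-mu_i) phi), logit(mu) = b0 + b1 x + w,
    w = B z on the sum-to-zero subspace (B = eigenvectors of Q with positive
    eigenvalue, so the prior of z is independent N(0, sigma_w2/lambda_j));
    flat prior on b0, N(0, beta_sd^2) on b1. Returns marginal moments and
    central-interval endpoints for b0 and b1 plus the largest relative
    marginal mass on any grid boundary (to certify the grid covers the
    posterior).
    """
    lam, U = np.linalg.eigh(Q)
    pos = lam > 1e-9 * lam.max()
    B = U[:, pos]
    lam_pos = lam[pos]
    n_free = B.shape[1]
    sd_z = np.sqrt(sigma_w2 / lam_pos)
    z_grids = [np.linspace(-z_half_width_sd * s, z_half_width_sd * s, n_z) for s in sd_z]

    mesh = np.meshgrid(*z_grids, indexing="ij")
    w_field = sum(mesh[j][..., None] * B[:, j] for j in range(n_free))  # (*z_shape, n)
    log_prior_z = sum(-0.5 * lam_pos[j] * mesh[j] ** 2 / sigma_w2 for j in range(n_free))
    log_prior_b1 = -0.5 * b1_grid**2 / beta_sd**2

    shape = (len(b0_grid), len(b1_grid)) + mesh[0].shape
    log_post = np.empty(shape)
    b1_col = b1_grid.reshape(-1, *([1] * (n_free + 1)))  # broadcast over z axes + area axis
    for i0, b0 in enumerate(b0_grid):
        eta = b0 + b1_col * x + w_field[None]
        mu = 1.0 / (1.0 + np.exp(-eta))
        ll = stats.beta.logpdf(y, mu * phi, (1.0 - mu) * phi).sum(axis=-1)
        log_post[i0] = ll + log_prior_z[None] + log_prior_b1.reshape(-1, *([1] * n_free))

    p = np.exp(log_post - log_post.max())

    out = {}
    axes_all = tuple(range(log_post.ndim))
    for name, axis, grid in (("beta0", 0, b0_grid), ("beta1", 1, b1_grid)):
        marg = p.sum(axis=tuple(a for a in axes_all if a != axis))
        marg = marg / marg.sum()
        mean = float(np.sum(grid * marg))
        sd = float(np.sqrt(np.sum((grid - mean) ** 2 * marg)))
        out[name] = {
            "mean": mean,
            "sd": sd,
            "q2.5": _weighted_quantile(grid, marg, 0.025),
            "q97.5": _weighted_quantile(grid, marg, 0.975),
            "edge_mass": float(marg[0] + marg[-1]),
        }
    # boundary mass along the z axes as well (grid-coverage certificate)
    z_edge = 0.0
    for j in range(n_free):
        axis = 2 + j
        marg = p.sum(axis=tuple(a for a in axes_all if a != axis))
        marg = marg / marg.sum()
        z_edge = max(z_edge, float(marg[0] + marg[-1]))
    out["z_edge_mass"] = z_edge
    return out


def mc_se_mean(draws_by_chain: np.ndarray) -> float:
    """Monte-Carlo standard error of the posterior mean, via arviz bulk ESS."""
    import arviz as az

    ess = float(az.ess(draws_by_chain))
    return float(draws_by_chain.std(ddof=1) / np.sqrt(max(ess, 1.0)))


def mc_se_quantile(draws_by_chain: np.ndarray, q: float) -> float:
    """MC standard error of an empirical quantile (ESS-adjusted, KDE density)."""
    import arviz as az

    flat = draws_by_chain.reshape(-1)
    ess = float(az.ess(draws_by_chain, method="quantile", prob=q))
    xq = np.quantile(flat, q)
    dens = float(stats.gaussian_kde(flat)(xq)[0])
    return float(np.sqrt(q * (1 - q) / max(ess, 1.0)) / max(dens, 1e-12))
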