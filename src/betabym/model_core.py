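"""The beta-BYM probability model.

Observed county prevalence proportions y_i in (0, 1) are modeled as
conditionally independent Beta(mu_i * phi, (1 - mu_i) * phi), the
mean-precision parameterization, so E(y_i) = mu_i and
Var(y_i) = mu_i (1 - mu_i) / (1 + phi). The mean follows a logit-linked
Besag-York-Mollie (BYM) linear predictor

    logit(mu_i) = beta0 + x_i' beta + w_i + v_i,

where w is an intrinsic CAR (ICAR) spatially structured effect with
variance sigma_w^2, constrained to sum to zero within every connected
component of the contiguity graph, and v_i ~ N(0, sigma_v^2) is an
unstructured heterogeneity effect. Priors emulate the vague defaults of
standard Bayesian disease-mapping software: wide normal coefficients,
flat intercept, Gamma(1, 5e-5) on both random-effect precisions and
Gamma(1, 0.01) on phi; all overridable through PriorSpec.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, gammaln

from .data_io import CountyTable, DomainError, IntegrityError
from .spatial_graph import SpatialGraph

__all__ = [
    "ParameterState",
    "PriorSpec",
    "LinearPredictorView",
    "logit",
    "inv_logit",
    "beta_log_density",
    "icar_log_density",
    "linear_predictor",
    "log_posterior",
]


def logit(p):
    """log(p / (1-p)); domain error outside the open unit interval."""
    p = np.asarray(p, dtype=float)
    if np.any(p <= 0) or np.any(p >= 1):
        raise DomainError("logit requires values strictly in (0, 1)")
    out = np.log(p) - np.log1p(-p)
    return float(out) if out.ndim == 0 else out


def inv_logit(x):
    """Numerically stable inverse logit; never underflows to exactly 0 or 1 sign-side."""
    out = expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def beta_log_density(y, mu, phi) -> float | np.ndarray:
    """Log density of Beta(mu*phi, (1-mu)*phi) at y, elementwise.

    Shapes a = mu*phi, b = (1-mu)*phi; finite for interior y.
    """
    y = np.asarray(y, dtype=float)
    mu = np.asarray(mu, dtype=float)
    phi = np.asarray(phi, dtype=float)
    if np.any(y <= 0) or np.any(y >= 1):
        raise DomainError("beta_log_density requires y strictly in (0, 1)")
    if np.any(mu <= 0) or np.any(mu >= 1) or np.any(phi <= 0):
        raise DomainError("require mu in (0,1) and phi > 0")
    a = mu * phi
    b = (1.0 - mu) * phi
    out = (
        gammaln(phi)
        - gammaln(a)
        - gammaln(b)
        + (a - 1.0) * np.log(y)
        + (b - 1.0) * np.log1p(-y)
    )
    return float(out) if out.ndim == 0 else out


def icar_pairwise_sum(w: np.ndarray, graph: SpatialGraph) -> float:
    """Sum over undirected edges of (w_i - w_j)^2, each edge counted once."""
    e = graph.edges
    if len(e) == 0:
        return 0.0
    d = w[e[:, 0]] - w[e[:, 1]]
    return float(d @ d)


def check_sum_to_zero(w: np.ndarray, graph: SpatialGraph, tol: float = 1e-8) -> None:
    labels = graph.component_labels
    deg = graph.degree
    for c in range(graph.n_components):
        members = np.flatnonzero(labels == c)
        if deg[members].sum() == 0:
            continue  # isolated area: w fixed at 0, no constraint needed
        s = w[members].sum()
        if abs(s) > tol:
            raise DomainError(
                f"w violates sum-to-zero in component {c}: |sum| = {abs(s):.3e} > {tol:g}"
            )


def icar_rank(graph: SpatialGraph) -> int:
    """Rank of Q: (#non-isolated areas) - (#components containing an edge)."""
    deg = graph.degree
    active = deg > 0
    labels = graph.component_labels
    n_active_components = len(np.unique(labels[active])) if active.any() else 0
    return int(active.sum()) - n_active_components


def icar_log_density(w: np.ndarray, graph: SpatialGraph, sigma_w2: float) -> float:
    """Log of the intrinsic CAR density on the sum-to-zero subspace, up to a constant.

    Pairwise-difference form: -(1/(2 sigma_w^2)) sum_{i~j} (w_i - w_j)^2
    minus (rank/2) log sigma_w^2, rank = n - c. Isolated areas contribute
    nothing. Raises if the per-component constraint is violated beyond 1e-8.
    """
    w = np.asarray(w, dtype=float)
    if sigma_w2 <= 0:
        raise DomainError("sigma_w2 must be positive")
    check_sum_to_zero(w, graph)
    S = icar_pairwise_sum(w, graph)
    return -0.5 * S / sigma_w2 - 0.5 * icar_rank(graph) * math.log(sigma_w2)


@dataclass
class PriorSpec:
    """Hyperparameters of the vague default priors.

    beta_sd: normal sd for each regression coefficient (31.62 = precision 0.001).
    beta0_sd: normal sd for the intercept; inf means flat.
    precision_prior: Gamma(shape, rate) on 1/sigma_w^2 and 1/sigma_v^2.
    phi_prior: Gamma(shape, rate) on the beta precision phi.
    """

    beta_sd: float = 31.622776601683793
    beta0_sd: float = math.inf
    precision_prior: tuple[float, float] = (1.0, 5e-5)
    phi_prior: tuple[float, float] = (1.0, 0.01)

    def __post_init__(self) -> None:
        for v in (self.beta_sd, self.beta0_sd, *self.precision_prior, *self.phi_prior):
            if not v > 0:
                raise ValueError("all prior hyperparameters must be strictly positive")

    def to_dict(self) -> dict:
        return {
            "beta_sd": self.beta_sd,
            "beta0_sd": None if math.isinf(self.beta0_sd) else self.beta0_sd,
            "precision_prior": list(self.precision_prior),
            "phi_prior": list(self.phi_prior),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorSpec":
        d = dict(d)
        if d.get("beta0_sd") is None:
            d["beta0_sd"] = math.inf
        if "precision_prior" in d:
            d["precision_prior"] = tuple(d["precision_prior"])
        if "phi_prior" in d:
            d["phi_prior"] = tuple(d["phi_prior"])
        return cls(**d)


@dataclass
class ParameterState:
    """One point in parameter space (see module docstring for roles)."""

    beta0: float
    beta: np.ndarray
    w: np.ndarray
    v: np.ndarray
    sigma_w2: float
    sigma_v2: float
    phi: float

    def __post_init__(self) -> None:
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        self.w = np.asarray(self.w, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if not (self.sigma_w2 > 0 and self.sigma_v2 > 0 and self.phi > 0):
            raise DomainError("variances and phi must be strictly positive")

    def copy(self) -> "ParameterState":
        return replace(self, beta=self.beta.copy(), w=self.w.copy(), v=self.v.copy())


@dataclass
class LinearPredictorView:
    eta: np.ndarray
    mu: np.ndarray


def linear_predictor(state: ParameterState, X: np.ndarray) -> LinearPredictorView:
    eta = state.beta0 + X @ state.beta + state.w + state.v
    return LinearPredictorView(eta=eta, mu=inv_logit(eta))


def _log_normal_kernel(x, sd: float) -> float:
    if math.isinf(sd):
        return 0.0
    x = np.asarray(x, dtype=float)
    return float(-0.5 * np.sum(x * x) / (sd * sd))


def _log_gamma_kernel(x: float, shape: float, rate: float) -> float:
    return (shape - 1.0) * math.log(x) - rate * x


def _log_prior_sigma2(s2: float, shape: float, rate: float) -> float:
    # Gamma(shape, rate) prior on the precision 1/s2, expressed as a density
    # over s2 itself (includes the |d tau / d s2| = s2^-2 Jacobian).
    return -(shape + 1.0) * math.log(s2) - rate / s2


def log_posterior(
    state: ParameterState,
    table: CountyTable,
    graph: SpatialGraph,
    priors: PriorSpec,
    *,
    likelihood_mask: np.ndarray | None = None,
    include_likelihood: bool = True,
) -> float:
    """Joint log posterior up to a state-independent constant.

    Sum of: beta log likelihood over areas (optionally masked, for holdout
    prediction), the ICAR kernel of w, the iid normal kernel of v, and the
    priors on beta0, beta, the two random-effect precisions and phi.
    """
    n = table.n_areas
    if len(state.w) != n or len(state.v) != n or graph.n != n:
        raise IntegrityError("state / table / graph dimensions are misaligned")
    if len(state.beta) != table.n_covariates:
        raise IntegrityError(
            f"{len(state.beta)} coefficients for {table.n_covariates} covariates"
        )

    lp = 0.0
    if include_likelihood:
        ll = beta_log_density(table.y, linear_predictor(state, table.X).mu, state.phi)
        if likelihood_mask is not None:
            ll = np.where(np.asarray(likelihood_mask, bool), ll, 0.0)
        lp += float(np.sum(ll))

    lp += icar_log_density(state.w, graph, state.sigma_w2)
    lp += _log_normal_kernel(state.v, math.sqrt(state.sigma_v2)) - 0.5 * n * math.log(
        state.sigma_v2
    )
    lp += _log_normal_kernel(state.beta0, priors.beta0_sd)
    lp += _log_normal_kernel(state.beta, priors.beta_sd)
    a, b = priors.precision_prior
    lp += _log_prior_sigma2(state.sigma_w2, a, b)
    lp += _log_prior_sigma2(state.sigma_v2, a, b)
    ap, bp = priors.phi_prior
    lp += _log_gamma_kernel(state.phi, ap, bp)
    return lp
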