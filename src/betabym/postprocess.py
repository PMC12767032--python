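"""From posterior draws to reported quantities.

Per-area predicted prevalence (posterior mean of mu_i) with SD and 95%
credible interval, exceedance probabilities Pr(mu_i > t | data) for policy
thresholds, covariate significance by the 95%-CrI-excludes-zero rule,
overall summaries, and area-level leave-one-out cross-validation in which
the held-out area is predicted from its covariates plus the ICAR
conditional mean of its neighbors' sampled spatial effects.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .data_io import CountyTable
from .mcmc import MCMCConfig, ParameterSummary, PosteriorSamples, run_sampler, summarize_posterior
from .model_core import PriorSpec, inv_logit
from .spatial_graph import SpatialGraph

logger = logging.getLogger("betabym")

__all__ = [
    "FitResult",
    "ValidationResult",
    "county_predictions",
    "exceedance_probabilities",
    "significant_covariates",
    "overall_summary",
    "loocv_validate",
    "fit_result",
]

DEFAULT_THRESHOLDS = (0.70, 0.75)


@dataclass
class FitResult:
    """Per-area predictions, exceedance probabilities and covariate inference."""

    areas: pd.DataFrame  # index area_id: observed, predicted, sd, q2.5, q97.5, exceed_*
    covariates: pd.DataFrame  # index covariate: mean, sd, q2.5, q97.5, significant
    overall: dict  # mean/min/max of observed and predicted
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    summary: ParameterSummary | None = None

    def to_csv(self, path) -> None:
        self.areas.to_csv(path, index=True)

    def to_json(self, path) -> None:
        payload = {
            "overall": self.overall,
            "thresholds": list(self.thresholds),
            "covariates": json.loads(self.covariates.to_json(orient="index")),
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class ValidationResult:
    predictions: pd.DataFrame  # index area_id: observed, predicted (held out)
    r: float
    p_value: float
    folds: list[int] = field(default_factory=list)


def county_predictions(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior mean, SD and central 95% interval of each area's prevalence."""
    mu = samples.mu
    sd = mu.std(axis=0, ddof=1) if mu.shape[0] > 1 else np.zeros(mu.shape[1])
    sd[np.ptp(mu, axis=0) == 0] = 0.0  # all-equal draws: no rounding residue
    df = pd.DataFrame(
        {
            "predicted": mu.mean(axis=0),
            "sd": sd,
            "q2.5": np.quantile(mu, 0.025, axis=0, method="median_unbiased"),
            "q97.5": np.quantile(mu, 0.975, axis=0, method="median_unbiased"),
        },
        index=pd.Index(samples.area_id or range(mu.shape[1]), name="area_id"),
    )
    return df


def exceedance_probabilities(samples: PosteriorSamples, threshold: float) -> np.ndarray:
    """Per-area fraction of retained draws with mu_i above the threshold."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    return (samples.mu > threshold).mean(axis=0)


def significant_covariates(summary: ParameterSummary) -> pd.DataFrame:
    """Flag a coefficient significant iff its 95% CrI excludes zero."""
    rows = summary.table[summary.table.index.str.startswith("beta[")]
    out = rows.copy()
    out["significant"] = ((rows["q2.5"] > 0) | (rows["q97.5"] < 0)).to_numpy()
    out.index = [name[5:-1] for name in rows.index]
    return out


def overall_summary(predictions: pd.DataFrame, observed: np.ndarray | None = None) -> dict:
    """Unweighted mean/min/max of predicted (and observed) prevalence across areas."""
    if len(predictions) == 0:
        raise ValueError("empty prediction table")
    out = {
        "predicted_mean": float(predictions["predicted"].mean()),
        "predicted_min": float(predictions["predicted"].min()),
        "predicted_max": float(predictions["predicted"].max()),
    }
    if observed is not None:
        out.update(
            observed_mean=float(np.mean(observed)),
            observed_min=float(np.min(observed)),
            observed_max=float(np.max(observed)),
        )
    return out


def fit_result(
    samples: PosteriorSamples,
    table: CountyTable,
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
) -> FitResult:
    """Assemble the full reporting bundle from a posterior sample."""
    preds = county_predictions(samples)
    preds.insert(0, "observed", table.y)
    preds.insert(1, "area_name", table.area_name)
    for t in thresholds:
        preds[f"exceed_{t:g}"] = exceedance_probabilities(samples, t)
    summ = summarize_posterior(samples)
    covs = significant_covariates(summ)
    overall = overall_summary(preds, observed=table.y)
    return FitResult(preds, covs, overall, tuple(thresholds), summ)


def holdout_prediction_draws(samples: PosteriorSamples, graph: SpatialGraph, X: np.ndarray, i: int) -> np.ndarray:
    """Per-draw held-out mu_i: covariates plus the neighbor mean of sampled w."""
    nbrs = graph.neighbors[i]
    w_star = samples.w[:, list(nbrs)].mean(axis=1) if nbrs else 0.0
    eta = samples.beta0 + samples.beta @ X[i] + w_star
    return inv_logit(eta)


def loocv_validate(
    table: CountyTable,
    graph: SpatialGraph,
    priors: PriorSpec | None = None,
    config: MCMCConfig | None = None,
    *,
    folds: list[int] | None = None,
) -> ValidationResult:
    """Area-level leave-one-out cross-validation.

    For each fold the model is refit with that area's likelihood term removed;
    its prevalence is predicted per draw as inv_logit(beta0 + x_i'beta + w_i*)
    with w_i* the average of the neighbors' sampled spatial effects (0 for an
    isolated area), i.e. the ICAR conditional mean. Returns held-out posterior
    mean predictions and their Pearson correlation with the observed values.
    ``folds`` restricts validation to a subset of areas (fast mode).
    """
    n = table.n_areas
    if n < 5:
        raise ValueError("leave-one-out validation needs at least 5 areas")
    priors = priors or PriorSpec()
    config = config or MCMCConfig()
    folds = list(range(n)) if folds is None else sorted(folds)

    preds = np.full(n, np.nan)
    for i in folds:
        mask = np.ones(n, bool)
        mask[i] = False
        fold_cfg = MCMCConfig(**{**config.__dict__, "seed": config.seed + 1000 + i})
        samples = run_sampler(table, graph, priors, fold_cfg, likelihood_mask=mask)
        preds[i] = holdout_prediction_draws(samples, graph, table.X, i).mean()
        logger.debug("fold %d/%d: predicted %.4f observed %.4f", i, n, preds[i], table.y[i])

    obs = table.y[folds]
    est = preds[folds]
    r, p = stats.pearsonr(obs, est)
    df = pd.DataFrame(
        {"observed": obs, "predicted": est},
        index=pd.Index([table.area_id[i] for i in folds], name="area_id"),
    )
    return ValidationResult(df, float(r), float(p), folds)
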