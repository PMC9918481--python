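"""k-fold cross-validation of the spatial model.

Held-out clusters are scored by four metrics comparing the posterior
mean predicted prevalence p̂_i against the observed cluster proportion
p_i = y_i/m_i:

* Pearson correlation  ρ(p̂, p) = cov(p̂, p) / (σ_p̂ σ_p)
* root mean squared error  √(Σ(p̂_i − p_i)² / n_test)
* mean absolute error      Σ|p̂_i − p_i| / n_test
* percentage bias          100 · Σ(p̂_i − p_i) / Σ p_j

Undefined cases (zero-variance vectors for ρ, zero denominator for the
percentage bias) are returned as NaN with a warning rather than raised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import InferenceConfig, PriorSpec, fit_spatial_binomial
from .predict import predict_at_points


@dataclass
class CVResult:
    """Cross-validation results: per-fold and pooled metrics."""

    k: int
    seed: int
    per_fold: list[dict] = field(default_factory=list)
    pooled: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"k": self.k, "seed": self.seed, "per_fold": self.per_fold,
                "pooled": self.pooled}


def kfold_split(n: int, k: int, seed: int) -> np.ndarray:
    """Random fold assignment of ``n`` items into ``k`` folds of near-equal size.

    Fold sizes differ by at most one; deterministic given ``seed``.
    """
    if not 2 <= k <= n:
        raise ValueError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    assign = np.empty(n, dtype=int)
    base, rem = divmod(n, k)
    start = 0
    for f in range(k):
        size = base + (1 if f < rem else 0)
        assign[perm[start:start + size]] = f
        start += size
    return assign


def _check_lengths(p_hat, p):
    p_hat = np.asarray(p_hat, float)
    p = np.asarray(p, float)
    if p_hat.shape != p.shape:
        raise ValueError(f"length mismatch: {p_hat.shape} vs {p.shape}")
    return p_hat, p


def metric_pearson(p_hat, p) -> float:
    """Pearson correlation; NaN (with warning) if either vector is constant."""
    p_hat, p = _check_lengths(p_hat, p)
    if len(p) < 2:
        raise ValueError("need n_test >= 2 for the correlation")
    if np.std(p_hat) == 0 or np.std(p) == 0:
        warnings.warn("zero-variance vector: correlation undefined", RuntimeWarning,
                      stacklevel=2)
        return float("nan")
    return float(np.corrcoef(p_hat, p)[0, 1])


def metric_rmse(p_hat, p) -> float:
    p_hat, p = _check_lengths(p_hat, p)
    return float(np.sqrt(np.mean((p_hat - p) ** 2)))


def metric_mae(p_hat, p) -> float:
    p_hat, p = _check_lengths(p_hat, p)
    return float(np.mean(np.abs(p_hat - p)))


def metric_pct_bias(p_hat, p) -> float:
    """100 · Σ(p̂_i − p_i) / Σ p_j; NaN (with warning) when Σp = 0."""
    p_hat, p = _check_lengths(p_hat, p)
    denom = float(np.sum(p))
    if denom == 0:
        warnings.warn("sum of observed values is zero: percentage bias undefined",
                      RuntimeWarning, stacklevel=2)
        return float("nan")
    return float(100.0 * np.sum(p_hat - p) / denom)


def _all_metrics(p_hat, p) -> dict:
    return {
        "rho": metric_pearson(p_hat, p),
        "rmse": metric_rmse(p_hat, p),
        "mae": metric_mae(p_hat, p),
        "pct_bias": metric_pct_bias(p_hat, p),
    }


def cross_validate(clusters: pd.DataFrame, selected_covariates: list[str],
                   priors: PriorSpec, k: int = 5,
                   config: InferenceConfig | None = None,
                   n_draws: int = 100) -> CVResult:
    """k-fold cross-validation of the full spatial model.

    Each fold's model is trained on the other k−1 folds and predicts the
    held-out clusters' prevalence (posterior mean of p at their
    locations); observed values are the held-out empirical proportions
    y/m. A fold whose fit fails or is flagged non-convergent is skipped
    with a warning and pooled metrics cover the successful folds.
    """
    cfg = config or InferenceConfig()
    n = len(clusters)
    assign = kfold_split(n, k, cfg.seed)
    cols = ("x_true", "y_true") if cfg.use_true_locations else ("x", "y")
    result = CVResult(k=k, seed=cfg.seed)
    pooled_hat, pooled_obs = [], []
    for f in range(k):
        test = clusters[assign == f]
        train = clusters[assign != f]
        try:
            fit = fit_spatial_binomial(train.reset_index(drop=True), selected_covariates,
                                       priors, cfg)
        except Exception as err:  # noqa: BLE001 - a failed fold must not kill the CV
            warnings.warn(f"fold {f} failed to fit: {err}", RuntimeWarning, stacklevel=2)
            result.per_fold.append({"fold": f, "n_test": int(len(test)), "failed": True})
            continue
        X_test = np.column_stack(
            [np.ones(len(test))] + [test[c].to_numpy(float) for c in selected_covariates])
        locs_test = test[list(cols)].to_numpy(float)
        pred = predict_at_points(fit, X_test, locs_test, n_draws=n_draws, seed=cfg.seed + f)
        obs = test["y_events"].to_numpy(float) / test["m"].to_numpy(float)
        entry = {"fold": f, "n_test": int(len(test)), "failed": False,
                 **_all_metrics(pred["mean"], obs)}
        result.per_fold.append(entry)
        pooled_hat.append(pred["mean"])
        pooled_obs.append(obs)
    if pooled_hat:
        ph = np.concatenate(pooled_hat)
        po = np.concatenate(pooled_obs)
        result.pooled = {"n_test": int(len(po)), **_all_metrics(ph, po)}
    else:
        warnings.warn("no fold succeeded; pooled metrics unavailable", RuntimeWarning,
                      stacklevel=2)
    return result
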