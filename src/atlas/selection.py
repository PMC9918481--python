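"""Two-stage covariate selection for binomial cluster data.

Stage one screens for multicollinearity: pairs of covariates with
|Pearson r| > 0.8 are flagged, each flagged covariate is fitted alone in a
binomial GLM and the higher-BIC member of every pair is dropped, then
variance inflation factors are computed on the survivors and covariates
with VIF > 4 are removed worst-first. Stage two runs a backward stepwise
search under BIC: at each step the single removal that lowers BIC most is
adopted, stopping when no removal lowers it.

GLM fits are maximum likelihood (IRLS) via statsmodels; everything else
(BIC bookkeeping, pair resolution, VIF iteration, stepwise loop) is
implemented here. The BIC sample size is the number of clusters — the
modelled observational units — not the number of Bernoulli trials.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

_MAX_ABS_COEF = 15.0  # logit-scale coefficients beyond this signal separation


@dataclass
class GlmFit:
    """A fitted binomial GLM: coefficients, log-likelihood, bookkeeping."""

    coefficients: np.ndarray
    log_likelihood: float
    n_obs: int
    n_params: int
    converged: bool

    def __post_init__(self) -> None:
        if len(self.coefficients) != self.n_params:
            raise ValueError("n_params must equal the coefficient count")


@dataclass
class SelectionTrace:
    """Audit trail of the two-stage covariate selection."""

    flagged_pairs: list[tuple[int, int, float]] = field(default_factory=list)
    dropped_by_bic: list[int] = field(default_factory=list)
    dropped_by_vif: list[tuple[int, float]] = field(default_factory=list)
    stepwise_path: list[tuple[int, float, float]] = field(default_factory=list)
    final_set: list[int] = field(default_factory=list)

    def validate(self) -> None:
        dropped = set(self.dropped_by_bic) | {i for i, _ in self.dropped_by_vif}
        dropped |= {i for i, _, _ in self.stepwise_path}
        if set(self.final_set) & dropped:
            raise ValueError("final_set overlaps dropped covariates")
        for _, before, after in self.stepwise_path:
            if not after < before:
                raise ValueError("stepwise BIC path must be strictly decreasing")


def pearson_matrix(X: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the covariate columns.

    Raises on constant columns (correlation undefined), naming them.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D array with at least 2 observations")
    sd = X.std(axis=0)
    const = np.flatnonzero(sd == 0)
    if const.size:
        raise ValueError(f"constant column(s) {const.tolist()}: correlation undefined")
    R = np.corrcoef(X, rowvar=False)
    return np.atleast_2d(R)


def flag_collinear_pairs(R: np.ndarray, threshold: float = 0.8) -> list[tuple[int, int, float]]:
    """Pairs (i < j) with |r| above the threshold.

    Absolute correlation is used: strong negative collinearity is as
    harmful as positive.
    """
    R = np.asarray(R, float)
    k = R.shape[0]
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            if abs(R[i, j]) > threshold:
                out.append((i, j, float(R[i, j])))
    return out


def fit_binomial_glm(X: np.ndarray, y: np.ndarray, m: np.ndarray) -> GlmFit:
    """Maximum-likelihood binomial GLM (logit link) via IRLS.

    ``X`` must already contain the intercept column. Separation or
    non-convergence is reported through ``converged=False`` with a
    warning, never silently.
    """
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float)
    m = np.broadcast_to(np.asarray(m, float), y.shape)
    if np.any(y < 0) or np.any(y > m):
        raise ValueError("need 0 <= y <= m elementwise")
    endog = np.column_stack([y, m - y])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels separation warnings handled below
        res = sm.GLM(endog, X, family=sm.families.Binomial()).fit(maxiter=100)
    coefs = np.asarray(res.params, float)
    converged = bool(getattr(res, "converged", True))
    if not np.all(np.isfinite(coefs)) or np.max(np.abs(coefs)) > _MAX_ABS_COEF:
        converged = False
    if not converged:
        warnings.warn("binomial GLM did not converge (possible separation)", RuntimeWarning,
                      stacklevel=2)
    return GlmFit(coefficients=coefs, log_likelihood=float(res.llf),
                  n_obs=X.shape[0], n_params=X.shape[1], converged=converged)


def bic(fit: GlmFit) -> float:
    """Bayesian information criterion −2·logL + p·ln(n) of a converged fit.

    ``n`` is the number of clusters (observational units).
    """
    if not fit.converged:
        raise ValueError("BIC requested for an unconverged fit")
    return -2.0 * fit.log_likelihood + fit.n_params * np.log(fit.n_obs)


def _with_intercept(X: np.ndarray, cols: list[int]) -> np.ndarray:
    return np.column_stack([np.ones(X.shape[0])] + [X[:, c] for c in cols])


def _single_covariate_bic(X, y, m, j) -> float:
    fit = fit_binomial_glm(_with_intercept(X, [j]), y, m)
    return bic(fit)


def resolve_collinear(X: np.ndarray, y: np.ndarray, m: np.ndarray,
                      flagged_pairs: list[tuple[int, int, float]],
                      trace: SelectionTrace | None = None) -> list[int]:
    """Resolve flagged collinear pairs by single-covariate BIC.

    Each flagged covariate is fitted alone (intercept + covariate); within
    every pair the lower-BIC member is retained and the other omitted. A
    covariate omitted in any pair stays omitted. Ties retain the lower
    column index (with a warning). Returns retained column indices over
    all of ``X``'s columns.
    """
    X = np.asarray(X, float)
    k = X.shape[1]
    omitted: set[int] = set()
    flagged_ids = sorted({i for i, _, _ in flagged_pairs} | {j for _, j, _ in flagged_pairs})
    bics = {j: _single_covariate_bic(X, y, m, j) for j in flagged_ids}
    for i, j, _r in flagged_pairs:
        if bics[i] < bics[j]:
            omitted.add(j)
        elif bics[j] < bics[i]:
            omitted.add(i)
        else:
            warnings.warn(f"BIC tie between covariates {i} and {j}; retaining {min(i, j)}",
                          RuntimeWarning, stacklevel=2)
            omitted.add(max(i, j))
    if trace is not None:
        trace.flagged_pairs = list(flagged_pairs)
        trace.dropped_by_bic = sorted(omitted)
    return [c for c in range(k) if c not in omitted]


def _vifs(X: np.ndarray) -> np.ndarray:
    """VIF_j = 1/(1−R²_j) from OLS of column j on the remaining columns (+ intercept)."""
    n, k = X.shape
    out = np.empty(k)
    for j in range(k):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        target = X[:, j]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((target - target.mean()) ** 2).sum())
        if ss_tot == 0:
            out[j] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[j] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return out


def vif_filter(X: np.ndarray, threshold: float = 4.0,
               trace: SelectionTrace | None = None) -> list[int]:
    """Iteratively drop the worst-VIF covariate while any VIF exceeds the threshold.

    Perfectly collinear covariates (infinite VIF) are removed first and
    logged. Returns retained column indices.
    """
    X = np.asarray(X, float)
    cols = list(range(X.shape[1]))
    dropped: list[tuple[int, float]] = []
    while len(cols) >= 2:
        v = _vifs(X[:, cols])
        worst = int(np.argmax(v))
        if v[worst] > threshold:
            dropped.append((cols[worst], float(v[worst])))
            del cols[worst]
        else:
            break
    if trace is not None:
        trace.dropped_by_vif = dropped
    return cols


def backward_select(X: np.ndarray, y: np.ndarray, m: np.ndarray,
                    trace: SelectionTrace | None = None) -> SelectionTrace:
    """Backward stepwise covariate selection under BIC.

    Starts from the model with all columns of ``X`` (plus intercept); at
    each iteration every single-covariate removal is tried and the lowest
    resulting BIC is adopted if it improves on the current BIC; stops when
    no removal lowers BIC. The intercept is never removed. Returns the
    :class:`SelectionTrace` with ``final_set`` and the removal path.
    """
    X = np.asarray(X, float)
    tr = trace if trace is not None else SelectionTrace()
    current = list(range(X.shape[1])) if X.size else []
    cur_bic = bic(fit_binomial_glm(_with_intercept(X, current), y, m))
    while current:
        candidates = []
        for drop in current:
            subset = [c for c in current if c != drop]
            cols = _with_intercept(X, subset)
            fit = fit_binomial_glm(cols, y, m)
            if not fit.converged:
                continue
            candidates.append((bic(fit), drop))
        if not candidates:
            break
        best_bic, best_drop = min(candidates)
        if best_bic < cur_bic:
            tr.stepwise_path.append((best_drop, cur_bic, best_bic))
            current = [c for c in current if c != best_drop]
            cur_bic = best_bic
        else:
            break
    tr.final_set = current
    tr.validate()
    return tr


def select_covariates(X: np.ndarray, y: np.ndarray, m: np.ndarray,
                      r_threshold: float = 0.8, vif_threshold: float = 4.0) -> SelectionTrace:
    """Run the full two-stage pipeline and return its trace.

    ``final_set`` indexes columns of the original ``X``.
    """
    tr = SelectionTrace()
    R = pearson_matrix(X)
    pairs = flag_collinear_pairs(R, r_threshold)
    keep = resolve_collinear(X, y, m, pairs, trace=tr)
    sub_tr = SelectionTrace()
    keep_v = vif_filter(X[:, keep], vif_threshold, trace=sub_tr)
    tr.dropped_by_vif = [(keep[c], v) for c, v in sub_tr.dropped_by_vif]
    kept = [keep[c] for c in keep_v]
    step = backward_select(X[:, kept], y, m)
    tr.stepwise_path = [(kept[c], b0, b1) for c, b0, b1 in step.stepwise_path]
    tr.final_set = [kept[c] for c in step.final_set]
    tr.validate()
    return tr
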