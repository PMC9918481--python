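"""Posterior prediction surfaces at 5 km resolution.

For every retained posterior draw (β, σ²_ω, φ, σ²_ε, u) the combined
random effect at new locations is simulated from its exact conditional
multivariate normal given the data-site values — kriging with a nugget:
the observed u = ω + ε has covariance K = Σ_ω + σ²_ε I at the data sites,
and the smooth field at new sites s* has

    E[ω* | u]   = C K⁻¹ u,         C = σ²_ω exp(−φ D(s*, s))
    Cov[ω* | u] = Σ** − C K⁻¹ Cᵀ

Cell-level prevalence for the draw is logit⁻¹(x*'β + ω*); the per-cell
mean and standard deviation over draws form the prediction and
uncertainty surfaces. The nugget is excluded by default (the surface
maps the stable prevalence field, not cluster-level noise);
``include_nugget=True`` adds σ²_ε to the conditional variance.

Joint conditional simulation is done in row blocks to bound memory; the
per-cell posterior mean and SD are unaffected by the blocking (only
cross-block correlations of individual simulated fields are dropped).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.special import expit

from .grids import CovariateGrid, GridTransform
from .model import ModelFit


@dataclass
class PredictionSurface:
    """Paired posterior mean and SD prevalence grids."""

    mean_grid: CovariateGrid
    sd_grid: CovariateGrid
    resolution_km: float = 5.0

    def __post_init__(self) -> None:
        if self.mean_grid.shape != self.sd_grid.shape:
            raise ValueError("mean and sd grids must share shape")
        if self.mean_grid.transform != self.sd_grid.transform:
            raise ValueError("mean and sd grids must share transform")
        mg = self.mean_grid.values
        ok = ~np.isnan(mg)
        if ok.any() and (np.nanmin(mg) < 0 or np.nanmax(mg) > 1):
            raise ValueError("mean prevalence outside [0,1]")
        sg = self.sd_grid.values
        if np.nanmin(sg, initial=0.0) < 0:
            raise ValueError("negative prediction SD")

    @property
    def mask(self) -> np.ndarray:
        return self.mean_grid.mask


def conditional_field_moments(locs_data: np.ndarray, u: np.ndarray, locs_new: np.ndarray,
                              sigma2_omega: float, phi: float, sigma2_eps: float,
                              jitter: float = 1e-8) -> tuple[np.ndarray, np.ndarray]:
    """Kriging moments of the smooth field ω* at new sites given u = ω + ε.

    Returns the conditional mean ``C K⁻¹ u`` and covariance
    ``Σ** − C K⁻¹ Cᵀ`` with K = Σ_ω + σ²_ε I at the data sites.
    """
    locs_data = np.asarray(locs_data, float)
    locs_new = np.asarray(locs_new, float)
    n = len(locs_data)
    K = sigma2_omega * np.exp(-phi * _pairwise(locs_data))
    K[np.diag_indices(n)] += sigma2_eps + jitter * max(sigma2_omega, 1.0)
    cK = cho_factor(K, lower=True)
    dx = locs_new[:, 0][:, None] - locs_data[:, 0][None, :]
    dy = locs_new[:, 1][:, None] - locs_data[:, 1][None, :]
    C = sigma2_omega * np.exp(-phi * np.sqrt(dx * dx + dy * dy))
    mean = C @ cho_solve(cK, np.asarray(u, float))
    half = solve_triangular(cK[0], C.T, lower=True)
    cov = sigma2_omega * np.exp(-phi * _pairwise(locs_new)) - half.T @ half
    return mean, cov


def _select_draws(n_avail: int, n_draws: int, rng: np.random.Generator) -> np.ndarray:
    if n_draws >= n_avail:
        return np.arange(n_avail)
    return np.sort(rng.choice(n_avail, size=n_draws, replace=False))


def _conditional_p_draws(fit: ModelFit, X_new: np.ndarray, locs_new: np.ndarray,
                         n_draws: int, seed: int, include_nugget: bool,
                         block_size: int = 512, jitter: float = 1e-8) -> np.ndarray:
    """Matrix (n_draws, n_new) of conditional prevalence simulations."""
    if "u" not in fit.draws or len(fit.draws["u"]) == 0:
        raise ValueError(
            "fit contains no posterior draws of the random effect; refit with draws retained")
    rng = np.random.default_rng(seed)
    locs = np.asarray(fit.locations, float)
    U = fit.draws["u"]
    B = fit.draws["beta"]
    s2w_d, phi_d, s2e_d = fit.draws["sigma2_omega"], fit.draws["phi"], fit.draws["sigma2_eps"]
    idx = _select_draws(len(U), n_draws, rng)
    n_new = len(locs_new)
    dx = locs_new[:, 0][:, None] - locs[:, 0][None, :]
    dy = locs_new[:, 1][:, None] - locs[:, 1][None, :]
    D_cross = np.sqrt(dx * dx + dy * dy)
    out = np.empty((len(idx), n_new))
    n = len(locs)
    D_data = _pairwise(locs)
    for row, j in enumerate(idx):
        s2w, phi, s2e = float(s2w_d[j]), float(phi_d[j]), float(s2e_d[j])
        K = s2w * np.exp(-phi * D_data)
        K[np.diag_indices(n)] += s2e + jitter * max(s2w, 1.0)
        cK = cho_factor(K, lower=True)
        C = s2w * np.exp(-phi * D_cross)
        alpha = cho_solve(cK, U[j])
        mean_new = C @ alpha
        omega_star = np.empty(n_new)
        for start in range(0, n_new, block_size):
            sl = slice(start, min(start + block_size, n_new))
            Cb = C[sl]
            Db = _pairwise(locs_new[sl])
            cov_b = s2w * np.exp(-phi * Db)
            half = solve_triangular(cK[0], Cb.T, lower=True)
            cov_b -= half.T @ half
            if include_nugget:
                cov_b[np.diag_indices(cov_b.shape[0])] += s2e
            cov_b[np.diag_indices(cov_b.shape[0])] += jitter * max(s2w, 1.0)
            Lb = np.linalg.cholesky(cov_b)
            omega_star[sl] = mean_new[sl] + Lb @ rng.standard_normal(cov_b.shape[0])
        out[row] = expit(X_new @ B[j] + omega_star)
    return out


def _pairwise(pts: np.ndarray) -> np.ndarray:
    dx = pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = pts[:, 1][:, None] - pts[:, 1][None, :]
    return np.sqrt(dx * dx + dy * dy)


def predict_at_points(fit: ModelFit, X_new: np.ndarray, locs_new: np.ndarray,
                      n_draws: int = 200, seed: int = 0,
                      include_nugget: bool = False) -> dict[str, np.ndarray]:
    """Posterior mean and SD of prevalence at arbitrary point locations."""
    P = _conditional_p_draws(fit, np.asarray(X_new, float), np.asarray(locs_new, float),
                             n_draws, seed, include_nugget)
    sd = P.std(axis=0, ddof=1) if P.shape[0] > 1 else np.zeros(P.shape[1])
    return {"mean": P.mean(axis=0), "sd": sd}


def predict_surface(fit: ModelFit, grids_5km: list[CovariateGrid],
                    n_draws: int = 200, seed: int = 0,
                    include_nugget: bool = False, block_size: int = 512,
                    ) -> PredictionSurface:
    """Posterior mean and SD prevalence surfaces on the covariate grids.

    ``grids_5km`` must be the selected covariates, in the same order as
    ``fit.covariate_names[1:]``, on a shared geotransform. Cells where any
    covariate is missing are masked and never acquire values.
    """
    expected = fit.covariate_names[1:]
    if len(grids_5km) != len(expected):
        raise ValueError(f"fit uses covariates {expected} but {len(grids_5km)} grids given")
    t = grids_5km[0].transform
    shape = grids_5km[0].shape
    for g in grids_5km[1:]:
        if g.shape != shape or g.transform != t:
            raise ValueError("covariate grids must share shape and transform")
    stack = np.stack([g.values for g in grids_5km]) if grids_5km else \
        np.empty((0,) + shape)
    mask = np.zeros(shape, bool)
    for g in grids_5km:
        mask |= g.mask
    ok = ~mask
    xs, ys = t.cell_centers(shape)
    cx, cy = np.meshgrid(xs, ys)
    locs_new = np.column_stack([cx[ok], cy[ok]])
    X_new = np.column_stack([np.ones(ok.sum())] + [stack[j][ok] for j in range(len(grids_5km))])
    P = _conditional_p_draws(fit, X_new, locs_new, n_draws, seed, include_nugget,
                             block_size=block_size)
    mean = np.full(shape, np.nan)
    sd = np.full(shape, np.nan)
    mean[ok] = P.mean(axis=0)
    sd[ok] = P.std(axis=0, ddof=1) if P.shape[0] > 1 else 0.0
    return PredictionSurface(
        mean_grid=CovariateGrid(mean, t, name="prediction_mean"),
        sd_grid=CovariateGrid(sd, t, name="prediction_sd"),
        resolution_km=t.cell,
    )
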