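"""Synthetic study generation.

Emulates the inputs of a DHS-style geolocated cluster survey:

* primary sampling units (clusters) with an urban/rural stratum, placed
  uniformly over the study extent (optionally clumped around parent
  points, a Thomas-process flavour of settlement clustering);
* the DHS confidentiality displacement of cluster GPS coordinates —
  urban clusters moved up to 2 km, rural up to 5 km, with a randomly
  chosen 1% of rural clusters eligible for up to 10 km;
* smooth gridded covariates as standardized Gaussian random fields at
  1 km resolution;
* binomial outcomes drawn from the logit-linked spatial model
  ``y_i ~ Binomial(m, p_i)``, ``logit(p_i) = x_i'β + ω_i + ε_i`` with
  ``ω ~ N(0, σ²_ω exp(−φD))`` on the TRUE locations and iid nugget
  ``ε_i ~ N(0, σ²_ε)``. The default 22 trials per cluster mirrors the
  survey's households-per-cluster count.

Clusters are carried as a :class:`pandas.DataFrame` with columns
``cluster_id, x_true, y_true, x, y, urban, far_rural, m, y_events`` plus
``cov_*`` covariate columns; :class:`ClusterRecord` is the corresponding
single-row record type.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .domain import StudyDomain
from .grids import CovariateGrid, GridTransform, extract_at_points


@dataclass(frozen=True)
class ClusterRecord:
    """One surveyed primary sampling unit."""

    cluster_id: int
    true_location: tuple[float, float]
    reported_location: tuple[float, float] | None
    urban: bool
    m: int = 0
    y: int = 0
    x_cov: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        if not (0 <= self.y <= max(self.m, 0)):
            raise ValueError(f"need 0 <= y <= m, got y={self.y}, m={self.m}")


@dataclass(frozen=True)
class SimulationTruth:
    """Known generative parameters for a synthetic study.

    ``beta`` includes the intercept; ``range_km`` is tied to the decay
    ``phi`` by ``range = 3/phi`` (the distance at which the exponential
    correlation drops to exp(−3) ≈ 0.05).
    """

    beta: tuple[float, ...]
    sigma2_omega: float
    phi: float
    sigma2_eps: float
    seed: int

    def __post_init__(self) -> None:
        if self.sigma2_omega < 0:
            # zero is allowed so degenerate no-spatial-effect studies can be simulated
            raise ValueError("sigma2_omega must be >= 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")
        if self.sigma2_eps < 0:
            raise ValueError("sigma2_eps must be >= 0")

    @property
    def range_km(self) -> float:
        return 3.0 / self.phi

    @classmethod
    def from_range(cls, beta, sigma2_omega, range_km, sigma2_eps, seed) -> "SimulationTruth":
        return cls(tuple(beta), sigma2_omega, 3.0 / range_km, sigma2_eps, seed)


def sample_clusters(domain: StudyDomain, n: int, urban_fraction: float, seed: int,
                    clumping: float = 0.0) -> pd.DataFrame:
    """Place ``n`` survey clusters in the domain.

    Each cluster is independently urban with probability ``urban_fraction``.
    With ``clumping = 0`` locations are uniform over the extent; with
    ``clumping > 0`` that fraction of clusters is instead scattered
    (Gaussian, sd = 3% of extent width) around ~n/25 uniformly placed
    parent points, mimicking settlement clustering. Deterministic given
    ``seed``.
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= urban_fraction <= 1.0:
        raise ValueError(f"urban_fraction must be in [0,1], got {urban_fraction}")
    if not domain.districts and domain.area <= 0:
        raise RuntimeError("empty study domain")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = domain.extent
    xs = rng.uniform(xmin, xmax, n)
    ys = rng.uniform(ymin, ymax, n)
    if clumping > 0:
        n_clump = int(round(clumping * n))
        n_par = max(1, n // 25)
        px = rng.uniform(xmin, xmax, n_par)
        py = rng.uniform(ymin, ymax, n_par)
        sd = 0.03 * domain.width
        which = rng.integers(0, n_par, n_clump)
        cx = np.clip(px[which] + rng.normal(0, sd, n_clump), xmin, xmax)
        cy = np.clip(py[which] + rng.normal(0, sd, n_clump), ymin, ymax)
        xs[:n_clump], ys[:n_clump] = cx, cy
    urban = rng.random(n) < urban_fraction
    return pd.DataFrame({
        "cluster_id": np.arange(n, dtype=int),
        "x_true": xs, "y_true": ys,
        "x": np.nan, "y": np.nan,
        "urban": urban,
        "far_rural": False,
        "m": 0, "y_events": 0,
    })


def displace_coordinates(clusters: pd.DataFrame, domain: StudyDomain, seed: int,
                         max_urban_km: float = 2.0, max_rural_km: float = 5.0,
                         far_rural_km: float = 10.0, far_rural_frac: float = 0.01,
                         ) -> pd.DataFrame:
    """Apply DHS-style confidentiality displacement to cluster coordinates.

    Urban clusters move at most ``max_urban_km`` (2 km); rural at most
    ``max_rural_km`` (5 km) except a randomly chosen ``⌊far_rural_frac ·
    n_rural⌋`` subset eligible for up to ``far_rural_km`` (10 km). The
    displacement has a uniform angle and a uniform distance on [0, cap];
    a displaced point falling outside the extent is redrawn (not clipped)
    so the distance distribution is preserved. Deterministic given ``seed``.

    Returns a copy with ``x, y`` (reported location) and ``far_rural`` set.
    """
    if clusters[["x_true", "y_true"]].isna().any().any():
        raise ValueError("true locations must be set before displacement")
    rng = np.random.default_rng(seed)
    out = clusters.copy()
    n = len(out)
    urban = out["urban"].to_numpy(bool)
    rural_idx = np.flatnonzero(~urban)
    n_far = int(np.floor(far_rural_frac * rural_idx.size))
    far = np.zeros(n, dtype=bool)
    if n_far > 0:
        far[rng.choice(rural_idx, size=n_far, replace=False)] = True
    caps = np.where(urban, max_urban_km, np.where(far, far_rural_km, max_rural_km))

    xmin, ymin, xmax, ymax = domain.extent
    xt = out["x_true"].to_numpy(float)
    yt = out["y_true"].to_numpy(float)
    x = np.empty(n)
    y = np.empty(n)
    pending = np.arange(n)
    for _ in range(10_000):
        d = rng.uniform(0.0, caps[pending])
        a = rng.uniform(0.0, 2 * np.pi, pending.size)
        px = xt[pending] + d * np.cos(a)
        py = yt[pending] + d * np.sin(a)
        ok = (px >= xmin) & (px <= xmax) & (py >= ymin) & (py <= ymax)
        x[pending[ok]] = px[ok]
        y[pending[ok]] = py[ok]
        pending = pending[~ok]
        if pending.size == 0:
            break
    else:  # pragma: no cover - only reachable with a degenerate domain
        raise RuntimeError(f"could not redraw {pending.size} displaced points inside the extent")
    out["x"], out["y"] = x, y
    out["far_rural"] = far
    return out


def generate_covariate_grids(domain: StudyDomain, k: int, smoothness_km: float,
                             seed: int, cell_km: float = 1.0) -> list[CovariateGrid]:
    """Simulate ``k`` smooth standardized covariate grids over the extent.

    Each grid is white noise convolved with a squared-exponential
    (Gaussian) kernel of scale ``smoothness_km``, then standardized to
    sample mean 0 / SD 1. Resolution defaults to 1 km, matching the
    native resolution of typical covariate stacks. Deterministic given
    ``seed``.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    if smoothness_km <= 0:
        raise ValueError(f"smoothness_km must be > 0, got {smoothness_km}")
    if cell_km <= 0:
        raise ValueError(f"cell_km must be > 0, got {cell_km}")
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = domain.extent
    nx = int(np.ceil((xmax - xmin) / cell_km))
    ny = int(np.ceil((ymax - ymin) / cell_km))
    t = GridTransform(x0=xmin, y1=ymax, cell=cell_km)
    grids = []
    sigma_cells = smoothness_km / cell_km
    for j in range(k):
        z = rng.standard_normal((ny, nx))
        f = gaussian_filter(z, sigma=sigma_cells, mode="reflect")
        f = (f - f.mean()) / f.std()
        grids.append(CovariateGrid(values=f, transform=t, name=f"cov_{j + 1}"))
    return grids


def design_matrix(clusters: pd.DataFrame, grids: list[CovariateGrid],
                  use_true_locations: bool = False) -> np.ndarray:
    """Intercept + covariates extracted at cluster locations.

    Extracts each grid at the reported (default) or true location and
    prepends a column of ones. Also writes the ``cov_*`` columns back into
    a copy of ``clusters`` via :func:`attach_covariates` when needed — this
    helper returns only the matrix.
    """
    cols = ("x_true", "y_true") if use_true_locations else ("x", "y")
    pts = clusters[list(cols)].to_numpy(float)
    if np.isnan(pts).any():
        raise ValueError(f"cluster locations {cols} contain NaN — run displace_coordinates first")
    xc = extract_at_points(grids, pts)
    return np.column_stack([np.ones(len(clusters)), xc])


def attach_covariates(clusters: pd.DataFrame, grids: list[CovariateGrid],
                      use_true_locations: bool = False) -> pd.DataFrame:
    """Return a copy of ``clusters`` with ``cov_*`` columns extracted from grids."""
    X = design_matrix(clusters, grids, use_true_locations=use_true_locations)
    out = clusters.copy()
    for j, g in enumerate(grids):
        out[g.name if g.name.startswith("cov_") else f"cov_{j + 1}"] = X[:, j + 1]
    return out


def simulate_study(domain: StudyDomain, n_clusters: int, truth: SimulationTruth,
                   n_covariates: int | None = None, urban_fraction: float = 0.3,
                   smoothness_km: float = 25.0, m_per_cluster: int = 22,
                   seed: int | None = None,
                   ) -> tuple[pd.DataFrame, list[CovariateGrid]]:
    """Generate a complete synthetic study: clusters, displacement, grids, outcomes.

    ``n_covariates`` defaults to ``len(truth.beta) - 1``. The sub-stage
    seeds are derived from ``seed`` (default ``truth.seed``); outcomes use
    ``truth.seed`` itself. Returns the finished cluster table (covariates
    extracted at reported locations, outcomes drawn at true locations) and
    the 1 km covariate grids.
    """
    k = n_covariates if n_covariates is not None else len(truth.beta) - 1
    base = truth.seed if seed is None else seed
    cl = sample_clusters(domain, n_clusters, urban_fraction, seed=base + 1)
    cl = displace_coordinates(cl, domain, seed=base + 2)
    if k > 0:
        grids = generate_covariate_grids(domain, k, smoothness_km=smoothness_km,
                                         seed=base + 3)
        cl = attach_covariates(cl, grids)
        X = design_matrix(cl, grids)
    else:
        grids = []
        X = np.ones((n_clusters, 1))
    cl = simulate_outcomes(cl, X, truth, m_per_cluster=m_per_cluster)
    return cl, grids


def simulate_outcomes(clusters: pd.DataFrame, X: np.ndarray, truth: SimulationTruth,
                      m_per_cluster: int = 22) -> pd.DataFrame:
    """Draw binomial outcomes from the generative spatial model.

    The spatial effect ω is drawn as one multivariate normal with
    covariance ``σ²_ω exp(−φD)`` built on the TRUE cluster locations
    (displacement corrupts the reported ones); the nugget ε is iid normal.
    ``p_i = logit⁻¹(x_i'β + ω_i + ε_i)`` and ``y_i ~ Binomial(m, p_i)``.
    Deterministic given ``truth.seed``.
    """
    X = np.asarray(X, float)
    n = len(clusters)
    if X.shape[0] != n:
        raise ValueError(f"X has {X.shape[0]} rows for {n} clusters")
    if X.shape[1] != len(truth.beta):
        raise ValueError(f"X has {X.shape[1]} columns but beta has {len(truth.beta)}")
    rng = np.random.default_rng(truth.seed)
    pts = clusters[["x_true", "y_true"]].to_numpy(float)
    dx = pts[:, 0][:, None] - pts[:, 0][None, :]
    dy = pts[:, 1][:, None] - pts[:, 1][None, :]
    D = np.sqrt(dx * dx + dy * dy)
    if truth.sigma2_omega > 0:
        S = truth.sigma2_omega * np.exp(-truth.phi * D)
        S[np.diag_indices(n)] += 1e-8 * truth.sigma2_omega
        try:
            L = np.linalg.cholesky(S)
        except np.linalg.LinAlgError as err:  # pragma: no cover
            raise np.linalg.LinAlgError(
                f"spatial covariance not positive definite after jitter "
                f"(n={n}, sigma2_omega={truth.sigma2_omega}, phi={truth.phi}): {err}"
            ) from err
        omega = L @ rng.standard_normal(n)
    else:
        omega = np.zeros(n)
    eps = rng.normal(0.0, np.sqrt(truth.sigma2_eps), n) if truth.sigma2_eps > 0 else np.zeros(n)
    p = expit(X @ np.asarray(truth.beta) + omega + eps)
    out = clusters.copy()
    out["m"] = int(m_per_cluster)
    out["y_events"] = rng.binomial(m_per_cluster, p)
    out["p_true"] = p
    return out
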