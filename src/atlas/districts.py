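"""District-level estimators for rare-event and model-based indicators.

Confidence-interval machinery used when an indicator is too sparse for
cluster-level geostatistical mapping and is instead reported per
district:

* Wilson score intervals for proportions (e.g. teenage pregnancy);
* Byar's cube-root approximation to Poisson rate limits for event counts
  above 5, with exact Poisson (gamma-quantile) limits at or below 5;
* exposure-offset Poisson / binomial GLMs for modelled fertility and
  mortality rates, with delta-method intervals built on the link scale
  and transformed back (so rate intervals stay non-negative);
* a synthetic-cohort life table combining the 12–23, 24–35, 36–47 and
  48–59 month death probabilities into the standard 1–4 year (4q1)
  child-mortality probability per 1000;
* the relative CI width (upper − lower)/estimate used as the published
  uncertainty metric.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass
class DistrictEstimate:
    """A district's point estimate with its confidence interval."""

    district_id: int | str
    estimate: float
    ci_low: float
    ci_high: float
    method: str
    scale: float = 1.0  # 1 = per unit, 1000 = per 1000
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.estimate > 0 and not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"CI ({self.ci_low}, {self.ci_high}) does not contain estimate {self.estimate}")

    @property
    def rel_width(self) -> float:
        return relative_ci_width(self)


@dataclass(frozen=True)
class LifeTableSegments:
    """Death probabilities for the four age segments (months) of the 1–4y window."""

    q_12_23: float
    q_24_35: float
    q_36_47: float
    q_48_59: float

    def __post_init__(self) -> None:
        for name, q in self.as_dict().items():
            if not 0.0 <= q <= 1.0:
                raise ValueError(f"{name} = {q} outside [0, 1]")

    def as_dict(self) -> dict[str, float]:
        return {"q_12_23": self.q_12_23, "q_24_35": self.q_24_35,
                "q_36_47": self.q_36_47, "q_48_59": self.q_48_59}


def _z(level: float) -> float:
    if not 0 < level < 1:
        raise ValueError(f"level must be in (0,1), got {level}")
    return float(stats.norm.ppf(0.5 + level / 2.0))


def wilson_ci(y: int, m: int, level: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Exactly 0 (resp. 1) at the boundary counts y=0 (y=m); nonzero width
    everywhere.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if not 0 <= y <= m:
        raise ValueError(f"need 0 <= y <= m, got y={y}, m={m}")
    lo, hi = proportion_confint(y, m, alpha=1.0 - level, method="wilson")
    lo = 0.0 if y == 0 else float(lo)
    hi = 1.0 if y == m else float(hi)
    return lo, hi


def byar_ci(count: float, denominator: float, level: float = 0.95) -> tuple[float, float]:
    """Byar's cube-root approximation to the Poisson rate confidence interval.

    Intended for counts above 5 (see :func:`route_rate_ci` for the
    routing rule); accurate to well under a percent for moderate counts.
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if count <= 0:
        raise ValueError("Byar's approximation needs a positive count")
    z = _z(level)
    c = float(count)
    lo = c * (1.0 - 1.0 / (9.0 * c) - z / (3.0 * np.sqrt(c))) ** 3
    cp = c + 1.0
    hi = cp * (1.0 - 1.0 / (9.0 * cp) + z / (3.0 * np.sqrt(cp))) ** 3
    return lo / denominator, hi / denominator


def exact_poisson_ci(count: int, denominator: float, level: float = 0.95) -> tuple[float, float]:
    """Exact Poisson rate limits via the gamma/chi-square tail relation.

    The limits satisfy P(X >= count | λ=lo·denom) = α/2 and
    P(X <= count | λ=hi·denom) = α/2 (lo = 0 when count = 0).
    """
    if denominator <= 0:
        raise ValueError("denominator must be > 0")
    if count < 0:
        raise ValueError("count must be >= 0")
    alpha = 1.0 - level
    lo = 0.0 if count == 0 else float(stats.gamma.ppf(alpha / 2.0, count))
    hi = float(stats.gamma.ppf(1.0 - alpha / 2.0, count + 1))
    return lo / denominator, hi / denominator


def route_rate_ci(count: int, denominator: float, level: float = 0.95,
                  district_id: int | str = 0, scale: float = 1.0) -> DistrictEstimate:
    """Route a rate CI to Byar (count > 5) or exact Poisson (count <= 5).

    The boundary count of exactly 5 goes to the exact method — the
    conservative choice for the case the above-5 / below-5 rule leaves
    open.
    """
    if count > 5:
        lo, hi = byar_ci(count, denominator, level)
        method = "byar"
    else:
        lo, hi = exact_poisson_ci(count, denominator, level)
        method = "exact_poisson"
    est = count / denominator
    return DistrictEstimate(district_id=district_id, estimate=est * scale,
                            ci_low=lo * scale, ci_high=hi * scale,
                            method=method, scale=scale, level=level)


@dataclass
class RateGlmResult:
    """Saturated per-group rate GLM: link-scale estimates and their vcov."""

    groups: list
    params: np.ndarray        # link scale (log rate or logit proportion)
    vcov: np.ndarray
    family: str
    excluded: list

    def rates(self) -> np.ndarray:
        """Estimates on the natural scale."""
        return np.exp(self.params) if self.family == "poisson" else _expit(self.params)


def _expit(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, float)))


def fit_rate_glm(occurrences, exposure, family: str, groups) -> RateGlmResult:
    """Per-group rates from an exposure-offset Poisson or binomial GLM.

    ``family='poisson'`` fits a log-link GLM with offset log(exposure) —
    for fertility-style rates; ``family='binomial'`` fits a logit-link GLM
    with trials = exposure — for mortality-style proportions. The design
    is saturated (one indicator per group), so the estimates reproduce
    the crude rates; the value added is the variance-covariance matrix
    that the delta-method interval consumes. Groups with zero exposure
    are excluded with a warning.
    """
    if family not in ("poisson", "binomial"):
        raise ValueError(f"family must be 'poisson' or 'binomial', got {family!r}")
    occ = np.asarray(occurrences, float)
    exp_ = np.asarray(exposure, float)
    groups = list(groups)
    if np.any(occ < 0):
        raise ValueError("occurrences must be non-negative")
    keep = exp_ > 0
    excluded = [g for g, k in zip(groups, keep) if not k]
    if excluded:
        warnings.warn(f"excluding zero-exposure group(s): {excluded}", RuntimeWarning,
                      stacklevel=2)
    occ, exp_ = occ[keep], exp_[keep]
    kept_groups = [g for g, k in zip(groups, keep) if k]
    uniq = list(dict.fromkeys(kept_groups))
    Xd = np.column_stack([(np.asarray(kept_groups, object) == g).astype(float) for g in uniq])
    with warnings.catch_warnings():
        # saturated per-group designs trip statsmodels' separation heuristic
        warnings.simplefilter("ignore")
        if family == "poisson":
            res = sm.GLM(occ, Xd, family=sm.families.Poisson(),
                         offset=np.log(exp_)).fit(maxiter=200)
        else:
            if np.any(occ > exp_):
                raise ValueError("binomial family needs occurrences <= exposure (trials)")
            res = sm.GLM(np.column_stack([occ, exp_ - occ]), Xd,
                         family=sm.families.Binomial()).fit(maxiter=200)
    return RateGlmResult(groups=uniq, params=np.asarray(res.params, float),
                         vcov=np.asarray(res.cov_params(), float), family=family,
                         excluded=excluded)


_TRANSFORMS = {
    "identity": (lambda t: t, lambda t: np.ones_like(np.asarray(t, float))),
    "exp": (np.exp, np.exp),
    "expit": (_expit, lambda t: _expit(t) * (1 - _expit(t))),
}


def delta_method_ci(estimates, vcov, transform: str = "identity",
                    level: float = 0.95) -> dict[str, np.ndarray]:
    """Delta-method standard errors and intervals for transformed estimates.

    ``estimates`` live on the link scale with covariance ``vcov``; the
    natural-scale SE is |g'(θ)|·SE(θ) and the interval is the symmetric
    link-scale interval mapped through the (monotone) transform, which
    keeps rate intervals inside the natural parameter space.
    """
    if transform not in _TRANSFORMS:
        raise ValueError(f"unknown transform {transform!r}")
    g, dg = _TRANSFORMS[transform]
    est = np.atleast_1d(np.asarray(estimates, float))
    V = np.atleast_2d(np.asarray(vcov, float))
    var = np.diag(V).copy()
    if np.any(var < -1e-12):
        raise ValueError("vcov has negative diagonal entries (not PSD)")
    var = np.clip(var, 0.0, None)
    eigmin = float(np.linalg.eigvalsh((V + V.T) / 2.0).min()) if V.size > 1 else var[0]
    if eigmin < -1e-8 * max(1.0, float(np.abs(V).max())):
        raise ValueError("vcov is not positive semi-definite")
    z = _z(level)
    se_link = np.sqrt(var)
    lo = g(est - z * se_link)
    hi = g(est + z * se_link)
    se_nat = np.abs(dg(est)) * se_link
    return {"estimate": g(est), "se": se_nat,
            "ci_low": np.minimum(lo, hi), "ci_high": np.maximum(lo, hi)}


def child_mortality_4q1(segments: LifeTableSegments, per: float = 1000.0) -> float:
    """Synthetic-cohort child mortality: combine age-segment probabilities.

    The probability of dying between exact ages 1 and 5 is one minus the
    product of surviving each 12-month segment:
    ``per · (1 − Π_j (1 − q_j))``.
    """
    qs = list(segments.as_dict().values())
    surv = 1.0
    for q in qs:
        surv *= 1.0 - q
    return per * (1.0 - surv)


def relative_ci_width(est: DistrictEstimate) -> float:
    """(upper − lower) / estimate; NaN (with warning) for a zero estimate."""
    if est.estimate == 0:
        warnings.warn(f"district {est.district_id}: zero estimate, relative CI width "
                      "undefined", RuntimeWarning, stacklevel=2)
        return float("nan")
    return (est.ci_high - est.ci_low) / est.estimate
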