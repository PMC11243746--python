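"""Univariable two-sample MR estimators and sensitivity statistics.

Every estimator works from per-SNV Wald ratios beta_Yj / beta_Xj with
first-order standard errors se_Yj / |beta_Xj| (a second-order option is
available).  Point estimates are causal log-odds of the outcome per SD
increase of the exposure; odds ratios are their exponentials.

Implemented: fixed-effect and multiplicative random-effect IVW, simple /
weighted / penalized-weighted median with parametric-bootstrap SEs,
MR-Egger regression with its pleiotropy intercept, Cochran's Q
heterogeneity, and the Bonferroni threshold used to declare
significance across the exposure-outcome grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .sumstats import HarmonizedSet

__all__ = [
    "RatioSet",
    "MREstimate",
    "HeterogeneityResult",
    "wald_ratios",
    "ivw",
    "median_estimators",
    "egger",
    "cochran_q",
    "bonferroni_threshold",
]

_Z95 = 1.959963984540054  # normal 97.5% quantile; summary-data MR convention


class EstimationError(ValueError):
    """Raised when an estimator's preconditions are not met."""


@dataclass
class RatioSet:
    """Per-SNV Wald ratios with inverse-variance weights."""

    rsids: list[str]
    ratio: np.ndarray
    ratio_se: np.ndarray
    excluded: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.ratio = np.asarray(self.ratio, dtype=float)
        self.ratio_se = np.asarray(self.ratio_se, dtype=float)
        if np.any(self.ratio_se <= 0):
            raise EstimationError("ratio standard errors must be positive")

    @property
    def weight(self) -> np.ndarray:
        return 1.0 / self.ratio_se**2

    def __len__(self) -> int:
        return len(self.rsids)


@dataclass
class MREstimate:
    """A causal estimate on the log-odds-per-SD scale."""

    method: str
    beta: float
    se: float
    ci_low: float
    ci_high: float
    pval: float
    n_snv: int
    egger_intercept: float | None = None
    intercept_se: float | None = None
    intercept_pval: float | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.beta))

    @property
    def or_ci(self) -> tuple[float, float]:
        return float(np.exp(self.ci_low)), float(np.exp(self.ci_high))


@dataclass
class HeterogeneityResult:
    method: str
    q_stat: float
    df: int
    pval: float


def _estimate(method: str, beta: float, se: float, n_snv: int, **kw) -> MREstimate:
    z = beta / se if se > 0 else np.inf * np.sign(beta)
    return MREstimate(
        method=method,
        beta=float(beta),
        se=float(se),
        ci_low=float(beta - _Z95 * se),
        ci_high=float(beta + _Z95 * se),
        pval=float(2 * stats.norm.sf(abs(z))),
        n_snv=n_snv,
        **kw,
    )


def wald_ratios(h: HarmonizedSet, exposure_index: int, second_order: bool = False) -> RatioSet:
    """Per-SNV causal ratios beta_Y / beta_X for one exposure.

    SNVs with beta_X = 0 are excluded (ratio undefined) and listed on
    ``RatioSet.excluded``.  The default SE is the first-order delta
    approximation se_Y / |beta_X|; ``second_order`` adds the
    beta_X-uncertainty term sqrt(se_Y^2/bx^2 + by^2 sx^2 / bx^4).
    """
    bx = h.bx[:, exposure_index]
    sx = h.sx[:, exposure_index]
    keep = bx != 0
    ratio = h.by[keep] / bx[keep]
    if second_order:
        se = np.sqrt(h.sy[keep] ** 2 / bx[keep] ** 2 + h.by[keep] ** 2 * sx[keep] ** 2 / bx[keep] ** 4)
    else:
        se = h.sy[keep] / np.abs(bx[keep])
    return RatioSet(
        rsids=[r for r, k in zip(h.rsids, keep) if k],
        ratio=ratio,
        ratio_se=se,
        excluded=[r for r, k in zip(h.rsids, keep) if not k],
    )


def ivw(r: RatioSet, mode: str = "multiplicative_random") -> MREstimate:
    """Inverse-variance-weighted estimate of the causal effect.

    The point estimate is the weighted mean of the ratios (equivalently
    weighted least squares of beta_Y on beta_X through the origin with
    weights se_Y^-2).  The fixed-effect SE is (sum w)^{-1/2}; the
    multiplicative random-effect SE inflates it by
    max(1, sqrt(Q / (J - 1))), never shrinking below the fixed SE.
    """
    if mode not in ("fixed", "multiplicative_random"):
        raise ValueError(f"unknown IVW mode {mode!r}")
    j = len(r)
    if j == 0:
        raise EstimationError("IVW requires at least one SNV")
    w = r.weight
    beta = float(np.sum(w * r.ratio) / np.sum(w))
    se_fixed = float(np.sum(w) ** -0.5)
    if j == 1:
        return _estimate("ivw_fe", beta, se_fixed, 1)
    if mode == "fixed":
        return _estimate("ivw_fe", beta, se_fixed, j)
    q = float(np.sum(w * (r.ratio - beta) ** 2))
    scale = max(1.0, np.sqrt(q / (j - 1)))
    return _estimate("ivw_mre", beta, se_fixed * scale, j)


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    """50th percentile of the weight-standardized CDF over sorted values,
    with linear interpolation (reduces to the sample median for equal
    weights)."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    s = (np.cumsum(w) - 0.5 * w) / np.sum(w)
    if s[0] >= 0.5:
        return float(v[0])
    if s[-1] <= 0.5:
        return float(v[-1])
    k = int(np.searchsorted(s, 0.5))
    return float(v[k - 1] + (v[k] - v[k - 1]) * (0.5 - s[k - 1]) / (s[k] - s[k - 1]))


def _penalized_weights(ratio: np.ndarray, weights: np.ndarray, penalty: float) -> np.ndarray:
    center = _weighted_median(ratio, weights)
    q_terms = weights * (ratio - center) ** 2
    p = stats.chi2.sf(q_terms, df=1)
    return weights * np.minimum(1.0, penalty * p)


def _median_point(ratio, weights, variant: str, penalty: float) -> float:
    if variant == "simple":
        return _weighted_median(ratio, np.ones_like(ratio))
    if variant == "weighted":
        return _weighted_median(ratio, weights)
    if variant == "penalized":
        return _weighted_median(ratio, _penalized_weights(ratio, weights, penalty))
    raise ValueError(f"unknown median variant {variant!r}")


def median_estimators(
    r: RatioSet,
    variant: str = "weighted",
    boot_reps: int = 1000,
    seed: int = 0,
    penalty: float = 20.0,
) -> MREstimate:
    """Simple, weighted or penalized-weighted median estimator.

    The penalized variant down-weights heterogeneous SNVs with
    w_j' = w_j * min(1, penalty * p_j), p_j being the upper-tail chi^2_1
    p-value of the SNV's Q contribution about the weighted median; for
    p_j >= 1/penalty (0.05 at the default 20) the penalty is inactive.
    The SE comes from a seeded parametric bootstrap resampling each
    ratio from N(ratio_j, ratio_se_j^2).
    """
    j = len(r)
    if j < 3:
        raise EstimationError(f"median estimators require >= 3 SNVs, got {j}")
    w = r.weight
    beta = _median_point(r.ratio, w, variant, penalty)
    rng = np.random.default_rng(seed)
    draws = rng.normal(loc=r.ratio, scale=r.ratio_se, size=(boot_reps, j))
    boot = np.array([_median_point(d, w, variant, penalty) for d in draws])
    se = float(np.std(boot, ddof=1))
    method = {"simple": "simple_median", "weighted": "weighted_median", "penalized": "penalized_median"}[variant]
    return _estimate(method, beta, se, j)


def egger(h: HarmonizedSet, exposure_index: int) -> MREstimate:
    """MR-Egger: weighted regression of beta_Y on beta_X with a free
    intercept, SNVs oriented so every beta_X is positive.

    The slope is the pleiotropy-adjusted causal estimate; a nonzero
    intercept indicates directional horizontal pleiotropy.  SEs are
    inflated by max(1, residual SD) — the multiplicative random-effect
    convention, floored so they never undercut the fixed-effect SEs.
    """
    bx = h.bx[:, exposure_index].copy()
    by = h.by.copy()
    keep = bx != 0
    bx, by, sy = bx[keep], by[keep], h.sy[keep]
    j = len(bx)
    if j < 3:
        raise EstimationError(f"MR-Egger requires >= 3 SNVs, got {j}")
    flip = bx < 0
    bx = np.abs(bx)
    by = np.where(flip, -by, by)
    if np.allclose(bx, bx[0]):
        raise EstimationError("all exposure effects equal after orientation: Egger design is collinear")
    w = 1.0 / sy**2
    x = np.column_stack([np.ones(j), bx])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * by)
    coef = np.linalg.solve(xtwx, xtwy)
    resid = by - x @ coef
    sigma2 = float(np.sum(w * resid**2) / (j - 2))
    cov = np.linalg.inv(xtwx) * max(1.0, sigma2)
    se_int, se_slope = np.sqrt(np.diag(cov))
    intercept_p = float(2 * stats.norm.sf(abs(coef[0] / se_int)))
    return _estimate(
        "egger",
        coef[1],
        se_slope,
        j,
        egger_intercept=float(coef[0]),
        intercept_se=float(se_int),
        intercept_pval=intercept_p,
    )


def cochran_q(r: RatioSet, center: float, method: str = "ivw") -> HeterogeneityResult:
    """Cochran's Q = sum w_j (ratio_j - center)^2 about a causal estimate.

    Degrees of freedom are J-1 for IVW and J-2 for MR-Egger (one extra
    parameter); the p-value is the upper chi^2 tail.
    """
    if method not in ("ivw", "egger"):
        raise ValueError(f"unknown heterogeneity method {method!r}")
    j = len(r)
    if j < 2:
        raise EstimationError("Cochran's Q requires >= 2 SNVs")
    q = float(np.sum(r.weight * (r.ratio - center) ** 2))
    df = j - 1 if method == "ivw" else j - 2
    return HeterogeneityResult(method=method, q_stat=q, df=df, pval=float(stats.chi2.sf(q, df)))


def bonferroni_threshold(n_exposures: int, n_outcomes: int, alpha: float = 0.05) -> float:
    """Multiple-testing threshold alpha / (exposures x outcomes).

    With 4 iron biomarkers and 3 kidney-disease outcomes at alpha 0.05
    this is 0.05/12 ~ 0.0042; p-values between the threshold and alpha
    are 'suggestive'.
    """
    if n_exposures < 1 or n_outcomes < 1:
        raise ValueError("counts must be >= 1")
    return alpha / (n_exposures * n_outcomes)
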