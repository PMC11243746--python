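"""Mixture-model MR (MRMix-style) robust to horizontal pleiotropy.

For a candidate causal effect theta, the residual SNV-outcome effects
r_j = beta_Yj - theta * beta_Xj are modelled as a zero-mean two-component
normal mixture: a *valid* component with variance
s_j^2 = se_Yj^2 + theta^2 se_Xj^2 (pure sampling noise, probability
pi0) and an *invalid* component with variance s_j^2 + sigma^2 carrying
horizontal pleiotropy.  (pi0, sigma^2) are fitted by EM at each theta on
a grid; the estimate is the theta that maximizes the fitted proportion
of valid instruments pi0.
A coarse grid pass is refined around its argmax so theta is reported at
the fine step.

Numerical notes: because the per-SNV base variances differ, the sigma^2
M-step has no closed form; it is solved by bisection on the derivative
of the expected complete-data log-likelihood, accepting the update only
when it improves that objective — a generalized EM, so the observed
log-likelihood never decreases.  The likelihood is flat in pi0 wherever
sigma^2 = 0 (the two components coincide), so each grid point is fitted
from a few deterministic starts and the best log-likelihood kept, ties
going to the larger pi0.  The boundary model "all instruments valid"
(pi0 = 1, sigma^2 = 0) is additionally evaluated in closed form at every
grid point and adopted unless the mixture beats it by more than the BIC
allowance for its two extra parameters, log(J): when residuals at some
theta are only fractionally overdispersed, the unconstrained maximizer
degenerates to pi0 ~ 0 with sigma^2 equal to the small variance excess,
which is statistically indistinguishable from the all-valid model yet
would wreck the pi0 profile that the theta search maximizes.  Exact
pi0 ties across grid points (the all-valid plateau) are resolved by
higher log-likelihood, then smaller |theta|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .sumstats import HarmonizedSet

__all__ = ["EMResult", "MixFit", "em_mixture", "mrmix_fit", "standardize_binary_outcome"]


@dataclass
class EMResult:
    pi0: float
    sigma2: float
    loglik: float
    n_iter: int
    converged: bool
    trace: np.ndarray  # log-likelihood after each iteration


@dataclass
class MixFit:
    """MRMix fit: causal effect, valid-instrument proportion, and the
    variance of invalid-instrument pleiotropy, with the profile over the
    evaluated theta grid."""

    theta: float
    pi0: float
    sigma2: float
    grid: np.ndarray
    pi0_grid: np.ndarray
    sigma2_grid: np.ndarray
    loglik_profile: np.ndarray
    converged: np.ndarray


def _log_normal(r, var):
    return -0.5 * (np.log(2 * np.pi * var) + r**2 / var)


def _loglik(r, base, pi0, sigma2):
    """Observed-data log-likelihood, vectorized over leading grid axis.

    r, base: (..., J); pi0, sigma2: (...,). Returns (...,).
    """
    eps = 1e-300
    p0 = np.clip(pi0, eps, 1.0)
    p1 = np.clip(1.0 - pi0, eps, 1.0)
    lv = _log_normal(r, base) + np.log(p0)[..., None]
    li = _log_normal(r, base + sigma2[..., None]) + np.log(p1)[..., None]
    return np.sum(logsumexp(np.stack([lv, li]), axis=0), axis=-1)


def _qfun(r, base, g1, v):
    """Expected invalid-component log-likelihood as a function of sigma^2."""
    return np.sum(g1 * _log_normal(r, base + v[..., None]), axis=-1)


def _sigma2_step(r, base, g1, sigma2, ub, n_bisect=40):
    """Improve the sigma^2 part of the complete-data objective.

    Tries the cheap weighted-moment candidate sum g1 (r^2 - base) /
    sum g1 first; where that does not improve, maximizes by bisection on
    the derivative; keeps the old value when nothing improves.  Any
    improving step preserves the generalized-EM monotonicity guarantee.
    """
    q_old = _qfun(r, base, g1, sigma2)
    gsum = np.sum(g1, axis=-1)
    moment = np.sum(g1 * (r**2 - base), axis=-1) / np.maximum(gsum, 1e-300)
    moment = np.clip(moment, 0.0, ub)
    q_mom = _qfun(r, base, g1, moment)
    out = np.where(q_mom >= q_old, moment, sigma2)
    # Bisection only where the moment proposal was rejected outright;
    # a neutral proposal means sigma^2 sits on a plateau already.
    need = q_mom < q_old - 1e-12
    if np.any(need):
        def deriv(v):
            bv = base[need] + v[..., None]
            return 0.5 * np.sum(g1[need] * (r[need] ** 2 - bv) / bv**2, axis=-1)

        lo = np.zeros(int(need.sum()))
        hi = np.full_like(lo, ub)
        d0 = deriv(lo)
        if np.any(d0 > 0):
            for _ in range(n_bisect):
                mid = 0.5 * (lo + hi)
                go_up = deriv(mid) > 0
                lo = np.where(go_up, mid, lo)
                hi = np.where(go_up, hi, mid)
        cand = np.where(d0 <= 0, 0.0, 0.5 * (lo + hi))
        better = _qfun(r[need], base[need], g1[need], cand) >= q_old[need]
        sub = out[need]
        sub = np.where(better, cand, sub)
        out[need] = sub
    return out


def _em_vectorized(r, base, pi0, sigma2, max_iter, tol, record_trace=False):
    """Run the EM on a batch: r, base (G, J); pi0, sigma2 (G,).

    Converged grid points are frozen and dropped from the working set.
    Returns (pi0, sigma2, loglik, n_iter, converged, trace); the trace is
    the full log-likelihood vector after every iteration when requested.
    """
    eps = 1e-12
    g = r.shape[0]
    ub = 10.0 * float(np.max(r**2) + np.max(base)) + 1e-9
    pi0 = np.array(pi0, dtype=float, copy=True)
    sigma2 = np.array(sigma2, dtype=float, copy=True)
    ll = _loglik(r, base, pi0, sigma2)
    converged = np.zeros(g, dtype=bool)
    active = np.arange(g)
    trace = []
    it = 0
    for it in range(1, max_iter + 1):
        ra, ba = r[active], base[active]
        p0 = np.clip(pi0[active], eps, 1 - eps)
        lv = _log_normal(ra, ba) + np.log(p0)[..., None]
        li = _log_normal(ra, ba + sigma2[active][..., None]) + np.log(1 - p0)[..., None]
        gamma = 1.0 / (1.0 + np.exp(np.clip(li - lv, -700, 700)))
        pi0[active] = np.mean(gamma, axis=-1)
        g1 = 1.0 - gamma
        sigma2[active] = np.where(
            np.sum(g1, axis=-1) > 1e-12,
            _sigma2_step(ra, ba, g1, sigma2[active], ub),
            sigma2[active],
        )
        ll_new = _loglik(ra, ba, pi0[active], sigma2[active])
        gain = ll_new - ll[active]
        ll[active] = ll_new
        if record_trace:
            trace.append(ll.copy())
        if it > 1:
            done = gain < tol
            converged[active[done]] = True
            active = active[~done]
        if len(active) == 0:
            break
    return pi0, sigma2, ll, it, converged, trace


def em_mixture(
    residuals,
    base_var,
    init: tuple[float, float] | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-8,
) -> EMResult:
    """Fit (pi0, sigma^2) of the valid/invalid mixture by EM.

    The pi0 update is the exact M-step (mean responsibility); the
    sigma^2 update maximizes the expected complete-data log-likelihood
    numerically and is only accepted when it improves it, so the
    observed log-likelihood is non-decreasing across iterations.
    Default initialization is (0.5, var(residuals)/2).
    """
    r = np.asarray(residuals, dtype=float)[None, :]
    base = np.broadcast_to(np.asarray(base_var, dtype=float), r.shape[1:])[None, :]
    if np.any(base <= 0):
        raise ValueError("base variances must be positive")
    if init is None:
        init = (0.5, max(float(np.var(r)) / 2.0, 1e-12))
    pi0 = np.array([float(init[0])])
    sigma2 = np.array([max(float(init[1]), 0.0)])
    pi0, sigma2, ll, n_iter, conv, trace = _em_vectorized(
        r, base, pi0, sigma2, max_iter, tol, record_trace=True
    )
    return EMResult(
        pi0=float(pi0[0]),
        sigma2=float(sigma2[0]),
        loglik=float(ll[0]),
        n_iter=n_iter,
        converged=bool(conv[0]),
        trace=np.array([t[0] for t in trace]),
    )


def _profile(bx, sx, by, sy, grid, max_iter, tol):
    """Fit the mixture at every theta on the grid, from several
    deterministic EM starts; per point keep the best log-likelihood,
    ties to the larger pi0.  The all-valid boundary (pi0 = 1,
    sigma^2 = 0) is kept instead unless the mixture clears the BIC
    allowance log(J) for its two extra free parameters."""
    g = len(grid)
    j = bx.shape[0]
    r = by[None, :] - grid[:, None] * bx[None, :]
    base = sy[None, :] ** 2 + grid[:, None] ** 2 * sx[None, :] ** 2
    var_r = np.maximum(np.var(r, axis=-1), 1e-12)
    starts = [
        (np.full(g, 0.5), var_r / 2.0),
        (np.full(g, 0.95), var_r / 2.0),
        (np.full(g, 0.999), var_r / 10.0),
    ]
    best = None
    for p_init, s_init in starts:
        pi0, sig2, ll, _, conv, _ = _em_vectorized(
            r, base, p_init.copy(), s_init.copy(), max_iter, tol
        )
        if best is None:
            best = [pi0, sig2, ll, conv]
        else:
            improve = (ll > best[2] + 1e-9) | (
                (np.abs(ll - best[2]) <= 1e-9) & (pi0 > best[0])
            )
            best[0] = np.where(improve, pi0, best[0])
            best[1] = np.where(improve, sig2, best[1])
            best[2] = np.where(improve, ll, best[2])
            best[3] = np.where(improve, conv, best[3])
    ll_null = np.sum(_log_normal(r, base), axis=-1)
    use_null = best[2] - ll_null <= np.log(j)
    return (
        np.where(use_null, 1.0, best[0]),
        np.where(use_null, 0.0, best[1]),
        np.where(use_null, ll_null, best[2]),
        best[3] | use_null,  # the boundary evaluation is exact
    )


def _argmax_pi0(grid, pi0s, lls, conv):
    ok = np.flatnonzero(conv)
    if len(ok) == 0:
        ok = np.arange(len(grid))  # every point flagged: fall back to all
    keys = sorted(ok, key=lambda i: (-pi0s[i], -lls[i], abs(grid[i]), grid[i]))
    return keys[0]


def mrmix_fit(
    h: HarmonizedSet,
    exposure_index: int,
    theta_range: tuple[float, float] = (-0.5, 0.5),
    coarse_step: float = 0.01,
    fine_step: float = 0.001,
    max_iter: int = 2_000,
    tol: float = 1e-8,
) -> MixFit:
    """Estimate (theta, pi0, sigma^2) for one exposure by grid search.

    Effects are used on the harmonized scale and are assumed already
    standardized (SD units for the exposure, log-odds for the outcome;
    see :func:`standardize_binary_outcome` for the rescaling helper).
    A coarse grid over ``theta_range`` is refined at ``fine_step``
    within one coarse step of the coarse argmax.
    """
    j = h.n_snv
    if j < 4:
        raise ValueError(f"MRMix requires >= 4 SNVs, got {j}")
    bx, sx = h.bx[:, exposure_index], h.sx[:, exposure_index]
    by, sy = h.by, h.sy

    lo, hi = theta_range
    coarse = np.round(np.arange(lo, hi + coarse_step / 2, coarse_step), 10)
    p_c, s_c, l_c, c_c = _profile(bx, sx, by, sy, coarse, max_iter, tol)
    i_c = _argmax_pi0(coarse, p_c, l_c, c_c)

    center = coarse[i_c]
    fine = np.round(
        np.arange(center - coarse_step, center + coarse_step + fine_step / 2, fine_step),
        10,
    )
    fine = fine[(fine >= lo) & (fine <= hi)]
    p_f, s_f, l_f, c_f = _profile(bx, sx, by, sy, fine, max_iter, tol)
    i_f = _argmax_pi0(fine, p_f, l_f, c_f)

    grid = np.concatenate([coarse, fine])
    return MixFit(
        theta=float(fine[i_f]),
        pi0=float(p_f[i_f]),
        sigma2=float(s_f[i_f]),
        grid=grid,
        pi0_grid=np.concatenate([p_c, p_f]),
        sigma2_grid=np.concatenate([s_c, s_f]),
        loglik_profile=np.concatenate([l_c, l_f]),
        converged=np.concatenate([c_c, c_f]),
    )


def standardize_binary_outcome(
    beta: np.ndarray,
    se: np.ndarray,
    n: float | np.ndarray,
    eaf: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Rescale binary-trait log-odds effects onto the standardized scale.

    With effect-allele frequencies available the per-SNV scale factor is
    sqrt(2 f (1-f)) (per-allele effects expressed per genotype SD);
    without them the z / sqrt(n) convention is used, giving unit
    standard errors 1/sqrt(n).  Both paths leave z-statistics unchanged.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    if eaf is not None and np.all(np.isfinite(eaf)):
        scale = np.sqrt(2.0 * np.asarray(eaf) * (1.0 - np.asarray(eaf)))
        return beta * scale, se * scale
    z = beta / se
    return z / np.sqrt(n), np.ones_like(beta) / np.sqrt(n)
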