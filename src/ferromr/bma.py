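"""Multivariable MR by Bayesian model averaging over exposure subsets.

Every subset (model) of the K candidate exposures is scored by its
closed-form Gaussian marginal likelihood under a weighted linear model
of the SNV-outcome effects on the member SNV-exposure effects, with a
zero-centred normal shrinkage prior on standardized coefficients and an
independent-inclusion model prior.  Factors are ranked by marginal
inclusion probability (MIP, the posterior mass of models containing
them) and summarized by the model-averaged causal estimate (theta_MACE).

Per-instrument diagnostics on the best model — Cochran's Q contributions
and Cook's distances from the weighted regression — flag outlying or
overly influential SNVs (Q > 10, or Cd above the median of the
F(|model|, J - |model|) distribution); removal triggers a single refit
of the model space.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .sumstats import HarmonizedSet

__all__ = [
    "BMAModel",
    "BMAPosterior",
    "IVDiagnostics",
    "bma_enumerate",
    "iv_diagnostics",
    "bma_with_outlier_removal",
]


@dataclass
class BMAModel:
    members: tuple[int, ...]
    prior_prob: float
    marginal_loglik: float
    pp: float
    theta_lambda: np.ndarray  # per-member causal estimates, original beta_X scale


@dataclass
class BMAPosterior:
    models: list[BMAModel]
    exposures: list[str]
    mip: np.ndarray
    theta_mace: np.ndarray

    def model_table(self, top: int | None = 10, include_empty: bool = False) -> pd.DataFrame:
        """Per-model posterior summary ranked by PP (non-empty models by
        default, mirroring how best-model tables are published)."""
        rows = []
        for m in self.models:
            if not include_empty and not m.members:
                continue
            rows.append(
                {
                    "model": ",".join(self.exposures[k] for k in m.members) or "(null)",
                    "pp": m.pp,
                    "theta_lambda": ",".join(f"{t:.3f}" for t in m.theta_lambda),
                }
            )
        df = pd.DataFrame(rows).sort_values("pp", ascending=False, kind="stable")
        return df.head(top).reset_index(drop=True) if top else df.reset_index(drop=True)

    def factor_table(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"factor": self.exposures, "mip": self.mip, "theta_mace": self.theta_mace}
        )
        return df.sort_values("mip", ascending=False, kind="stable").reset_index(drop=True)


@dataclass
class IVDiagnostics:
    rsid: str
    q_contribution: float
    cooks_distance: float
    removed: bool
    rule: str


def _design(h: HarmonizedSet):
    """Weight-transformed response and standardized design columns."""
    sw = 1.0 / h.sy
    y = sw * h.by
    x = sw[:, None] * h.bx
    norms = np.linalg.norm(x, axis=0)
    return y, x, norms


def bma_enumerate(
    h: HarmonizedSet, prior_incl: float = 0.5, prior_sd: float = 0.25
) -> BMAPosterior:
    """Enumerate all 2^K exposure subsets and average over them.

    Per model lambda the weighted outcome vector y (weights se_Y^-2) is
    regressed on the member columns of beta_X, each standardized to unit
    weighted norm, under theta ~ N(0, prior_sd^2 I): the marginal
    likelihood is the Gaussian N(y; 0, I + prior_sd^2 C C^T) and the
    per-member estimates are the posterior means, rescaled back to the
    original beta_X units.  Model priors are
    prior_incl^|lambda| (1-prior_incl)^(K-|lambda|); the empty model
    carries the null likelihood so the posterior is a proper
    distribution over all subsets.
    """
    if not 0 <= prior_incl <= 1:
        raise ValueError("prior_incl must lie in [0, 1]")
    y, x, norms = _design(h)
    j, k = x.shape
    tau2 = prior_sd**2
    models: list[BMAModel] = []
    for size in range(k + 1):
        for members in itertools.combinations(range(k), size):
            if prior_incl in (0.0, 1.0):
                prior = float(
                    (prior_incl ** len(members)) * ((1 - prior_incl) ** (k - len(members)))
                )
            else:
                prior = float(
                    prior_incl ** len(members) * (1 - prior_incl) ** (k - len(members))
                )
            if members and np.any(norms[list(members)] == 0):
                models.append(BMAModel(members, prior, -np.inf, 0.0, np.zeros(len(members))))
                continue
            if not members:
                ll = float(np.sum(stats.norm.logpdf(y)))
                theta = np.zeros(0)
            else:
                idx = list(members)
                c = x[:, idx] / norms[idx]
                cov = np.eye(j) + tau2 * (c @ c.T)
                ll = float(stats.multivariate_normal.logpdf(y, mean=np.zeros(j), cov=cov))
                a = c.T @ c + np.eye(len(idx)) / tau2
                theta_std = np.linalg.solve(a, c.T @ y)
                theta = theta_std / norms[idx]
            models.append(BMAModel(members, prior, ll, 0.0, theta))

    log_post = np.array(
        [np.log(m.prior_prob) + m.marginal_loglik if m.prior_prob > 0 else -np.inf
         for m in models]
    )
    log_post -= np.max(log_post[np.isfinite(log_post)])
    pp = np.exp(log_post)
    pp /= pp.sum()
    for m, p in zip(models, pp):
        m.pp = float(p)

    mip = np.zeros(k)
    mace = np.zeros(k)
    for m in models:
        for pos, kk in enumerate(m.members):
            mip[kk] += m.pp
            mace[kk] += m.pp * m.theta_lambda[pos]
    return BMAPosterior(models=models, exposures=list(h.exposures), mip=mip, theta_mace=mace)


def best_model(posterior: BMAPosterior, include_empty: bool = False) -> BMAModel:
    cands = [m for m in posterior.models if include_empty or m.members]
    return max(cands, key=lambda m: m.pp)


def iv_diagnostics(
    h: HarmonizedSet,
    model: BMAModel,
    q_max: float = 10.0,
    cd_rule: str = "f_median",
) -> list[IVDiagnostics]:
    """Per-instrument outlier/influence diagnostics on one model.

    The member columns are refit by weighted least squares (the fit the
    influence measures are defined on): q_contribution is the SNV's
    weighted squared residual (its Cochran's Q term) and Cook's distance
    comes from the regression influence formula (via statsmodels OLS on
    the weight-transformed variables).  An SNV is removed when
    q > ``q_max`` or Cd exceeds the median of the F(p, J - p)
    distribution, p = |model|.
    """
    if not model.members:
        raise ValueError("diagnostics need a non-empty model")
    y, x, norms = _design(h)
    idx = list(model.members)
    p = len(idx)
    j = len(y)
    if j - p <= 0:
        raise ValueError(f"diagnostics undefined: J={j} <= |model|={p}")
    xm = x[:, idx]
    fit = sm.OLS(y, xm).fit()
    resid = y - fit.fittedvalues
    q_terms = resid**2  # already weight-transformed: w_j (by - yhat)^2
    cooks = sm.OLS(y, xm).fit().get_influence().cooks_distance[0]
    cd_cut = float(stats.f.ppf(0.5, p, j - p)) if cd_rule == "f_median" else float(cd_rule)
    out = []
    for i, rsid in enumerate(h.rsids):
        rules = []
        if q_terms[i] > q_max:
            rules.append(f"q>{q_max:g}")
        if cooks[i] > cd_cut:
            rules.append("cd>f_median")
        out.append(
            IVDiagnostics(
                rsid=rsid,
                q_contribution=float(q_terms[i]),
                cooks_distance=float(cooks[i]),
                removed=bool(rules),
                rule="+".join(rules),
            )
        )
    return out


def bma_with_outlier_removal(
    h: HarmonizedSet, prior_incl: float = 0.5, prior_sd: float = 0.25
) -> tuple[BMAPosterior, list[IVDiagnostics], HarmonizedSet]:
    """Full MR-BMA pass: enumerate, diagnose the best model, remove
    flagged instruments once, and refit the model space.

    Returns (final posterior, diagnostics from the initial fit, the
    HarmonizedSet actually used in the final fit).
    """
    post = bma_enumerate(h, prior_incl, prior_sd)
    best = best_model(post)
    if not best.members:
        return post, [], h
    diags = iv_diagnostics(h, best)
    removed = [d.rsid for d in diags if d.removed]
    if not removed or h.n_snv - len(removed) <= len(best.members):
        return post, diags, h
    keep = np.array([r not in removed for r in h.rsids])
    h2 = h.subset(keep)
    return bma_enumerate(h2, prior_incl, prior_sd), diags, h2
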