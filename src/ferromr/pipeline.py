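"""End-to-end orchestration: selection -> harmonization -> estimators ->
MRMix -> MR-BMA, with publication-shaped TSV outputs and a run log.

`run_full_analysis` drives the whole study from a :class:`RunConfig`
(file paths plus every threshold and seed); `analyze_study` is the
in-memory equivalent working directly on tables, which the example
scripts and tests use.  Both are pure functions of their inputs: the
same config and seed produce identical outputs.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import bma, estimators, instruments, mrmix
from .instruments import AnnotationTable, LDMatrix, MHC_REGION_GRCH37, PowerSpec
from .simulate import SimStudy
from .sumstats import GwasTable, HarmonizedSet, harmonize, read_sumstats

__all__ = ["RunConfig", "ResultBundle", "classify_significance",
           "analyze_study", "run_full_analysis", "load_config", "save_config"]

log = logging.getLogger("ferromr")

EXPOSURE_KEYS = ("iron", "ferritin", "tfsat", "tibc")


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for one full analysis run."""

    exposure_paths: dict = field(default_factory=dict)  # trait -> TSV path
    outcome_path: str = ""
    ld_path: str = ""
    annotation_path: str = ""
    out_dir: str = ""
    strategy: int = 1
    p_threshold: float = 5e-8
    clump_r2: float = 0.01
    proxy_r2: float = 0.8
    mhc_region: tuple = MHC_REGION_GRCH37
    palindrome_maf_cut: float = 0.42
    alpha: float = 0.05
    n_exposures_tested: int = 4
    n_outcomes_tested: int = 3
    boot_reps: int = 1000
    mrmix_range: tuple = (-0.5, 0.5)
    mrmix_coarse: float = 0.01
    mrmix_fine: float = 0.001
    prior_incl: float = 0.5
    prior_sd: float = 0.25
    power_odds_ratio: float = 1.1
    seed: int = 0

    def validate(self) -> None:
        if self.strategy not in (1, 2, 3):
            raise ValueError("strategy must be 1, 2 or 3")
        for name in ("p_threshold", "clump_r2", "proxy_r2", "alpha",
                     "palindrome_maf_cut"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must lie in (0, 1], got {v}")


def save_config(cfg: RunConfig, path) -> None:
    d = dataclasses.asdict(cfg)
    d["mhc_region"] = list(d["mhc_region"])
    d["mrmix_range"] = list(d["mrmix_range"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


def load_config(path) -> RunConfig:
    d = yaml.safe_load(Path(path).read_text())
    d["mhc_region"] = tuple(d["mhc_region"])
    d["mrmix_range"] = tuple(d["mrmix_range"])
    cfg = RunConfig(**d)
    cfg.validate()
    return cfg


def classify_significance(pval: float, threshold: float, alpha: float = 0.05) -> str:
    """'significant' below the Bonferroni threshold, 'suggestive' between
    the threshold and alpha, 'null' above alpha."""
    if threshold > alpha:
        raise ValueError("threshold must not exceed alpha")
    if pval < threshold:
        return "significant"
    if pval < alpha:
        return "suggestive"
    return "null"


@dataclass
class ResultBundle:
    """All outputs of one analysis run as tidy DataFrames."""

    estimates: pd.DataFrame        # forest-table shape, one row per exposure x method
    heterogeneity: pd.DataFrame
    mrmix: pd.DataFrame            # exposure, theta, pi0, sigma2
    bma_factors: pd.DataFrame      # factor, mip, theta_mace
    bma_models: pd.DataFrame       # model, pp, theta_lambda (top 10)
    diagnostics: pd.DataFrame      # rsid, q, cd, removed, rule
    selection: pd.DataFrame        # per-SNV fate through the QC funnel
    strength: pd.DataFrame         # per-SNV F statistics (vs serum iron)
    power: pd.DataFrame
    harmonized: HarmonizedSet

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for name in ("estimates", "heterogeneity", "mrmix", "bma_factors",
                     "bma_models", "diagnostics", "selection", "strength", "power"):
            getattr(self, name).to_csv(out / f"{name}.tsv", sep="\t", index=False)


def _select_and_qc(exposures, outcome, ld, annotations, cfg: RunConfig):
    """Run the instrument QC funnel; returns (final rsids, fate table)."""
    fate: dict[str, str] = {}
    candidates = instruments.select_instruments(exposures, cfg.strategy, cfg.p_threshold)
    log.info("strategy %d: %d candidate SNVs", cfg.strategy, len(candidates))
    for r in candidates:
        fate[r] = "candidate"

    # MHC exclusion (coordinates from the first exposure table).
    ref = exposures[0]
    cand_df = pd.DataFrame(
        [{"rsid": r, "chr": ref.get(r)["chr"], "pos": ref.get(r)["pos"]}
         for r in candidates]
    )
    if len(cand_df):
        kept_df, removed_df = instruments.exclude_mhc(cand_df, cfg.mhc_region)
        for r in removed_df["rsid"]:
            fate[r] = "removed_mhc"
        candidates = list(kept_df["rsid"])

    # Confounder / outcome-association exclusion.
    candidates, removed = instruments.exclude_pleiotropic(
        candidates, annotations, outcome, cfg.p_threshold
    )
    for _, row in removed.iterrows():
        fate[row["rsid"]] = f"removed_{row['reason']}"

    # Proxy substitution for SNVs absent from the outcome table.
    exp_rsids = set.intersection(*[set(t.rsids) for t in exposures])
    available = sorted(exp_rsids & set(outcome.rsids))
    positions = {r: float(ref.get(r)["pos"]) for r in available if r in ref}
    final = []
    for r in candidates:
        if r in outcome:
            final.append(r)
            continue
        proxy = instruments.find_proxy(r, ld, available, cfg.proxy_r2, positions)
        if proxy is None:
            fate[r] = "dropped_no_proxy"
        elif proxy in final:
            fate[r] = f"proxy_already_used:{proxy}"
        else:
            fate[r] = f"proxied_by:{proxy}"
            fate.setdefault(proxy, "proxy")
            final.append(proxy)
    candidates = final

    # LD clumping on the minimum exposure p-value.
    rows = []
    for r in candidates:
        ps = [t.get(r)["pval"] for t in exposures if r in t]
        pos = float(ref.get(r)["pos"]) if r in ref else np.inf
        rows.append({"rsid": r, "pval": min(ps), "pos": pos})
    if rows:
        accepted, warnings = instruments.clump(pd.DataFrame(rows), ld, cfg.clump_r2)
        for msg in warnings:
            log.warning("clump: %s", msg)
        for r in candidates:
            fate[r] = "selected" if r in accepted else "clumped_out"
        candidates = accepted
    sel = pd.DataFrame(
        [{"rsid": r, "fate": f} for r, f in fate.items()], columns=["rsid", "fate"]
    )
    return candidates, sel


def analyze_study(
    exposures: list[GwasTable],
    outcome: GwasTable,
    ld: LDMatrix,
    annotations: AnnotationTable,
    cfg: RunConfig | None = None,
) -> ResultBundle:
    """Full analysis of one study held in memory."""
    cfg = cfg or RunConfig()
    cfg.validate()
    selected, sel_report = _select_and_qc(exposures, outcome, ld, annotations, cfg)
    if not selected:
        raise RuntimeError("instrument selection: no SNVs survived the QC funnel")
    h = harmonize(exposures, outcome, cfg.palindrome_maf_cut, rsids=selected)
    for _, row in h.dropped.iterrows():
        ridx = sel_report["rsid"] == row["rsid"]
        sel_report.loc[ridx, "fate"] = f"harmonization_dropped:{row['reason']}"
    if h.n_snv == 0:
        raise RuntimeError("harmonization: no SNVs survived")
    log.info("harmonized %d instruments", h.n_snv)

    bonf = estimators.bonferroni_threshold(
        cfg.n_exposures_tested, cfg.n_outcomes_tested, cfg.alpha
    )
    est_rows, het_rows, mix_rows = [], [], []
    for k, trait in enumerate(h.exposures):
        ratios = estimators.wald_ratios(h, k)
        ests = [
            estimators.ivw(ratios, "multiplicative_random"),
            estimators.ivw(ratios, "fixed"),
        ]
        if len(ratios) >= 3:
            for variant in ("simple", "weighted", "penalized"):
                ests.append(
                    estimators.median_estimators(
                        ratios, variant, cfg.boot_reps, seed=cfg.seed
                    )
                )
            ests.append(estimators.egger(h, k))
        for e in ests:
            est_rows.append(
                {
                    "exposure": trait,
                    "strategy": cfg.strategy,
                    "method": e.method,
                    "n_snv": e.n_snv,
                    "beta": e.beta,
                    "se": e.se,
                    "or": e.odds_ratio,
                    "or_ci_low": e.or_ci[0],
                    "or_ci_high": e.or_ci[1],
                    "pval": e.pval,
                    "classification": classify_significance(e.pval, bonf, cfg.alpha),
                    "egger_intercept": e.egger_intercept,
                    "intercept_pval": e.intercept_pval,
                }
            )
        if len(ratios) >= 2:
            ivw_est = ests[0]
            het = estimators.cochran_q(ratios, ivw_est.beta, "ivw")
            het_rows.append({"exposure": trait, "method": "ivw",
                             "q": het.q_stat, "df": het.df, "pval": het.pval})
            egger_ests = [e for e in ests if e.method == "egger"]
            if egger_ests:
                het_e = estimators.cochran_q(ratios, egger_ests[0].beta, "egger")
                het_rows.append({"exposure": trait, "method": "egger",
                                 "q": het_e.q_stat, "df": het_e.df, "pval": het_e.pval})
        if h.n_snv >= 4:
            fit = mrmix.mrmix_fit(
                h, k, cfg.mrmix_range, cfg.mrmix_coarse, cfg.mrmix_fine
            )
            mix_rows.append({"exposure": trait, "theta": fit.theta,
                             "pi0": fit.pi0, "sigma2": fit.sigma2})

    if h.n_snv > h.n_exposure + 1:
        post, diags, _ = bma.bma_with_outlier_removal(h, cfg.prior_incl, cfg.prior_sd)
        bma_factors = post.factor_table()
        bma_models = post.model_table(top=10)
        diag_df = pd.DataFrame(
            [{"rsid": d.rsid, "q_contribution": d.q_contribution,
              "cooks_distance": d.cooks_distance, "removed": d.removed,
              "rule": d.rule} for d in diags]
        )
    else:
        bma_factors = pd.DataFrame(columns=["factor", "mip", "theta_mace"])
        bma_models = pd.DataFrame(columns=["model", "pp", "theta_lambda"])
        diag_df = pd.DataFrame(columns=["rsid", "q_contribution", "cooks_distance",
                                        "removed", "rule"])

    strengths = instruments.instrument_strength(exposures[0],
                                                [r for r in h.rsids if r in exposures[0]])
    strength_df = pd.DataFrame(
        [{"rsid": s.rsid, "r2": s.r2_exposure, "n": s.n, "f_stat": s.f_stat,
          "weak": s.weak} for s in strengths]
    )
    r2_sum = float(strength_df["r2"].sum()) if len(strength_df) else 0.0
    n_out = float(outcome.df["n"].iloc[0])
    case_fraction = getattr(cfg, "case_fraction", None)
    if case_fraction is None:
        case_fraction = 0.024  # pooled kidney-disease GWAS case share
    pw = instruments.mr_power(
        PowerSpec(n_outcome=n_out, case_fraction=case_fraction, r2_sum=r2_sum,
                  odds_ratio=cfg.power_odds_ratio, alpha=cfg.alpha)
    )
    power_df = pd.DataFrame([dataclasses.asdict(pw)])

    return ResultBundle(
        estimates=pd.DataFrame(est_rows),
        heterogeneity=pd.DataFrame(het_rows),
        mrmix=pd.DataFrame(mix_rows, columns=["exposure", "theta", "pi0", "sigma2"]),
        bma_factors=bma_factors,
        bma_models=bma_models,
        diagnostics=diag_df,
        selection=sel_report,
        strength=strength_df,
        power=power_df,
        harmonized=h,
    )


def analyze_simulated(study: SimStudy, cfg: RunConfig | None = None) -> ResultBundle:
    """Convenience wrapper running the full analysis on a simulated bundle."""
    return analyze_study(study.exposures, study.outcome, study.ld,
                         study.annotations, cfg)


def run_full_analysis(cfg: RunConfig) -> ResultBundle:
    """File-driven analysis: read inputs from the config paths, run
    everything, and write the publication-shaped TSVs to ``out_dir``."""
    cfg.validate()
    exposures = [read_sumstats(cfg.exposure_paths[t], t) for t in EXPOSURE_KEYS]
    outcome = read_sumstats(cfg.outcome_path, "outcome")
    ld = LDMatrix.read_tsv(cfg.ld_path)
    annotations = AnnotationTable.read_tsv(cfg.annotation_path)
    bundle = analyze_study(exposures, outcome, ld, annotations, cfg)
    if cfg.out_dir:
        bundle.write(cfg.out_dir)
        save_config(cfg, Path(cfg.out_dir) / "config.yaml")
    return bundle
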