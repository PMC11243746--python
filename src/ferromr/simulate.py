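"""Seeded synthetic GWAS summary statistics with the structure the
iron-status MR analysis assumes.

Each SNV carries a latent iron-status effect shared by the four
biomarkers (serum iron, ferritin, transferrin saturation positively
loaded, TIBC negatively), plus a small biomarker-specific deviation so
the four exposure GWAS are correlated but not collinear.  The binary
outcome receives theta times the latent effect (log-odds per SD of
iron status) and, for a configurable fraction of invalid instruments, an
additional direct (pleiotropic) effect.  Observed effects add sampling
noise with the standard GWAS standard errors
se = (2 f (1-f) n)^{-1/2} for continuous traits and
se = (2 f (1-f) n phi (1-phi))^{-1/2} for a case-control outcome with
case fraction phi.  LD is block-diagonal with r^2 decaying
geometrically within blocks.  All draws flow from one seed through
deterministic substreams, so identical configs give byte-identical
tables.

Default cohort sizes are the source GWAS sizes scaled down tenfold
(iron 163,511 -> 16,351 and so on) so the full analysis runs in
seconds while keeping realistic instrument strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .instruments import AnnotationTable, LDMatrix
from .sumstats import GwasTable, REQUIRED_COLUMNS

__all__ = ["SynthConfig", "SimStudy", "simulate_study", "make_strategy_fixture"]

_EXPOSURE_TRAITS = ("iron", "ferritin", "tfsat", "tibc")
# Non-palindromic allele pairs only, so harmonization needs no frequency calls.
_ALLELE_PAIRS = (("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"), ("G", "A"), ("C", "A"))


@dataclass
class SynthConfig:
    """Study conditions for one synthetic two-sample MR data set."""

    seed: int = 0
    n_snv: int = 60
    ld_block_size: int = 5
    ld_decay: float = 0.3          # within-block r^2 between adjacent SNVs
    maf_range: tuple[float, float] = (0.05, 0.5)
    # Exposure GWAS sizes: source cohorts scaled down 10x.
    n_iron: int = 16_351
    n_ferritin: int = 24_614
    n_tfsat: int = 13_147
    n_tibc: int = 13_543
    # Outcome: pooled case-control design, 10x scale-down of the IgAN GWAS.
    n_outcome: int = 65_314
    case_fraction: float = 0.024
    theta: float = 0.1             # causal log-OR per SD of latent iron status
    factor_loadings: tuple[float, float, float, float] = (1.0, 1.0, 1.0, -1.0)
    latent_sd: float = 0.08        # SD of the shared iron-status effect per SNV
    idio_sd: float = 0.03          # biomarker-specific deviation from the factor
    invalid_fraction: float = 0.0  # share of SNVs with direct outcome effects
    sigma_pleio: float = 0.05      # SD of those direct effects
    n_confounder_snvs: int = 2
    causal_exposure: int | None = None  # outcome responds to this biomarker
                                        # instead of the latent factor

    def __post_init__(self) -> None:
        if not 0 < self.case_fraction < 1:
            raise ValueError("case_fraction must lie in (0, 1)")
        if not 0 <= self.invalid_fraction <= 1:
            raise ValueError("invalid_fraction must lie in [0, 1]")
        if not 0 <= self.ld_decay < 1:
            raise ValueError("ld_decay must lie in [0, 1)")


@dataclass
class SimStudy:
    """One simulated study: tables, LD, annotations and ground truth."""

    exposures: list[GwasTable]
    outcome: GwasTable
    ld: LDMatrix
    annotations: AnnotationTable
    truth: pd.DataFrame
    config: SynthConfig = field(repr=False, default=None)


def _continuous_se(maf: np.ndarray, n: int) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * maf * (1.0 - maf) * n)


def _binary_se(maf: np.ndarray, n: int, case_fraction: float) -> np.ndarray:
    return 1.0 / np.sqrt(
        2.0 * maf * (1.0 - maf) * n * case_fraction * (1.0 - case_fraction)
    )


def _pvals(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-320, 1.0)


def _positions(n_snv: int, block_size: int):
    """Place blocks on successive chromosomes, 50 kb apart within a
    chromosome, avoiding the chr6 MHC band."""
    chroms, poss = [], []
    counters: dict[int, int] = {}
    for j in range(n_snv):
        block = j // block_size
        c = (block % 22) + 1
        i = counters.get(c, 0)
        counters[c] = i + 1
        chroms.append(str(c))
        poss.append(1_000_000 + 50_000 * i)
    return chroms, poss


def _table(trait, rsids, chroms, poss, eas, oas, maf, beta, se, n) -> GwasTable:
    df = pd.DataFrame(
        {
            "rsid": rsids,
            "chr": chroms,
            "pos": poss,
            "ea": eas,
            "oa": oas,
            "eaf": maf,
            "beta": beta,
            "se": se,
            "pval": _pvals(beta, se),
            "n": float(n),
        }
    )[REQUIRED_COLUMNS]
    return GwasTable(trait=trait, df=df)


def _block_ld(n_snv: int, block_size: int, decay: float) -> np.ndarray:
    r2 = np.zeros((n_snv, n_snv))
    for start in range(0, n_snv, block_size):
        stop = min(start + block_size, n_snv)
        idx = np.arange(start, stop)
        d = np.abs(idx[:, None] - idx[None, :])
        r2[start:stop, start:stop] = decay**d
    np.fill_diagonal(r2, 1.0)
    return r2


def simulate_study(cfg: SynthConfig) -> SimStudy:
    """Generate one seeded study bundle.

    Returns four exposure tables, the outcome table, the LD matrix, an
    annotation table (confounder-associated SNVs standing in for a
    phenome-wide lookup) and a truth record holding every latent
    quantity for recovery tests.
    """
    ss = np.random.SeedSequence(cfg.seed)
    rng_struct, rng_effects, *rng_noise = [
        np.random.default_rng(s) for s in ss.spawn(2 + len(_EXPOSURE_TRAITS) + 2)
    ]

    n = cfg.n_snv
    rsids = [f"rs{j + 1}" for j in range(n)]
    chroms, poss = _positions(n, cfg.ld_block_size)
    pair_idx = rng_struct.integers(0, len(_ALLELE_PAIRS), size=n)
    eas = [_ALLELE_PAIRS[i][0] for i in pair_idx]
    oas = [_ALLELE_PAIRS[i][1] for i in pair_idx]
    maf = rng_struct.uniform(*cfg.maf_range, size=n)

    latent = rng_effects.normal(0.0, cfg.latent_sd, size=n)
    loadings = np.asarray(cfg.factor_loadings, dtype=float)
    idio = rng_effects.normal(0.0, cfg.idio_sd, size=(n, 4))
    true_bx = latent[:, None] * loadings[None, :] + idio

    invalid = rng_effects.random(n) < cfg.invalid_fraction
    direct = np.where(invalid, rng_effects.normal(0.0, cfg.sigma_pleio, size=n), 0.0)
    target = latent if cfg.causal_exposure is None else true_bx[:, cfg.causal_exposure]
    true_by = cfg.theta * target + direct

    sizes = (cfg.n_iron, cfg.n_ferritin, cfg.n_tfsat, cfg.n_tibc)
    exposures = []
    for k, (trait, nk) in enumerate(zip(_EXPOSURE_TRAITS, sizes)):
        se = _continuous_se(maf, nk)
        beta = true_bx[:, k] + rng_noise[k].normal(0.0, se)
        exposures.append(_table(trait, rsids, chroms, poss, eas, oas, maf, beta, se, nk))

    se_y = _binary_se(maf, cfg.n_outcome, cfg.case_fraction)
    beta_y = true_by + rng_noise[4].normal(0.0, se_y)
    outcome = _table("outcome", rsids, chroms, poss, eas, oas, maf, beta_y, se_y,
                     cfg.n_outcome)

    ld = LDMatrix(rsids=rsids, r2=_block_ld(n, cfg.ld_block_size, cfg.ld_decay))

    rng_ann = rng_noise[5]
    n_conf = min(cfg.n_confounder_snvs, n)
    conf_idx = rng_ann.choice(n, size=n_conf, replace=False) if n_conf else np.array([], int)
    ann_rows = [
        {"rsid": rsids[i], "trait": ("smoking", "bmi")[j % 2], "pval": 1e-12}
        for j, i in enumerate(sorted(conf_idx))
    ]
    if n:  # one benign, above-threshold annotation for realism
        ann_rows.append({"rsid": rsids[0], "trait": "height", "pval": 1e-4})
    annotations = AnnotationTable(pd.DataFrame(ann_rows, columns=["rsid", "trait", "pval"]))

    truth = pd.DataFrame(
        {
            "rsid": rsids,
            "maf": maf,
            "latent": latent,
            **{f"true_{t}": true_bx[:, k] for k, t in enumerate(_EXPOSURE_TRAITS)},
            "direct": direct,
            "invalid": invalid,
            "true_outcome": true_by,
        }
    )
    return SimStudy(exposures=exposures, outcome=outcome, ld=ld,
                    annotations=annotations, truth=truth, config=cfg)


def make_strategy_fixture(cfg: SynthConfig, target_strategy: int) -> SimStudy:
    """A study whose planted SNVs satisfy *exactly* the target selection
    strategy (and, by nesting, every weaker one).

    Effects are set relative to the analytic standard errors: |z| = 8
    for genome-wide significance, |z| = 3 for clear non-significance.
    Strategy 1 SNVs are significant and direction-consistent in all four
    biomarkers; strategy-2-only SNVs are significant in exactly one but
    direction-consistent everywhere; strategy-3-only SNVs are
    significant in one biomarker with an inconsistent sign pattern.
    The LD matrix is the identity and annotations are empty, so
    selection logic is isolated from the other filters.
    """
    if target_strategy not in (1, 2, 3):
        raise ValueError("target_strategy must be 1, 2 or 3")
    n = 6
    rsids = [f"rs{j + 1}" for j in range(n)]
    chroms, poss = _positions(n, cfg.ld_block_size)
    maf = np.full(n, 0.25)
    loadings = np.asarray(cfg.factor_loadings, dtype=float)
    sizes = (cfg.n_iron, cfg.n_ferritin, cfg.n_tfsat, cfg.n_tibc)
    ses = np.stack([_continuous_se(maf, nk) for nk in sizes], axis=1)

    z = np.zeros((n, 4))
    if target_strategy == 1:
        z[:] = 8.0 * loadings[None, :]
    elif target_strategy == 2:
        z[:] = 3.0 * loadings[None, :]
        z[np.arange(n), np.arange(n) % 4] = 8.0 * loadings[np.arange(n) % 4]
    else:
        # One significant biomarker; the others small with a sign clash.
        z[:] = 3.0 * loadings[None, :]
        z[:, 3] = 3.0 * loadings[3] * -1.0  # TIBC same-signed as iron: inconsistent
        z[np.arange(n), np.arange(n) % 3] = 8.0 * loadings[np.arange(n) % 3]
    true_bx = z * ses

    exposures = []
    for k, (trait, nk) in enumerate(zip(_EXPOSURE_TRAITS, sizes)):
        exposures.append(
            _table(trait, rsids, chroms, poss, ["A"] * n, ["G"] * n, maf,
                   true_bx[:, k], ses[:, k], nk)
        )
    se_y = _binary_se(maf, cfg.n_outcome, cfg.case_fraction)
    beta_y = cfg.theta * true_bx[:, 0]
    outcome = _table("outcome", rsids, chroms, poss, ["A"] * n, ["G"] * n, maf,
                     beta_y, se_y, cfg.n_outcome)
    ld = LDMatrix(rsids=rsids, r2=np.eye(n))
    annotations = AnnotationTable(pd.DataFrame(columns=["rsid", "trait", "pval"]))
    truth = pd.DataFrame({"rsid": rsids, "target_strategy": target_strategy})
    return SimStudy(exposures=exposures, outcome=outcome, ld=ld,
                    annotations=annotations, truth=truth,
                    config=replace(cfg, n_snv=n))
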