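"""Instrument selection, LD clumping, exclusions, strength and power.

Instrumental SNVs for systemic iron status are chosen under three
strategies of increasing permissiveness:

1. genome-wide significant (p < 5e-8 by default) in *all four* iron
   biomarkers;
2. genome-wide significant in at least one biomarker *and* directionally
   consistent with iron status across all four (TIBC sign-inverted);
3. genome-wide significant in at least one biomarker.

Strategy 1 is therefore nested in 2, and 2 in 3.  Selected candidates
then pass through proxy substitution (r^2 > 0.8), greedy LD clumping
(r^2 < 0.01, lowest p kept), removal of the chromosome-6 MHC region,
and exclusion of SNVs associated with confounder traits or directly
with the outcome.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats import GwasTable

__all__ = [
    "LDMatrix",
    "AnnotationTable",
    "InstrumentStrength",
    "PowerSpec",
    "MHC_REGION_GRCH37",
    "select_instruments",
    "is_direction_consistent",
    "clump",
    "find_proxy",
    "exclude_mhc",
    "exclude_pleiotropic",
    "snv_r2",
    "f_statistic",
    "instrument_strength",
    "mr_power",
]

#: Classical MHC on chromosome 6, GRCh37, inclusive ends.
MHC_REGION_GRCH37 = ("6", 28_477_797, 33_448_354)


@dataclass
class LDMatrix:
    """Square matrix of squared correlations (r^2) keyed by rsID."""

    rsids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.r2 = np.asarray(self.r2, dtype=float)
        n = len(self.rsids)
        if self.r2.shape != (n, n):
            raise ValueError("LD matrix shape does not match rsid list")
        if not np.allclose(self.r2, self.r2.T, atol=1e-10):
            raise ValueError("LD matrix must be symmetric")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-10):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("r^2 entries must lie in [0, 1]")
        self._index = {r: i for i, r in enumerate(self.rsids)}

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, a: str, b: str) -> float | None:
        """r^2 between two SNVs, or None if either is absent from the panel."""
        ia, ib = self._index.get(a), self._index.get(b)
        if ia is None or ib is None:
            return None
        return float(self.r2[ia, ib])

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.r2, index=self.rsids, columns=self.rsids).to_csv(
            path, sep="\t", index_label="rsid"
        )

    @classmethod
    def read_tsv(cls, path) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(rsids=list(df.columns), r2=df.to_numpy(dtype=float))


@dataclass
class AnnotationTable:
    """Offline (rsid, trait, pval) associations standing in for a
    phenome-wide lookup such as PhenoScanner."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("rsid", "trait", "pval"):
            if col not in self.df.columns:
                raise ValueError(f"annotation table missing column {col!r}")
        if len(self.df) and not ((self.df["pval"] > 0) & (self.df["pval"] <= 1)).all():
            raise ValueError("annotation p-values must lie in (0, 1]")

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path) -> "AnnotationTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"rsid": str, "trait": str}))


@dataclass
class InstrumentStrength:
    rsid: str
    r2_exposure: float
    k: int
    n: float
    f_stat: float
    weak: bool


@dataclass
class PowerSpec:
    """Design of a two-sample MR power calculation for a binary outcome."""

    n_outcome: float
    case_fraction: float
    r2_sum: float
    odds_ratio: float
    alpha: float = 0.05
    power: float = field(default=np.nan)


def is_direction_consistent(snv_betas, direction_signs) -> bool:
    """True iff sign(beta_k * direction_sign_k) agrees across biomarkers.

    A zero or non-finite beta is indeterminate and treated as
    inconsistent.  TIBC carries direction sign -1, so an iron-raising SNV
    has positive betas on iron/ferritin/TfSat and negative on TIBC.
    """
    b = np.asarray(snv_betas, dtype=float)
    s = np.asarray(direction_signs, dtype=float)
    if b.shape != s.shape:
        raise ValueError("betas and direction signs must have equal length")
    if np.any(~np.isfinite(b)) or np.any(b == 0):
        return False
    oriented = np.sign(b * s)
    return bool(np.all(oriented == oriented[0]))


def select_instruments(
    exposures: list[GwasTable], strategy: int, p_threshold: float = 5e-8
) -> list[str]:
    """Candidate instrument rsids under one of the three strategies.

    Order of the returned list follows first appearance across the
    exposure tables.  SNVs absent from a table count as not significant
    there, and cannot be direction-consistent (strategy 2) or satisfy
    strategy 1.
    """
    if len(exposures) != 4:
        raise ValueError(f"expected 4 exposure tables, got {len(exposures)}")
    if strategy not in (1, 2, 3):
        raise ValueError(f"strategy must be 1, 2 or 3, got {strategy}")
    signs = [t.direction_sign for t in exposures]

    ordered: dict[str, None] = {}
    for t in exposures:
        for r in t.rsids:
            ordered.setdefault(r, None)

    out = []
    for rsid in ordered:
        pvals, betas = [], []
        for t in exposures:
            if rsid in t:
                rec = t.get(rsid)
                pvals.append(rec["pval"])
                betas.append(rec["beta"])
            else:
                pvals.append(1.0)
                betas.append(np.nan)
        sig = [p < p_threshold for p in pvals]
        if strategy == 1:
            take = all(sig)
        elif strategy == 2:
            take = any(sig) and is_direction_consistent(betas, signs)
        else:
            take = any(sig)
        if take:
            out.append(rsid)
    return out


def clump(
    candidates: pd.DataFrame, ld: LDMatrix, r2_max: float = 0.01
) -> tuple[list[str], list[str]]:
    """Greedy LD clumping: keep the lowest-p SNV of every correlated cluster.

    ``candidates`` needs columns ``rsid`` and ``pval`` (optional ``pos``
    used for deterministic tie-breaks at equal p, then lexicographic
    rsid).  A candidate is accepted iff its r^2 with every
    already-accepted SNV is below ``r2_max``; SNVs absent from the LD
    panel are treated as independent.  Returns (accepted-in-order,
    warnings).
    """
    if "pos" in candidates.columns:
        ordered = candidates.sort_values(
            ["pval", "pos", "rsid"], kind="stable"
        )
    else:
        ordered = candidates.sort_values(["pval", "rsid"], kind="stable")
    accepted: list[str] = []
    warnings: list[str] = []
    for rsid in ordered["rsid"]:
        if rsid not in ld:
            warnings.append(f"{rsid}: absent from LD panel, treated as independent")
            accepted.append(rsid)
            continue
        ok = True
        for kept in accepted:
            r2 = ld.get(rsid, kept)
            if r2 is not None and r2 >= r2_max:
                ok = False
                break
        if ok:
            accepted.append(rsid)
    return accepted, warnings


def find_proxy(
    missing: str,
    ld: LDMatrix,
    available,
    r2_min: float = 0.8,
    positions: dict | None = None,
) -> str | None:
    """Best available proxy for a missing SNV: highest r^2 >= ``r2_min``.

    Ties broken by smaller base position (when ``positions`` provided),
    then lexicographic rsid; returns None when no proxy qualifies.
    """
    if missing not in ld:
        return None
    best = None
    for cand in available:
        if cand == missing:
            continue
        r2 = ld.get(missing, cand)
        if r2 is None or r2 < r2_min:
            continue
        pos = positions.get(cand, math.inf) if positions else math.inf
        key = (-r2, pos, cand)
        if best is None or key < best[0]:
            best = (key, cand)
    return None if best is None else best[1]


def exclude_mhc(
    candidates: pd.DataFrame, region: tuple = MHC_REGION_GRCH37
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop SNVs inside the MHC region (inclusive ends, GRCh37).

    ``candidates`` needs ``rsid``, ``chr`` and ``pos`` columns.  Returns
    (kept, removed).
    """
    chrom, lo, hi = region
    chrom = str(chrom).removeprefix("chr")
    chr_norm = candidates["chr"].astype(str).str.removeprefix("chr")
    inside = (chr_norm == chrom) & (candidates["pos"] >= lo) & (candidates["pos"] <= hi)
    return candidates[~inside].copy(), candidates[inside].copy()


def exclude_pleiotropic(
    candidates: list[str],
    annotations: AnnotationTable,
    outcome_table: GwasTable,
    p_threshold: float = 5e-8,
) -> tuple[list[str], pd.DataFrame]:
    """Remove confounder-associated SNVs and SNVs directly associated
    with the outcome (p < threshold); returns (kept, removal log)."""
    hits = annotations.df[annotations.df["pval"] < p_threshold]
    confounder_map: dict[str, str] = {}
    for _, row in hits.iterrows():
        confounder_map.setdefault(row["rsid"], row["trait"])
    kept, removed = [], []
    for rsid in candidates:
        if rsid in confounder_map:
            removed.append((rsid, f"confounder:{confounder_map[rsid]}"))
        elif rsid in outcome_table and outcome_table.get(rsid)["pval"] < p_threshold:
            removed.append((rsid, "outcome_association"))
        else:
            kept.append(rsid)
    return kept, pd.DataFrame(removed, columns=["rsid", "reason"])


def snv_r2(beta: float, eaf: float | None, n: float | None = None, se: float | None = None) -> float:
    """Variance in a standardized trait explained by one SNV.

    R^2 = 2 f (1 - f) beta^2 when the effect-allele frequency is known;
    otherwise the z-statistic fallback z^2 / (z^2 + n - 2).
    """
    if eaf is not None and np.isfinite(eaf):
        return float(2.0 * eaf * (1.0 - eaf) * beta**2)
    if se is None or n is None:
        raise ValueError("need (se, n) when eaf is missing")
    z2 = (beta / se) ** 2
    return float(z2 / (z2 + n - 2.0))


def f_statistic(r2: float, k: int, n: float) -> float:
    """Instrument-strength F statistic (R^2/k) / ((1-R^2)/(n-k-1)).

    F < 10 conventionally flags a weak instrument.
    """
    if not 0 <= r2 < 1:
        raise ValueError(f"r2 must lie in [0, 1), got {r2}")
    if n <= k + 1:
        raise ValueError(f"need n > k + 1, got n={n}, k={k}")
    return float((r2 / k) * (n - k - 1) / (1.0 - r2))


def instrument_strength(table: GwasTable, rsids: list[str]) -> list[InstrumentStrength]:
    """Per-SNV strength (k = 1) against one exposure table."""
    out = []
    for rsid in rsids:
        rec = table.get(rsid)
        eaf = rec["eaf"] if np.isfinite(rec["eaf"]) else None
        r2 = snv_r2(rec["beta"], eaf, n=rec["n"], se=rec["se"])
        f = f_statistic(r2, 1, rec["n"])
        out.append(
            InstrumentStrength(
                rsid=rsid, r2_exposure=r2, k=1, n=float(rec["n"]), f_stat=f, weak=f < 10
            )
        )
    return out


def mr_power(spec: PowerSpec) -> PowerSpec:
    """Closed-form power of the two-sample MR test for a binary outcome.

    power = Phi( sqrt(N * R^2 * phi * (1 - phi)) * |ln OR| - z_{1-a/2} )
    with N the outcome sample size, phi the case fraction and R^2 the
    summed variance explained by the instruments.  At OR = 1 this
    degenerates to the two-sided floor Phi(-z) ~ alpha/2.
    """
    if not 0 < spec.case_fraction < 1:
        raise ValueError("case_fraction must lie in (0, 1)")
    if min(spec.n_outcome, spec.r2_sum, spec.odds_ratio) <= 0:
        raise ValueError("n_outcome, r2_sum and odds_ratio must be positive")
    z = stats.norm.ppf(1 - spec.alpha / 2)
    ncp = math.sqrt(
        spec.n_outcome * spec.r2_sum * spec.case_fraction * (1 - spec.case_fraction)
    ) * abs(math.log(spec.odds_ratio))
    power = float(stats.norm.cdf(ncp - z))
    return PowerSpec(
        n_outcome=spec.n_outcome,
        case_fraction=spec.case_fraction,
        r2_sum=spec.r2_sum,
        odds_ratio=spec.odds_ratio,
        alpha=spec.alpha,
        power=power,
    )
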