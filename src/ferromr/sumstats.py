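"""GWAS summary-statistic tables and two-sample harmonization.

Summary statistics are exchanged as tab-separated tables with one row per
single-nucleotide variant (SNV) and a fixed header::

    rsid  chr  pos  ea  oa  eaf  beta  se  pval  n

``ea`` is the effect allele, ``beta`` the additive effect per copy of it
(SD units for continuous biomarkers, log-odds for the case-control
outcome), ``eaf`` its frequency ('.' when unknown).  Positions are
1-based on GRCh37.

Harmonization places the exposure and outcome associations for each SNV
on a single, coding-independent effect-allele orientation: the allele
pair is first canonicalized over strand complement and allele swap, then
every table's beta is re-signed onto the canonical effect allele.
Palindromic SNVs (A/T, G/C), where strand cannot be resolved from the
alleles, are aligned by allele-frequency concordance when the frequency
is informative and dropped otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "REQUIRED_COLUMNS",
    "TRAIT_SIGNS",
    "FormatError",
    "ValidationError",
    "GwasTable",
    "HarmonizedSet",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
]

REQUIRED_COLUMNS = ["rsid", "chr", "pos", "ea", "oa", "eaf", "beta", "se", "pval", "n"]

#: Direction of each biomarker with respect to systemic iron status.
#: Total iron-binding capacity (TIBC) rises when body iron falls, so it
#: carries sign -1; serum iron, ferritin and transferrin saturation +1.
TRAIT_SIGNS = {"iron": 1, "ferritin": 1, "tfsat": 1, "tibc": -1, "outcome": 1}

_VALID_ALLELES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


class FormatError(ValueError):
    """Raised when an input table is not in the expected dialect."""


class ValidationError(ValueError):
    """Raised when table content violates an invariant (e.g. duplicate rsid)."""


def _row_problem(row) -> str | None:
    """Return a reason string if the row violates an invariant, else None."""
    ea, oa = row["ea"], row["oa"]
    if ea not in _VALID_ALLELES or oa not in _VALID_ALLELES:
        return "invalid_allele"
    if ea == oa:
        return "ea_equals_oa"
    if not np.isfinite(row["beta"]):
        return "nonfinite_beta"
    if not (np.isfinite(row["se"]) and row["se"] > 0):
        return "nonpositive_se"
    if not (0 < row["pval"] <= 1):
        return "pval_out_of_range"
    if not (np.isfinite(row["n"]) and row["n"] > 0):
        return "nonpositive_n"
    eaf = row["eaf"]
    if not (np.isnan(eaf) or 0 <= eaf <= 1):
        return "eaf_out_of_range"
    return None


@dataclass
class GwasTable:
    """Per-SNV association records for one trait.

    Parameters
    ----------
    trait
        Label, one of ``iron | ferritin | tfsat | tibc | outcome`` (other
        labels are accepted and default to direction +1).
    df
        DataFrame with the :data:`REQUIRED_COLUMNS`; rsids unique.
    direction_sign
        +1 or -1: the direction of the trait relative to systemic iron
        status (-1 for TIBC).  Inferred from ``trait`` when omitted.
    rejected
        Rows rejected on read, with a ``reason`` column.
    """

    trait: str
    df: pd.DataFrame
    direction_sign: int = 0
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REQUIRED_COLUMNS + ["reason"])
    )

    def __post_init__(self) -> None:
        if self.direction_sign == 0:
            self.direction_sign = TRAIT_SIGNS.get(self.trait, 1)
        if self.direction_sign not in (1, -1):
            raise ValidationError(f"direction_sign must be +1/-1, got {self.direction_sign}")
        missing = [c for c in REQUIRED_COLUMNS if c not in self.df.columns]
        if missing:
            raise FormatError(f"missing required column(s): {missing}")
        dup = self.df["rsid"][self.df["rsid"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate rsid(s): {sorted(set(dup))}")
        self.df = self.df.reset_index(drop=True)
        self._index = {r: i for i, r in enumerate(self.df["rsid"])}

    def __len__(self) -> int:
        return len(self.df)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def get(self, rsid: str) -> pd.Series:
        return self.df.iloc[self._index[rsid]]

    @property
    def rsids(self) -> list[str]:
        return list(self.df["rsid"])


@dataclass
class HarmonizedSet:
    """J instruments x K exposures plus the outcome, on one orientation.

    ``bx``/``sx`` are J x K exposure effects and standard errors, ``by``/
    ``sy`` the outcome log-odds effects; ``orientation`` maps each rsid to
    its harmonized (effect allele, other allele) pair; ``dropped`` lists
    every input rsid that did not survive, with a reason.
    """

    rsids: list[str]
    exposures: list[str]
    bx: np.ndarray
    sx: np.ndarray
    by: np.ndarray
    sy: np.ndarray
    orientation: dict
    dropped: pd.DataFrame

    def __post_init__(self) -> None:
        self.bx = np.atleast_2d(np.asarray(self.bx, dtype=float))
        self.sx = np.atleast_2d(np.asarray(self.sx, dtype=float))
        self.by = np.asarray(self.by, dtype=float)
        self.sy = np.asarray(self.sy, dtype=float)
        j = len(self.rsids)
        if not (self.bx.shape[0] == self.sx.shape[0] == len(self.by) == len(self.sy) == j):
            raise ValidationError("inconsistent harmonized dimensions")
        if j and (np.any(self.sx <= 0) or np.any(self.sy <= 0)):
            raise ValidationError("all standard errors must be positive")

    @property
    def n_snv(self) -> int:
        return len(self.rsids)

    @property
    def n_exposure(self) -> int:
        return self.bx.shape[1] if self.n_snv else len(self.exposures)

    def subset(self, keep) -> "HarmonizedSet":
        """New HarmonizedSet restricted to positions ``keep`` (indices or bool mask)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        rsids = [self.rsids[i] for i in keep]
        return HarmonizedSet(
            rsids=rsids,
            exposures=list(self.exposures),
            bx=self.bx[keep],
            sx=self.sx[keep],
            by=self.by[keep],
            sy=self.sy[keep],
            orientation={r: self.orientation[r] for r in rsids},
            dropped=self.dropped.copy(),
        )


def read_sumstats(path, trait: str) -> GwasTable:
    """Read a summary-statistic TSV into a validated :class:`GwasTable`.

    Rows violating per-record invariants (se <= 0, p outside (0,1], bad
    alleles, ...) are rejected and reported on ``table.rejected``; a
    missing required column raises :class:`FormatError` and a duplicate
    rsid :class:`ValidationError`.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={"rsid": str, "chr": str, "ea": str, "oa": str},
        na_values=["."],
        keep_default_na=True,
        float_precision="round_trip",
    )
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s): {missing}")
    df = df[REQUIRED_COLUMNS].copy()
    for col in ("pos", "eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    reasons = df.apply(_row_problem, axis=1)
    bad = df[reasons.notna()].copy()
    bad["reason"] = reasons[reasons.notna()]
    good = df[reasons.isna()].reset_index(drop=True)
    return GwasTable(trait=trait, df=good, rejected=bad.reset_index(drop=True))


def write_sumstats(table: GwasTable, path) -> None:
    """Write a :class:`GwasTable` in the TSV dialect read by :func:`read_sumstats`."""
    out = table.df.copy()
    out["eaf"] = out["eaf"].map(lambda v: "." if pd.isna(v) else repr(float(v)))
    for col in ("beta", "se", "pval"):
        out[col] = out[col].map(lambda v: repr(float(v)))
    out.to_csv(path, sep="\t", index=False)


def canonical_orientation(ea: str, oa: str) -> tuple[str, str]:
    """Coding-independent orientation for an allele pair.

    Among the four equivalent codings (as given, swapped, strand
    complement, complement swapped) return the lexicographically smallest
    (ea, oa) tuple.  The result depends only on the unordered pair up to
    strand, so any input coding of the same SNV maps to the same
    orientation.
    """
    cea, coa = _COMPLEMENT[ea], _COMPLEMENT[oa]
    return min((ea, oa), (oa, ea), (cea, coa), (coa, cea))


def is_palindromic(ea: str, oa: str) -> bool:
    return _COMPLEMENT[ea] == oa


def _align_to(rec, canon: tuple[str, str]):
    """Re-sign a record onto the canonical orientation.

    Returns (beta, se, eaf_on_canonical_ea) or None when no swap or
    strand flip reconciles the allele pairs.  Palindromic pairs are
    label-aligned here; the frequency check happens in :func:`harmonize`.
    """
    ea, oa = rec["ea"], rec["oa"]
    pair = (ea, oa)
    comp = (_COMPLEMENT[ea], _COMPLEMENT[oa])
    eaf = rec["eaf"]
    if pair == canon or comp == canon:
        return rec["beta"], rec["se"], eaf
    if pair[::-1] == canon or comp[::-1] == canon:
        return -rec["beta"], rec["se"], (1.0 - eaf) if np.isfinite(eaf) else np.nan
    return None


def harmonize(
    exposures: list[GwasTable],
    outcome: GwasTable,
    palindrome_maf_cut: float = 0.42,
    rsids: list[str] | None = None,
) -> HarmonizedSet:
    """Harmonize exposure and outcome tables onto one orientation per SNV.

    Parameters
    ----------
    exposures
        K exposure tables (typically iron, ferritin, TfSat, TIBC).
    outcome
        Outcome table (log-odds scale).
    palindrome_maf_cut
        A palindromic SNV is kept only when min(eaf, 1-eaf) is below this
        cut in *every* table (frequency informative enough to identify
        the shared allele); it is then aligned so all tables agree on
        which allele is the minor one.
    rsids
        Optional explicit instrument list; defaults to the union of all
        input rsids (so every record is accounted for in the drop log).

    Notes
    -----
    The output is invariant to the allele coding of every input table:
    swapping ea/oa and negating beta (and/or strand-complementing both
    alleles) in any table yields an identical :class:`HarmonizedSet`,
    and re-harmonizing already-harmonized tables is the identity.
    """
    tables = list(exposures) + [outcome]
    if rsids is None:
        seen: dict[str, None] = {}
        for t in tables:
            for r in t.rsids:
                seen.setdefault(r, None)
        rsids = list(seen)

    kept: list[str] = []
    orientation: dict = {}
    rows_bx, rows_sx, rows_by, rows_sy = [], [], [], []
    dropped: list[tuple[str, str]] = []

    for rsid in rsids:
        absent = [t.trait for t in tables if rsid not in t]
        if absent:
            dropped.append((rsid, f"missing_in_{absent[0]}"))
            continue
        recs = [t.get(rsid) for t in tables]
        canon = canonical_orientation(recs[0]["ea"], recs[0]["oa"])
        aligned = []
        fail = None
        for rec in recs:
            a = _align_to(rec, canon)
            if a is None:
                fail = "allele_mismatch"
                break
            aligned.append(a)
        if fail is None and is_palindromic(*canon):
            eafs = np.array([a[2] for a in aligned])
            if np.any(~np.isfinite(eafs)):
                fail = "palindromic_missing_eaf"
            elif np.any(np.minimum(eafs, 1 - eafs) >= palindrome_maf_cut):
                fail = "palindromic_ambiguous"
            else:
                # Align by matching minor allele against the first table.
                ref_minor = eafs[0] < 0.5
                aligned = [
                    (b, s, f) if (f < 0.5) == ref_minor else (-b, s, 1 - f)
                    for (b, s, f) in aligned
                ]
        if fail is not None:
            dropped.append((rsid, fail))
            continue
        kept.append(rsid)
        orientation[rsid] = canon
        rows_bx.append([a[0] for a in aligned[:-1]])
        rows_sx.append([a[1] for a in aligned[:-1]])
        rows_by.append(aligned[-1][0])
        rows_sy.append(aligned[-1][1])

    k = len(exposures)
    return HarmonizedSet(
        rsids=kept,
        exposures=[t.trait for t in exposures],
        bx=np.array(rows_bx, dtype=float).reshape(len(kept), k),
        sx=np.array(rows_sx, dtype=float).reshape(len(kept), k),
        by=np.array(rows_by, dtype=float),
        sy=np.array(rows_sy, dtype=float),
        orientation=orientation,
        dropped=pd.DataFrame(dropped, columns=["rsid", "reason"]),
    )
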