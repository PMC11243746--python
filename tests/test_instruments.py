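"""instrument_selection: strategies, clumping, proxies, exclusions, F, power."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from ferromr.instruments import (
    AnnotationTable,
    LDMatrix,
    MHC_REGION_GRCH37,
    PowerSpec,
    clump,
    exclude_mhc,
    exclude_pleiotropic,
    f_statistic,
    find_proxy,
    instrument_strength,
    is_direction_consistent,
    mr_power,
    select_instruments,
    snv_r2,
)
from ferromr.simulate import SynthConfig, simulate_study

from .conftest import make_table

SIGNS = (1, 1, 1, -1)


# ------------------------------------------------- direction consistency


def test_direction_consistent_examples():
    assert is_direction_consistent((0.1, 0.2, 0.05, -0.3), SIGNS)
    assert not is_direction_consistent((0.1, 0.2, 0.05, 0.3), SIGNS)
    assert not is_direction_consistent((0.0, 0.2, 0.05, -0.3), SIGNS)  # zero beta
    assert not is_direction_consistent((np.nan, 0.2, 0.05, -0.3), SIGNS)


def test_direction_consistent_all_16_sign_patterns():
    for pattern in itertools.product((-1.0, 1.0), repeat=4):
        betas = tuple(0.1 * p for p in pattern)
        oriented = [b * s for b, s in zip(betas, SIGNS)]
        brute = all(o > 0 for o in oriented) or all(o < 0 for o in oriented)
        assert is_direction_consistent(betas, SIGNS) == brute


# ---------------------------------------------------------- strategies


def _four_tables(rows_per_trait):
    traits = ("iron", "ferritin", "tfsat", "tibc")
    return [make_table(t, rows_per_trait[t]) for t in traits]


def test_select_examples():
    # rs1: significant everywhere, consistent -> all strategies.
    # rs2: one p above threshold, consistent -> strategies 2 and 3 only.
    tables = _four_tables({
        "iron": [{"beta": 0.1, "pval": 1e-9}, {"beta": 0.1, "pval": 1e-9}],
        "ferritin": [{"beta": 0.1, "pval": 1e-10}, {"beta": 0.1, "pval": 1e-9}],
        "tfsat": [{"beta": 0.1, "pval": 1e-12}, {"beta": 0.1, "pval": 1e-9}],
        "tibc": [{"beta": -0.1, "pval": 1e-9}, {"beta": -0.1, "pval": 1e-7}],
    })
    assert select_instruments(tables, 1) == ["rs1"]
    assert select_instruments(tables, 2) == ["rs1", "rs2"]
    assert select_instruments(tables, 3) == ["rs1", "rs2"]


def test_select_requires_four_tables():
    tables = _four_tables({t: [{}] for t in ("iron", "ferritin", "tfsat", "tibc")})
    with pytest.raises(ValueError):
        select_instruments(tables[:3], 1)
    with pytest.raises(ValueError):
        select_instruments(tables, 4)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_strategy_nesting(seed):
    study = simulate_study(SynthConfig(seed=seed, n_snv=40))
    s1 = set(select_instruments(study.exposures, 1))
    s2 = set(select_instruments(study.exposures, 2))
    s3 = set(select_instruments(study.exposures, 3))
    assert s1 <= s2 <= s3


def test_select_brute_force_oracle():
    study = simulate_study(SynthConfig(seed=9, n_snv=40))
    tables = study.exposures
    signs = [t.direction_sign for t in tables]
    for strategy in (1, 2, 3):
        got = set(select_instruments(tables, strategy))
        expect = set()
        for r in tables[0].rsids:
            recs = [t.get(r) for t in tables]
            sig = [rec["pval"] < 5e-8 for rec in recs]
            betas = [rec["beta"] for rec in recs]
            if strategy == 1:
                ok = all(sig)
            elif strategy == 2:
                ok = any(sig) and is_direction_consistent(betas, signs)
            else:
                ok = any(sig)
            if ok:
                expect.add(r)
        assert got == expect


# ------------------------------------------------------------- clumping


def test_clump_dominated_pair():
    ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.5], [0.5, 1.0]]))
    cands = pd.DataFrame({"rsid": ["rs1", "rs2"], "pval": [1e-12, 1e-9]})
    kept, warnings = clump(cands, ld)
    assert kept == ["rs1"] and not warnings


def test_clump_identity_ld_keeps_all():
    ld = LDMatrix([f"rs{i}" for i in range(1, 6)], np.eye(5))
    cands = pd.DataFrame({"rsid": [f"rs{i}" for i in range(1, 6)],
                          "pval": [1e-9, 1e-12, 1e-10, 1e-8, 1e-11]})
    kept, _ = clump(cands, ld)
    assert sorted(kept) == sorted(cands["rsid"])
    assert kept == list(cands.sort_values("pval")["rsid"])  # acceptance order


def test_clump_absent_snv_warns_and_keeps():
    ld = LDMatrix(["rs1"], np.array([[1.0]]))
    cands = pd.DataFrame({"rsid": ["rs1", "rsX"], "pval": [1e-9, 1e-10]})
    kept, warnings = clump(cands, ld)
    assert set(kept) == {"rs1", "rsX"}
    assert any("rsX" in w for w in warnings)


def _greedy_oracle(cands, ld, r2_max):
    order = sorted(cands.itertuples(index=False),
                   key=lambda t: (t.pval, getattr(t, "pos", 0), t.rsid))
    out = []
    for row in order:
        if all((ld.get(row.rsid, k) or 0.0) < r2_max for k in out):
            out.append(row.rsid)
    return out


def test_clump_greedy_replay_oracle():
    rng = np.random.default_rng(4)
    n = 10
    rsids = [f"rs{i}" for i in range(n)]
    a = rng.uniform(0, 1, size=(n, n))
    r2 = np.clip((a + a.T) / 2, 0, 1)
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(rsids, r2)
    cands = pd.DataFrame({"rsid": rsids, "pval": rng.uniform(1e-12, 1e-8, n),
                          "pos": np.arange(n)})
    for r2_max in (0.01, 0.1, 0.5):
        kept, _ = clump(cands, ld, r2_max)
        assert kept == _greedy_oracle(cands, ld, r2_max)
        # pairwise independence of the clumped set
        for x, y in itertools.combinations(kept, 2):
            assert ld.get(x, y) < r2_max


def test_clump_tie_break_at_equal_p():
    ld = LDMatrix(["rsB", "rsA"], np.array([[1.0, 0.9], [0.9, 1.0]]))
    cands = pd.DataFrame({"rsid": ["rsB", "rsA"], "pval": [1e-9, 1e-9],
                          "pos": [200, 100]})
    kept, _ = clump(cands, ld)
    assert kept == ["rsA"]  # smaller position wins the tie


# -------------------------------------------------------------- proxies


def _proxy_panel():
    rsids = ["rsM", "rsP1", "rsP2", "rsP3"]
    r2 = np.eye(4)
    r2[0, 1] = r2[1, 0] = 0.90
    r2[0, 2] = r2[2, 0] = 0.85
    r2[0, 3] = r2[3, 0] = 0.70
    return LDMatrix(rsids, r2)


def test_find_proxy_argmax_and_threshold():
    ld = _proxy_panel()
    assert find_proxy("rsM", ld, ["rsP1", "rsP2", "rsP3"]) == "rsP1"
    assert find_proxy("rsM", ld, ["rsP3"]) is None  # best r2 = 0.7 < 0.8
    assert find_proxy("rsQ", ld, ["rsP1"]) is None  # missing SNV unknown to panel


def test_find_proxy_tie_break():
    rsids = ["rsM", "rsB", "rsA"]
    r2 = np.eye(3)
    r2[0, 1] = r2[1, 0] = 0.9
    r2[0, 2] = r2[2, 0] = 0.9
    ld = LDMatrix(rsids, r2)
    # equal r2: smaller position wins, then lexicographic rsid
    assert find_proxy("rsM", ld, ["rsB", "rsA"], positions={"rsB": 10, "rsA": 20}) == "rsB"
    assert find_proxy("rsM", ld, ["rsB", "rsA"]) == "rsA"


def test_find_proxy_brute_force_oracle():
    rng = np.random.default_rng(12)
    n = 8
    rsids = [f"rs{i}" for i in range(n)]
    a = rng.uniform(0.5, 1.0, size=(n, n))
    r2 = (a + a.T) / 2
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix(rsids, np.clip(r2, 0, 1))
    avail = rsids[1:]
    got = find_proxy("rs0", ld, avail, r2_min=0.8)
    best = max((c for c in avail if ld.get("rs0", c) >= 0.8),
               key=lambda c: (ld.get("rs0", c), [-ord(x) for x in c]),
               default=None)
    assert got == best


# ------------------------------------------------------------------ MHC


def test_exclude_mhc_boundaries():
    chrom, lo, hi = MHC_REGION_GRCH37
    rows = pd.DataFrame({
        "rsid": ["in", "lo", "hi", "before", "after", "otherchr"],
        "chr": ["6", "6", "6", "6", "6", "7"],
        "pos": [30_000_000, lo, hi, lo - 1, hi + 1, 30_000_000],
    })
    kept, removed = exclude_mhc(rows)
    assert set(removed["rsid"]) == {"in", "lo", "hi"}  # inclusive ends
    assert set(kept["rsid"]) == {"before", "after", "otherchr"}


def test_exclude_mhc_chr_prefix():
    rows = pd.DataFrame({"rsid": ["a"], "chr": ["chr6"], "pos": [30_000_000]})
    kept, removed = exclude_mhc(rows)
    assert len(removed) == 1 and len(kept) == 0


# ------------------------------------------------------ confounders etc.


def test_exclude_pleiotropic():
    ann = AnnotationTable(pd.DataFrame({
        "rsid": ["rs1", "rs2"],
        "trait": ["smoking", "bmi"],
        "pval": [1e-10, 1e-6],  # rs2 above threshold: kept
    }))
    outcome = make_table("outcome", [{"pval": 0.5}, {"pval": 0.5},
                                     {"pval": 1e-9}])
    kept, removed = exclude_pleiotropic(["rs1", "rs2", "rs3"], ann, outcome)
    assert kept == ["rs2"]
    assert dict(zip(removed["rsid"], removed["reason"])) == {
        "rs1": "confounder:smoking", "rs3": "outcome_association"
    }


def test_exclude_pleiotropic_set_algebra_oracle():
    rng = np.random.default_rng(3)
    rsids = [f"rs{i + 1}" for i in range(20)]  # matches make_table naming
    ann = AnnotationTable(pd.DataFrame({
        "rsid": rng.choice(rsids, 10),
        "trait": ["t"] * 10,
        "pval": rng.uniform(1e-12, 1e-4, 10),
    }))
    outcome = make_table("outcome",
                         [{"pval": p} for p in rng.uniform(1e-12, 1.0, 20)])
    kept, removed = exclude_pleiotropic(rsids, ann, outcome)
    bad_ann = set(ann.df[ann.df["pval"] < 5e-8]["rsid"])
    bad_out = {r for r in rsids if outcome.get(r)["pval"] < 5e-8}
    assert set(kept) == set(rsids) - bad_ann - bad_out
    assert set(kept) | set(removed["rsid"]) == set(rsids)


# --------------------------------------------------- strength and power


def test_f_statistic_examples():
    assert f_statistic(0.0, 1, 1000) == 0.0
    assert f_statistic(0.01, 1, 163_511) == pytest.approx(1651.6, abs=0.05)
    with pytest.raises(ValueError):
        f_statistic(1.0, 1, 1000)
    with pytest.raises(ValueError):
        f_statistic(0.1, 5, 6)


@given(r2=st.floats(0.001, 0.5), n=st.floats(100, 1e6))
def test_f_statistic_monotone(r2, n):
    assert f_statistic(r2 + 1e-3, 1, n) > f_statistic(r2, 1, n)
    assert f_statistic(r2, 1, n + 100) > f_statistic(r2, 1, n)


def test_snv_r2_paths():
    assert snv_r2(0.1, 0.25) == pytest.approx(2 * 0.25 * 0.75 * 0.01)
    z2 = (0.1 / 0.02) ** 2
    assert snv_r2(0.1, None, n=1000, se=0.02) == pytest.approx(z2 / (z2 + 998))
    with pytest.raises(ValueError):
        snv_r2(0.1, None)


def test_instrument_strength_weak_flag():
    table = make_table("iron", [
        {"beta": 0.2, "eaf": 0.3, "n": 50_000.0},   # strong
        {"beta": 0.005, "eaf": 0.3, "n": 5_000.0},  # weak
    ])
    s = instrument_strength(table, ["rs1", "rs2"])
    assert not s[0].weak and s[0].f_stat > 10
    assert s[1].weak and s[1].f_stat < 10


def test_power_null_or_floor():
    p = mr_power(PowerSpec(n_outcome=50_000, case_fraction=0.1,
                           r2_sum=0.01, odds_ratio=1.0))
    assert p.power == pytest.approx(stats.norm.cdf(-stats.norm.ppf(0.975)),
                                    abs=1e-12)


def test_power_monotone():
    base = dict(n_outcome=50_000, case_fraction=0.1, r2_sum=0.01, odds_ratio=1.2)
    p0 = mr_power(PowerSpec(**base)).power
    assert mr_power(PowerSpec(**{**base, "n_outcome": 100_000})).power > p0
    assert mr_power(PowerSpec(**{**base, "r2_sum": 0.02})).power > p0
    assert mr_power(PowerSpec(**{**base, "odds_ratio": 1.4})).power > p0
    # symmetric in ln OR
    assert mr_power(PowerSpec(**{**base, "odds_ratio": 1 / 1.2})).power == \
        pytest.approx(p0)


def test_power_monte_carlo_oracle():
    """Formula power equals the MC rejection rate of the IVW z-test on data
    simulated at the same design, within 3 MC standard errors."""
    spec = PowerSpec(n_outcome=40_000, case_fraction=0.2, r2_sum=0.015,
                     odds_ratio=1.15)
    analytic = mr_power(spec).power
    rng = np.random.default_rng(2024)
    reps, j = 20_000, 10
    f = np.full(j, 0.3)
    # standardized exposure effects summing to r2_sum of explained variance
    bx = np.sqrt(spec.r2_sum / (j * 2 * f * (1 - f)))
    sy = 1.0 / np.sqrt(2 * f * (1 - f) * spec.n_outcome
                       * spec.case_fraction * (1 - spec.case_fraction))
    by = np.log(spec.odds_ratio) * bx + rng.normal(0, sy, size=(reps, j))
    w = bx**2 / sy**2
    z = (by / bx * w).sum(axis=1) / np.sqrt(w.sum())
    mc = np.mean(np.abs(z) > stats.norm.ppf(0.975))
    tol = 3 * np.sqrt(analytic * (1 - analytic) / reps)
    assert abs(mc - analytic) <= tol


# ------------------------------------------------------------- LDMatrix


def test_ldmatrix_validation():
    with pytest.raises(ValueError):
        LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))  # asymmetric
    with pytest.raises(ValueError):
        LDMatrix(["a", "b"], np.array([[0.9, 0.5], [0.5, 1.0]]))  # diag != 1
    with pytest.raises(ValueError):
        LDMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))  # r2 > 1
    with pytest.raises(ValueError):
        LDMatrix(["a"], np.eye(2))  # shape mismatch


def test_ldmatrix_tsv_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    a = rng.uniform(0, 0.5, size=(4, 4))
    r2 = (a + a.T) / 2
    np.fill_diagonal(r2, 1.0)
    ld = LDMatrix([f"rs{i}" for i in range(4)], r2)
    path = tmp_path / "ld.tsv"
    ld.to_tsv(path)
    back = LDMatrix.read_tsv(path)
    assert back.rsids == ld.rsids
    np.testing.assert_allclose(back.r2, ld.r2)
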