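"""Shared fixtures: seeded synthetic studies and harmonized sets."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from ferromr.simulate import SynthConfig, simulate_study
from ferromr.sumstats import GwasTable, HarmonizedSet, REQUIRED_COLUMNS, harmonize

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_table(trait, rows):
    """GwasTable from a list of dicts with defaults for unspecified columns."""
    defaults = {
        "rsid": None, "chr": "1", "pos": 1_000_000, "ea": "A", "oa": "G",
        "eaf": 0.3, "beta": 0.1, "se": 0.01, "pval": 1e-10, "n": 10_000.0,
    }
    records = []
    for i, row in enumerate(rows):
        rec = dict(defaults)
        rec["rsid"] = f"rs{i + 1}"
        rec["pos"] = 1_000_000 + 50_000 * i
        rec.update(row)
        records.append(rec)
    return GwasTable(trait=trait, df=pd.DataFrame(records)[REQUIRED_COLUMNS])


def make_harmonized(bx, by, sx=None, sy=None, exposures=None):
    """HarmonizedSet directly from effect arrays (J x K exposures)."""
    bx = np.atleast_2d(np.asarray(bx, dtype=float))
    if bx.shape[0] == 1 and len(np.asarray(by)) > 1:
        bx = bx.T
    j, k = bx.shape
    sx = np.full((j, k), 0.01) if sx is None else np.broadcast_to(
        np.asarray(sx, dtype=float), (j, k)).copy()
    sy = np.full(j, 0.05) if sy is None else np.asarray(sy, dtype=float)
    rsids = [f"rs{i + 1}" for i in range(j)]
    return HarmonizedSet(
        rsids=rsids,
        exposures=exposures or [f"x{i}" for i in range(k)],
        bx=bx, sx=sx, by=np.asarray(by, dtype=float), sy=sy,
        orientation={r: ("A", "G") for r in rsids},
        dropped=pd.DataFrame(columns=["rsid", "reason"]),
    )


def spawn_seeds(root_seed, n):
    """Deterministic child seeds below 2**31."""
    ss = np.random.SeedSequence(root_seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


@pytest.fixture(scope="session")
def default_study():
    """One study at package defaults: 60 SNVs, paper-scaled cohort sizes."""
    return simulate_study(SynthConfig(seed=11))


@pytest.fixture(scope="session")
def strong_harmonized():
    """J=50 all-valid harmonized set with strong instruments (theta=0.2)."""
    cfg = SynthConfig(seed=7, n_snv=50, ld_block_size=1, ld_decay=0.0,
                      n_iron=100_000, n_ferritin=100_000, n_tfsat=100_000,
                      n_tibc=100_000, n_outcome=50_000, case_fraction=0.1,
                      theta=0.2, idio_sd=0.0, invalid_fraction=0.0,
                      n_confounder_snvs=0)
    s = simulate_study(cfg)
    return harmonize(s.exposures, s.outcome)
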