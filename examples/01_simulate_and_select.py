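"""Simulate a synthetic iron-status study and select instruments.

The generator emits four exposure GWAS tables (serum iron, ferritin,
transferrin saturation, TIBC), a binary kidney-disease outcome table, a
block-diagonal LD matrix and SNV annotations — everything the pipeline
needs, with known ground truth for checking estimates later.
"""

from ferromr import SynthConfig, select_instruments, simulate_study
from ferromr.instruments import instrument_strength

study = simulate_study(SynthConfig(seed=7))

print("exposure tables:", [t.trait for t in study.exposures])
print("one table's head:")
print(study.exposures[0].df.head(3).to_string(index=False))

# Three nested selection strategies: (1) genome-wide significant and
# direction-consistent in all four biomarkers, (2) in serum iron,
# ferritin and transferrin saturation, (3) in serum iron alone.
for strategy in (1, 2, 3):
    sel = select_instruments(study.exposures, strategy)
    print(f"strategy {strategy}: {len(sel)} candidate SNVs")

s1 = set(select_instruments(study.exposures, 1))
s3 = set(select_instruments(study.exposures, 3))
print("strategy 1 is a subset of strategy 3:", s1 <= s3)

# Instrument strength against the serum-iron GWAS: F > 10 is the usual
# weak-instrument rule of thumb.
strengths = instrument_strength(study.exposures[0], sorted(s1)[:5])
for s in strengths:
    print(f"{s.rsid}: R^2 = {s.r2_exposure:.4f}, F = {s.f_stat:.1f}, "
          f"weak = {s.weak}")
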