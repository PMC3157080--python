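"""Screen probes for fidelity across tissue preservation and specimen source.

Builds a synthetic panel of 30 probes — 20 engineered to be concordant
between matched FFPE and fresh-frozen aliquots and stable between TUR and
cystectomy specimens, 10 engineered with no FFPE/FF concordance — then runs
the two-part high-fidelity screen at its standard design (32 matched pairs;
30 TUR vs 25 cystectomy samples).
"""

import pandas as pd

from nodalrisk import (
    FidelityCriteria,
    SimulationConfig,
    generate_matched_pairs,
    generate_specimen_sets,
    screen_panel,
)
from nodalrisk.io import ExpressionMatrix

# 20 good probes: high FFPE/FF concordance
good_cfg = SimulationConfig(n_samples=32, n_probes=20, n_informative=0,
                            pair_concordance=0.85, seed=1)
ffpe_g, ff_g = generate_matched_pairs(good_cfg)

# 10 bad probes: independent FFPE and FF values (no concordance)
bad_cfg = SimulationConfig(n_samples=32, n_probes=10, n_informative=0,
                           pair_concordance=0.0, seed=2)
ffpe_b, ff_b = generate_matched_pairs(bad_cfg)

ffpe = ExpressionMatrix(values=pd.concat(
    [ffpe_g.values.add_prefix("good_"), ffpe_b.values.add_prefix("bad_")], axis=1))
ff = ExpressionMatrix(values=pd.concat(
    [ff_g.values.add_prefix("good_"), ff_b.values.add_prefix("bad_")], axis=1))

# TUR and cystectomy groups drawn from the same distribution (no source shift)
spec_cfg = SimulationConfig(n_samples=30, n_probes=30, n_informative=0, seed=3)
tur, cyst = generate_specimen_sets(spec_cfg, n_tur=30, n_cyst=25)
tur = ExpressionMatrix(values=tur.values.set_axis(ffpe.probe_ids, axis=1))
cyst = ExpressionMatrix(values=cyst.values.set_axis(ffpe.probe_ids, axis=1))

report = screen_panel(ffpe, ff, tur, cyst, ffpe.probe_ids, FidelityCriteria())
passing = report[report.pass_overall]
print(report[["r", "p_corr", "p_diff", "pass_overall"]].round(4).head(8))
print(f"\n{len(passing)}/{len(report)} probes pass the high-fidelity screen")
print("passing probes engineered concordant:",
      sum(p.startswith("good_") for p in passing.index))
print("passing probes engineered null:",
      sum(p.startswith("bad_") for p in passing.index))
# A passing probe correlates positively across preservation methods
# (p < 0.025, one-tailed) AND shows no TUR-vs-cystectomy shift (p >= 0.01).
# Expect nearly all 20 concordant probes to pass and the 10 null probes to
# fail at about the 2.5% false-pass rate.
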