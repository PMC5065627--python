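"""Simulate the two simplified clock models for WT and the lwd1 lwd2 mutant.

Builds Model II (LWD1 activates both PRR9 and CCA1) with an archived
oscillatory parameter set, simulates both genotypes with the adaptive
solver, and prints the CCA1 period and mean level of each.  The mutant
keeps a (faster) rhythm with reduced CCA1 — the phenotype the screen
selects for.
"""

import numpy as np

from lwdclock import MODEL_II, build_model, simulate
from lwdclock.network import LWD1LWD2, WT, apply_genotype
from lwdclock.rhythm import peak_period_oracle
from lwdclock.synthetic import ARCHIVED_MODEL_II_SET

model = build_model(MODEL_II).with_parameters(ARCHIVED_MODEL_II_SET)

for genotype in (WT, LWD1LWD2):
    trace = simulate(apply_genotype(model, genotype), t_end=360.0)
    post = trace.time >= 120.0  # discard the transient
    y = trace.channel("CCA1")[post]
    period = peak_period_oracle(trace.time[post], y)
    print(f"{genotype.name:10s} CCA1 period {period:6.2f} time units, "
          f"mean level {y.mean():6.3f}")
print("\nPeriods are in dimensionless screen time; the screen normalises "
      "each set so the WT period reads 24 h. The lwd1lwd2 rhythm persists "
      "with a lower CCA1 level, as selected by the screen criteria.")
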