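"""Gene dosage on a circular chromosome and the insertion-density exponent.

Builds a fast-growth E. coli-like parameter set (C=40, D=20, tau=30 min),
checks the closed-form population dosage against the explicit age-structured
fork simulation, then samples an insertion landscape proportional to
dosage**3 and recovers the exponent from 3 kb bins.
"""

import numpy as np

from insertion_fate.core import GenomeSpec
from insertion_fate.coverage import sliding_coverage
from insertion_fate.dosage import (
    DosageParams,
    dosage_prediction_for,
    fit_dosage_exponent,
    mean_copy_number,
    simulated_mean_copy_number,
)
from insertion_fate.synth import SynthConfig, make_genome, sample_insertions

params = DosageParams(C_min=40, D_min=20, tau_min=30)
print("locus m      closed form   fork simulation")
for m in (0.0, 0.5, 1.0):
    sim, se = simulated_mean_copy_number(m, params, n_cells=100_000, seed=0)
    print(f"  {m:.1f}       {mean_copy_number(m, params):10.4f}   {sim:.4f} +- {se:.4f}")
print("-> ori loci average 4 copies/cell, ter loci ~1.59; the fork model and")
print("   the closed form 2**((C(1-m)+D)/tau) agree within Monte-Carlo error.\n")

cfg = SynthConfig(length_bp=500_000, n_insertions=100_000, alpha=3.0,
                  at_boost=0.0, essential_survival=1.0, seed=0)
ann = make_genome(cfg)
ins = sample_insertions(ann, cfg)
prof = sliding_coverage(ins.as_sites(), ann.spec, window_bp=3000, step_bp=3000)
fit = fit_dosage_exponent(prof, dosage_prediction_for(prof, cfg.dosage))
print(f"insertions sampled ~ dosage^3: fitted exponent alpha = "
      f"{fit.alpha:.3f} +- {fit.alpha_stderr:.3f} over {fit.n_bins} bins")
print("-> an exponent near 3 means the landscape is much steeper than the")
print("   dosage itself, the signature of an extra ori-biased insertion force.")
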