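"""Sister-lineage divergence separates switching from extrinsic-noise clones.

Simulates microcolonies (3 generations, sampled every 3 min) for one
telegraph-switching clone and one mean-matched clone with only extrinsic
fluctuations, and compares the time-averaged |expression difference|
between sister lineages.
"""

from insertion_fate.lineage import compare_divergence, sister_divergence
from insertion_fate.synth import (
    SynthConfig, assign_clone_phenotypes, make_genome, sample_insertions,
    simulate_microcolony,
)

cfg = SynthConfig(seed=1)
ann = make_genome(cfg)
ins = sample_insertions(ann, cfg)
clones = assign_clone_phenotypes(ins, ann, cfg)
switch = next(c for c in clones if c.clone_class == "rrn_switching")
normal = next(c for c in clones if c.clone_class == "normal")
mu_match = cfg.switch.stationary_mean

d_sw = [sister_divergence(simulate_microcolony(switch, cfg, seed=s)) for s in range(20)]
d_nm = [sister_divergence(simulate_microcolony(normal, cfg, seed=s, mu_override=mu_match))
        for s in range(20)]
print(f"mean divergence, switching clone: "
      f"{sum(r.colony_divergence for r in d_sw)/20:.1f} a.u.")
print(f"mean divergence, extrinsic clone: "
      f"{sum(r.colony_divergence for r in d_nm)/20:.1f} a.u. (same mean expression)")
comp = compare_divergence(d_sw, d_nm)
print(f"ratio = {comp.ratio:.2f}, rank-sum p = {comp.p_value:.2g} over 20+20 colonies")
print("-> sister lineages of a switching promoter drift far apart because the")
print("   on/off state is inherited and flips rarely; extrinsic fluctuations")
print("   decorrelate quickly, keeping sisters close.")
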