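"""Which gene lists co-occur with insertions, net of the dosage trend?

Generates the synthetic world (AT islands standing in for H-NS binding
tracts, essential genes, rrn operons), then scores each interval list
against 5000 density-preserving shuffles whose background is the 25 kb
sliding average of the insertions themselves.
"""

from insertion_fate.coverage import sliding_coverage
from insertion_fate.enrichment import enrichment_z
from insertion_fate.synth import SynthConfig, make_genome, sample_insertions

cfg = SynthConfig(seed=1)
ann = make_genome(cfg)
ins = sample_insertions(ann, cfg).as_sites()
bg = sliding_coverage(ins, ann.spec, window_bp=25_000, step_bp=2500)

print(f"{len(ins)} insertions on a {cfg.length_bp//1000} kb circular genome")
print(f"{'list':<22}{'observed':>10}{'null mean':>11}{'Z':>9}{'p_emp':>10}")
for name in ("hns_islands", "essential", "regulator_targets"):
    res = enrichment_z(ins, ann.intervals[name], bg, n_shuffles=5000, seed=2)
    print(f"{name:<22}{res.observed:>10.0f}{res.null_mean:>11.1f}"
          f"{res.z:>9.2f}{res.p_emp:>10.2g}")
print("-> AT islands (the H-NS proxy) are strongly enriched (Z >> 3) and")
print("   essential genes strongly depleted (Z << -3); unbiased regulator")
print("   targets sit near Z = 0. p_emp tests enrichment one-sidedly.")
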