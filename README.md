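# insertion-fate

Analysis toolkit for the early fate of a strong promoter inserted at random
positions across a circular bacterial chromosome. When a reporter cassette is
delivered genome-wide by transposition (TraDIS-style) and the resulting clones
are profiled by sequencing, flow cytometry, cell sorting and time-lapse
microscopy, several quantitative questions arise that this package answers
from processed tables alone:

- **Where do insertions land?** Circular sliding-window coverage of insertion
  sites, compared against the Cooper–Helmstetter gene-dosage prediction
  `n(m) = 2^((C(1−m)+D)/τ)` for a locus at relative ori→ter position *m* in a
  steady-state population with replication period *C*, division period *D*
  and doubling time *τ*. A log–log fit `log(obs) = intercept + α·log(dosage)`
  measures how much steeper the landscape is than dosage alone, and an
  explicit age-structured fork simulator serves as the sampling oracle.
- **Do insertions co-occur with particular gene sets** (nucleoid-protein
  binding tracts, essential genes)? Enrichment Z-scores against a shuffle
  null that redraws sites from the empirical large-scale insertion density,
  so genome-scale dosage trends are subtracted and only local association is
  scored.
- **Are insertion flanks AT-rich?** One-sided two-sample Kolmogorov–Smirnov
  test of window AT fractions, `D = sup_x (F_bg − F_ins)`, with the
  asymptotic p-value `exp(−2D²·n_A n_B/(n_A+n_B))`.
- **Which clones are noisy?** Per-clone mean/SD/CV² of single-cell
  fluorescence; a robust fit of the extrinsic-noise line `sd = c·mean`
  (slope fixed at 1 in log space, median/MAD baseline) flags steep-noise
  outliers; copy-number normalization expresses multi-insertion clones per
  promoter copy; growth-rate trends classify interference-driven clones.
- **Do noisy clones switch?** Sister-lineage divergence in microcolonies:
  the time average of |E₁(t) − E₂(t)| between the two sub-lineages of every
  division, compared between clone classes with a rank-sum test.

A fully seeded synthetic-data generator (`insertion_fate.synth`) emulates the
processed form of such experiments — annotated circular genomes with AT-rich
islands (a stand-in for H-NS binding tracts), dosage- and AT-biased insertion
landscapes with essential-gene depletion, clone expression with shared
extrinsic noise plus telegraph-switching ribosomal-interference clones,
fluorescence-gated sorting, and microcolony lineage trees — so every stage is
testable end to end without downloads.

## Worked example

```bash
python examples/02_enrichment_pattern.py
```

```
10000 insertions on a 500 kb circular genome
list                    observed  null mean        Z     p_emp
hns_islands                 2601     1232.4    41.70    0.0002
essential                     38      427.8   -19.54         1
regulator_targets            651      692.3    -1.60      0.95
```

2601 of 10 000 insertion sites fall inside AT islands versus 1232 expected
under 5000 density-preserving shuffles — enrichment at Z ≈ +42 even though
the null already reproduces the ori-biased density. Essential genes show the
mirror-image depletion (Z ≈ −20), and a neutral control list sits at Z ≈ −1.6.
The one-sided empirical p tests enrichment, hence `p_emp ≈ 1` for depleted
lists (their signal is in the sign of Z).

The other scripts in `examples/` each demonstrate one capability: dosage
landscapes and exponent recovery (α = 2.986 ± 0.017 when the truth is 3),
AT-bias KS testing, noise scaling (extrinsic coefficient 0.299 recovered for
a generator truth of 0.3, with the telegraph clone the unique flagged
outlier), lineage divergence (ratio 7.4 between switching and extrinsic
clones, rank-sum p < 1e−7), and the full reproducible pipeline. A thin CLI
(`insertion-fate coverage|dosage-profile|enrich|atbias|noise|lineage|run`)
wraps the same functions for shell use.

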