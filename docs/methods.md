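# Methods

This note documents the models implemented by the package, the parameters
that matter, what the synthetic-data generator does and does not emulate,
and the numerical and design choices made where the design was open. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Coordinates and containers

All analyses run on a single circular replicon with 0-based, half-open
coordinates; every position calculation is modulo the genome length `L`.
The replication origin (`ori_pos`) and terminus (`ter_pos`) split the circle
into two replichores; `ter_pos` defaults to the antipode but is an explicit
field because real chromosomes have slightly unequal arms. A feature crossing
the origin is stored as two BED records sharing an id; all overlap logic
merges records first, so a split feature behaves as one. Insertion tables
carry optional per-site weights (read counts); weights default to 1.0 and
every counting operation sums weights, so site-based and read-weighted
analyses use the same code path. Whether a coverage analysis should be
site- or weight-based is left to the caller (`InsertionSet.as_sites()`
drops weights); enrichment nulls always resample unit-weight sites because
per-site read counts in transposon sequencing are amplification-distorted.

## Gene dosage (Cooper–Helmstetter)

For a locus at relative position `m ∈ [0, 1]` along its replichore (0 at
ori, 1 at ter), the population-average copy number per cell in steady-state
exponential growth is

    n(m) = 2^((C·(1−m) + D)/τ)

with `C` the replication period, `D` the division lag and `τ` the doubling
time, all in minutes. Defaults are canonical fast-growth values C=40, D=20,
τ=30. The implementation also carries an explicit fork model: writing
`q = (C(1−m)+D)/τ`, a cell of age `a` holds `2^⌊q⌋` copies until all of
them are passed simultaneously by the forks of the next replication round at
age `â = τ(1 − frac(q))`, and twice as many afterwards; ages follow the
stationary density `u(a) ∝ 2^(−a/τ)` on `[0, τ]`. Averaging the fork model
over `u` reproduces the closed form exactly, and the Monte-Carlo version of
that average is the internal oracle (`simulated_mean_copy_number`). The
oracle draws ages by stratified inversion of the age CDF by default —
a quasi-Monte-Carlo choice that removes essentially all sampling variance
from the comparison while the reported standard error stays the
conservative iid estimate.

### Exponent fit

`fit_dosage_exponent` regresses `log(observed density)` on `log(predicted
dosage)` over identical bins after normalizing both profiles to mean 1
(the comparison is scale-free, and the fit is invariant under multiplying
either profile by a positive constant). Zero-count bins are dropped, not
pseudo-counted, and their number is reported; fewer than three usable bins
is an error.

### Time-dependent insertion hazard: an invariance result

`simulate_age_structured_insertions` exposes a hazard per locus copy
proportional to `(copy age/τ)^β`, where copy age is the time since the copy
was last replicated. A structural fact of the stationary population is worth
recording: for *any* per-copy hazard `h(s)` of copy age `s` (and likewise
any wall-time hazard), the expected position density factorizes as
`dosage(m) × constant`. All copies of a locus are replicated simultaneously
at cycle phase `â(m)`, so `s = (a − â) mod τ`; substituting into
`u(a)·n_m(a)` gives the weight `2·2^⌊q⌋·2^(−â/τ)·2^(−s/τ)·h(s)` on both age
branches, and `2^⌊q⌋·2^(1−â/τ) = 2^q = dosage(m)` — the copy-age integral is
m-independent. Consequently β reshapes finite-population fluctuations but
never the mean landscape, and β=0 is the exact sampling oracle for the
closed form. Landscapes genuinely steeper than dosage are generated
directly, with `sample_insertions` density ∝ `dosage^α` — the observable an
exponent fit actually measures. The package deliberately does not claim a
mechanistic route from time-dependent rates to α > 1.

## Coverage and asymmetry

`sliding_coverage` computes insertion weight per bp in a centered, half-open
window `[c − ⌊w/2⌋, c − ⌊w/2⌋ + w)` that wraps the origin, via a circular
cumulative sum (O(L + bins)). The display default is the 3 kb window; the
step (default 1 kb) is a free parameter. With step = window the tiles
partition the circle and total weight is conserved exactly.
`oriter_asymmetry` is (right-replichore mean − left-replichore mean) /
overall mean on the normalized profile ("right" = increasing coordinate from
ori), so it is scale-free; a profile symmetric about ori scores 0 and a
profile entirely on the right scores +2.

## Enrichment against a density-preserving null

`overlap_score` counts insertion weight inside the union of
(optionally flank-extended) intervals; intervals are merged before scoring,
so nothing is double-counted and whether source lists overlap is
irrelevant. The null redraws the same number of unit-weight sites from a
background density: a bin is chosen ∝ value × width, the position is uniform
within the bin. The background is, by default, the sliding average of the
observed insertions themselves, so the test is conditional on the empirical
large-scale density (dosage trend included) and scores only local
co-occurrence.

**Background window width.** The background must be smooth at the scale of
the features being tested, otherwise the null reproduces — and therefore
cancels — exactly the signal of interest: a 3 kb-smoothed background already
contains the density excess of kb-scale AT islands, forcing Z → 0 by
construction. The enrichment default is therefore a 25 kb window (an order
of magnitude above the island/gene scale, well below the replichore scale on
which dosage varies), while the 3 kb default is kept for display coverage.
The window is an explicit parameter everywhere.

**Z and p.** `Z = (observed − null mean)/null sd` over `n_shuffles`
(default 5000) shuffles, signed: enriched lists positive, depleted negative.
The empirical p-value uses the add-one rule `p = (1 + #extreme)/(1 + S)` in
a *fixed a-priori direction* (enrichment by default; `alternative="less"`
tests depletion). A min-tail p taken in the observed direction cannot be a
calibrated p-value (it is bounded near 0.5 and anti-conservative by a factor
of two), so the observed-direction mode (`alternative="auto"`) is provided
for exploration only. With the fixed direction the p-value is exactly
super-uniform under the null by exchangeability of the observed and shuffled
draws. A degenerate null (sd = 0, e.g. a list covering the whole genome)
sets a flag instead of a Z. `flank_coverage_enrichment` applies the same
machinery to a different statistic — the mean fraction of a fixed-width
window (default 10 kb) centered on each insertion that is covered by the
interval set — which asks whether the *surroundings* of insertions are
occupied rather than the sites themselves.

Shuffle randomness comes from one PCG64 generator seeded by the master seed
and consumed in shuffle order; results are reproducible given
(seed, n_shuffles).

## AT-content bias

Window AT fraction is (A+T)/(A+C+G+T) with N excluded from both counts,
computed by circular cumulative sums. Sample A = windows centered on
insertions; sample B = windows at uniform random positions (not
density-matched — the question is absolute AT preference). The one-sided
two-sample KS statistic `D = sup_x (F_B − F_A)` is computed by an exact ECDF
sweep over all sample points (no binning) and tests "insertion windows
stochastically AT-richer"; the p-value is the one-sided asymptotic
`exp(−2D²·n_A n_B/(n_A+n_B))`, which is conservative at these sample sizes.
The window default of 1 kb matches the scale of nucleoid-protein binding
tracts (up to a few kb). D is invariant under any strictly monotone
transform of both samples.

## Expression noise

Per-clone statistics use the sample (n−1) standard deviation;
`CV² = (sd/mean)²` is undefined (flagged) when the mean is not positive.
The extrinsic regime predicts sd = c·mean; the scaling fit fixes the
log–log slope at 1 and estimates `log c` as the median of `log(sd/mean)`,
with the residual scale the MAD rescaled by 1.4826 to a σ-equivalent.
Robust location/scale are essential because the outliers are the object of
interest and must not leak into the baseline. A clone is an outlier when its
*positive* residual exceeds `k × scale` (default k = 3.5, the conventional
robust cutoff). A free-slope ordinary regression is reported alongside as a
diagnostic; it should be ≈ 1 in a pure extrinsic cohort.

`normalize_by_copy_number` divides mean and sd by the promoter copy number,
leaving CV² unchanged. An immediate consequence — worth stating because it
constrains interpretation — is that noise classification is *invariant*
under copy-number normalization: outlier status depends on (mean, sd) only
through their ratio. Per-copy normalization therefore corrects
expression-*level* outliers (multi-insertion clones return to the
single-copy trend of mean expression) but cannot, by construction, change
which clones are classified as noise outliers. `growth_trend` is an
ordinary least-squares slope of mean expression on growth rate with a
"flat" label when |slope| is below a configurable fraction (default 5%) of
the mean expression per unit rate.

## Lineage divergence

For each division in a microcolony tree, the two descendant sub-lineages are
compared: at each shared time point, a side's expression is the mean over
its live sampled descendants, and the pair divergence is the time average of
|E₁(t) − E₂(t)|. The colony divergence is the mean over division pairs.
Averaging over descendants keeps the statistic well-defined after further
divisions; a "sisters" mode restricts each side to the immediate daughter.
Divergence is invariant under adding a constant to all series and scales
linearly under multiplicative rescaling; a mean-normalized variant (divide
by the colony mean) is provided for cross-clone comparison. Two sets of
colonies are compared by the ratio of mean divergences plus a two-sided
Mann–Whitney rank-sum p-value.

## Synthetic data: what it emulates, and what it does not

The generator produces the *processed form* of the experiment under study
conditions chosen once:

- **Genome** (default 500 kb, ori at 0, ter antipodal): per-base AT
  probability 0.50 background / 0.70 inside AT islands (20 islands,
  exponential lengths, mean 2.5 kb, min 0.8 kb). Identifying H-NS binding
  with AT islands is a generative rule mirroring their empirical
  correlation, not a biological claim. 30 essential genes (1 kb) are placed
  outside islands; 7 rRNA operons (3 kb, random orientation) avoid both —
  seven because that is the E. coli rRNA operon count, which is also why
  insertion into one is tolerated. A neutral 40-interval "regulator_targets"
  list is placed unconstrained as a control.
- **Insertions** (default n = 10 000): density ∝ `dosage(m)^α × (1 +
  at_boost·island)` with α = 3 and at_boost = 2; candidates inside essential
  genes survive with probability 0.1, and sampling continues until n accepted
  sites (so n is exact and depletion, not truncation, carries the signal).
- **Clone phenotypes:** a site within 1 kb of an island is *silenced*
  (expression × 0.1); a site inside an rRNA operon in the opposite
  orientation (drawn with probability 0.8, the dominant configuration for
  interference) is *rrn_switching*; 5% of clones carry 2–3 insertions
  resampled from the landscape.
- **Expression:** per cell, all insertions share one extrinsic factor
  `(1+η)`, `η ~ N(0, cv_ext)` with cv_ext = 0.3, truncated at 0 (fluorescence
  cannot be negative; truncated-normal noise rather than log-normal). Mean
  contribution scales with growth rate (ribosomal promoter) and with
  relative local dosage. Switching sites draw a per-cell telegraph state
  from the stationary occupancy `p_on = k_on/(k_on+k_off)` (defaults
  k_on = 0.01/min, k_off = 0.05/min, levels 400/20 a.u. — a stable OFF state
  with rare ON excursions), and their ON level declines with growth rate
  (interference from an increasingly busy operon).
- **Sorting:** a fluorescence gate reweights clone frequencies by each
  clone's in-gate cell fraction; repeated application emulates sorting
  rounds; gates are specified as pooled-fluorescence quantiles (bottom/top
  30% by default).
- **Microcolonies:** division exactly every τ (no size control — the lineage
  statistic does not need division-time variability), 3 generations sampled
  every 3 min, leaves observed one extra τ. Normal clones follow a
  mean-reverting (OU) multiplicative fluctuation (stationary cv 0.2,
  relaxation 60 min) inherited at division, so sisters start correlated;
  switching clones follow the telegraph process with state inherited at
  division; 2% multiplicative measurement jitter.

Everything is deterministic given (config, seed). What the generator does
*not* emulate: read-level sequencing artifacts (mappability, GC bias, PCR
jackpots), transposase sequence motifs, supercoiling gradients as mechanism
(only their net effect via α), autofluorescence background, cell-size
effects on fluorescence, and division-time variability. Passing tests on
this world therefore demonstrate that the estimators recover the structure
they target under realistic noise — not that real libraries are free of the
artifacts above.

## Problem sizes and defaults used in checks

The automated checks run the generator at its defaults (500 kb genome,
10⁴ insertions) and, where a scaling claim is involved, at n = 10⁵
insertions with 3 kb bins for exponent recovery, 10⁵ cells for the dosage
oracle, 200 replicates × 1000 shuffles for null calibration (lists of
20 × 5 kb intervals at n = 1000 sites, so in-list counts are large enough
for the normal approximation behind the |Z| > 1.96 check), 5000 shuffles
for the enrichment sign pattern, 5000 windows per side for the AT-bias
scenario, 100 clones × 1000 cells for noise recovery, and 20 + 20 colonies
for lineage divergence. The full 4.6 Mb scale is supported by configuration.

## Known limitations

- The shuffle null conditions on a *smoothed* version of the observed
  density; features wider than the background window are absorbed into the
  null and cannot be detected (this is the intended conditioning, but the
  window choice is a real degree of freedom, exposed everywhere).
- The asymptotic one-sided KS p-value is conservative for small samples and
  underflows to 0 below ~1e−308; no exact small-sample p is implemented.
- The telegraph simulator updates states on the sampling grid dt, which
  biases switch counts when `k·dt` is not ≪ 1; defaults keep `k·dt ≤ 0.15`.
- Copy-number normalization cannot alter CV²-based classifications (see
  above); claims that it removes *noise* outliers are not reproducible under
  these definitions, only claims about expression-level outliers are.
- Weight-based (read-count) enrichment is supported in the observed score
  but the null always resamples sites; a weight-resampling null would need a
  read-count error model the package does not have.
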