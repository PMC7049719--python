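"""Cooper-Helmstetter age-structured gene dosage.

In a steady-state exponentially growing population with replication period
``C``, division period ``D`` and doubling time ``tau``, the population-average
copy number of a locus at relative replichore position ``m`` (0 at ori, 1 at
ter) is ``2**((C*(1-m)+D)/tau)``. The module provides the closed form, binned
dosage profiles, a log-log exponent fit between observed insertion density and
predicted dosage, and an explicit fork simulator that reconstructs per-cell
copy numbers from the stationary age distribution (used as an internal
consistency oracle and as a time-dependent insertion-rate simulator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .core import GenomeSpec, InsertionSet
from .coverage import CoverageProfile, normalize_profile
from .errors import InsufficientDataError, ValidationError

__all__ = [
    "DosageParams",
    "TimeRateModel",
    "ExponentFit",
    "locus_relative_position",
    "mean_copy_number",
    "simulated_mean_copy_number",
    "dosage_profile",
    "dosage_prediction_for",
    "fit_dosage_exponent",
    "simulate_age_structured_insertions",
]


@dataclass(frozen=True)
class DosageParams:
    """C/D periods and doubling time, all in minutes.

    Defaults are canonical fast-growth E. coli values: C=40, D=20, tau=30
    (LB-like growth).
    """

    C_min: float = 40.0
    D_min: float = 20.0
    tau_min: float = 30.0

    def __post_init__(self) -> None:
        if self.C_min < 0 or self.D_min < 0:
            raise ValidationError("C and D must be >= 0")
        if self.tau_min <= 0:
            raise ValidationError("tau must be > 0")


@dataclass(frozen=True)
class TimeRateModel:
    """Power-law growth of the insertion hazard with copy age.

    ``beta`` is the exponent of the hazard per locus copy as a function of
    the time elapsed since that copy was last replicated; ``beta = 0`` is the
    pure-dosage (time-homogeneous) model.
    """

    beta: float = 0.0
    horizon_min: float = 60.0

    def __post_init__(self) -> None:
        if self.beta < 0:
            raise ValidationError("beta must be >= 0")
        if self.horizon_min <= 0:
            raise ValidationError("horizon must be > 0")


@dataclass(frozen=True)
class ExponentFit:
    """Result of the log-log fit log(observed) = intercept + alpha*log(predicted)."""

    alpha: float
    alpha_stderr: float
    intercept: float
    n_bins: int
    n_dropped: int = 0

    def __post_init__(self) -> None:
        if self.n_bins < 3:
            raise ValidationError("exponent fit needs >= 3 bins")


def locus_relative_position(p, genome: GenomeSpec):
    """Relative position m in [0, 1] along the replichore containing ``p``.

    m(ori) = 0 and m(ter) = 1 on both replichores; each arc ori->ter is
    normalized by its own length, so unequal replichores are handled.
    """
    L = genome.length_bp
    p = np.asarray(p, dtype=float)
    d_fwd = (p - genome.ori_pos) % L
    right = float(genome.right_replichore_bp)
    left = float(genome.left_replichore_bp)
    m = np.where(d_fwd <= right, d_fwd / right, (L - d_fwd) / left)
    if m.ndim == 0:
        return float(m)
    return m


def mean_copy_number(m, params: DosageParams):
    """Population-average copy number of a locus at relative position m."""
    m = np.asarray(m, dtype=float)
    out = 2.0 ** ((params.C_min * (1.0 - m) + params.D_min) / params.tau_min)
    if out.ndim == 0:
        return float(out)
    return out


def _per_cell_copies(ages: np.ndarray, m: np.ndarray, params: DosageParams):
    """Per-cell copy number and copy age for cells of given ages (fork model).

    For locus m, write q = (C(1-m)+D)/tau. A cell carries 2**floor(q) copies
    until all of them are passed simultaneously by the forks of the next
    round at age a_hat = tau*(1 - frac(q)), after which it carries twice as
    many. Copy age (time since the copies were last replicated) is
    (age - a_hat) mod tau.
    """
    tau = params.tau_min
    q = (params.C_min * (1.0 - m) + params.D_min) / tau
    floor_q = np.floor(q)
    frac = q - floor_q
    a_hat = tau * (1.0 - frac)  # in (0, tau]
    ages = ages[:, None]
    doubled = ages >= a_hat[None, :]
    copies = 2.0**floor_q[None, :] * np.where(doubled, 2.0, 1.0)
    copy_age = np.mod(ages - a_hat[None, :], tau)
    return copies, copy_age


def _sample_ages(n: int, tau: float, rng: np.random.Generator, stratified: bool) -> np.ndarray:
    """Draw cell ages from the stationary age density u(a) ~ 2**(-a/tau)."""
    if stratified:
        v = (np.arange(n) + rng.random(n)) / n
    else:
        v = rng.random(n)
    # inverse CDF of u(a) = (2 ln2 / tau) 2**(-a/tau) on [0, tau]
    return -tau * np.log2(1.0 - v / 2.0)


def simulated_mean_copy_number(
    m: float,
    params: DosageParams,
    n_cells: int = 100_000,
    seed: int = 0,
    stratified: bool = True,
):
    """Monte-Carlo population mean copy number from the explicit fork model.

    Returns (mean, standard_error). With ``stratified=True`` ages are drawn
    by stratified inversion of the stationary age CDF (quasi-Monte-Carlo),
    which sharply reduces the variance of the mean; the returned standard
    error is the conservative iid estimate.
    """
    rng = np.random.default_rng(seed)
    ages = _sample_ages(n_cells, params.tau_min, rng, stratified)
    copies, _ = _per_cell_copies(ages, np.asarray([m], dtype=float), params)
    copies = copies[:, 0]
    return float(copies.mean()), float(copies.std(ddof=1) / np.sqrt(n_cells))


def dosage_profile(
    genome: GenomeSpec,
    params: DosageParams,
    n_bins: int = 100,
    normalized: bool = False,
) -> CoverageProfile:
    """Expected dosage evaluated at the centers of n_bins equal bins."""
    if n_bins < 2:
        raise ValidationError("n_bins must be >= 2")
    L = genome.length_bp
    width = L / n_bins
    centers = (np.arange(n_bins) + 0.5) * width
    values = mean_copy_number(locus_relative_position(centers, genome), params)
    prof = CoverageProfile(int(round(width)), int(round(width)), centers, values, genome)
    return normalize_profile(prof) if normalized else prof


def dosage_prediction_for(profile: CoverageProfile, params: DosageParams) -> CoverageProfile:
    """Expected dosage evaluated on the bins of an existing profile."""
    values = mean_copy_number(locus_relative_position(profile.centers, profile.genome), params)
    return CoverageProfile(
        profile.window_bp, profile.step_bp, profile.centers.copy(), values, profile.genome
    )


def fit_dosage_exponent(observed: CoverageProfile, predicted: CoverageProfile) -> ExponentFit:
    """Least-squares exponent of observed insertion density vs predicted dosage.

    Both profiles are normalized to mean 1 before fitting (the comparison is
    scale-free); zero observed bins are dropped and their count reported.
    """
    if len(observed) != len(predicted) or not np.allclose(observed.centers, predicted.centers):
        raise ValidationError("profiles must be on identical bins")
    if np.any(predicted.values <= 0):
        raise ValidationError("predicted dosage must be positive everywhere")
    obs = observed.values / observed.values.mean()
    pred = predicted.values / predicted.values.mean()
    keep = obs > 0
    n_dropped = int((~keep).sum())
    if keep.sum() < 3:
        raise InsufficientDataError("fewer than 3 usable bins for the exponent fit")
    res = stats.linregress(np.log(pred[keep]), np.log(obs[keep]))
    return ExponentFit(
        alpha=float(res.slope),
        alpha_stderr=float(res.stderr),
        intercept=float(res.intercept),
        n_bins=int(keep.sum()),
        n_dropped=n_dropped,
    )


def simulate_age_structured_insertions(
    genome: GenomeSpec,
    params: DosageParams,
    model: TimeRateModel,
    n: int,
    seed: int = 0,
    n_age_samples: int = 2048,
    n_grid: int = 2048,
) -> InsertionSet:
    """Sample insertion positions from the explicit age-structured fork model.

    Cell ages are drawn from the stationary exponential age distribution and
    fork positions reconstructed per Cooper-Helmstetter, so a locus passed by
    k active rounds is present in 2**k copies. The insertion hazard per locus
    copy grows as (copy age / tau)**beta, where copy age is the time since
    the copy was last replicated.

    Note a structural property of the stationary population: the expected
    position density is proportional to the dosage profile for *every* beta
    (the copy-age distribution factorizes out of the position marginal), so
    beta reshapes finite-population fluctuations, not the mean landscape;
    beta = 0 is the exact sampling oracle for the closed-form dosage.
    """
    if n < 0:
        raise ValidationError("n must be >= 0")
    rng = np.random.default_rng(seed)
    if n == 0:
        return InsertionSet(np.empty(0, dtype=np.int64), genome=genome)
    L = genome.length_bp
    n_grid = min(n_grid, L)
    edges = np.linspace(0, L, n_grid + 1)
    grid_centers = (edges[:-1] + edges[1:]) / 2.0
    m = locus_relative_position(grid_centers, genome)
    ages = _sample_ages(n_age_samples, params.tau_min, rng, stratified=False)
    copies, copy_age = _per_cell_copies(ages, m, params)
    w = copies * (copy_age / params.tau_min) ** model.beta if model.beta > 0 else copies
    row_mass = w.sum(axis=1)
    rows = rng.choice(n_age_samples, size=n, p=row_mass / row_mass.sum())
    positions = np.empty(n, dtype=np.int64)
    for r in np.unique(rows):
        sel = rows == r
        k = int(sel.sum())
        cdf = np.cumsum(w[r])
        cols = np.searchsorted(cdf, rng.random(k) * cdf[-1], side="right")
        cols = np.clip(cols, 0, n_grid - 1)
        pos = edges[cols] + rng.random(k) * (edges[cols + 1] - edges[cols])
        positions[sel] = np.floor(pos).astype(np.int64) % L
    return InsertionSet(positions, genome=genome)
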