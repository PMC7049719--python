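"""Clone-level expression statistics and extrinsic noise-scaling classification.

In the extrinsic-noise regime the standard deviation of single-cell
fluorescence is proportional to the mean, sd = c * mean. The scaling fit
fixes the log-log slope at 1 and estimates c robustly (median of
log(sd/mean)); clones whose positive log-residual exceeds k times the
MAD-based scale are flagged as steep-noise outliers. A free-slope diagnostic
regression is reported alongside.

Note a structural property used by the tests: because outlier status depends
on (mean, sd) only through their ratio, it is invariant under copy-number
normalization (which divides both by the same integer).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, ValidationError

__all__ = [
    "CloneStats",
    "NoiseScalingFit",
    "GrowthTrend",
    "clone_stats",
    "fit_noise_scaling",
    "normalize_by_copy_number",
    "growth_trend",
]

_MAD_TO_SIGMA = 1.4826  # consistency factor for normal data


@dataclass(frozen=True)
class CloneStats:
    """Per-clone mean / sample sd / CV^2 of single-cell fluorescence."""

    clone_id: str
    mean: float
    sd: float
    cv2: Optional[float]
    n_cells: int
    copy_number: int = 1
    cv2_defined: bool = True


@dataclass(frozen=True)
class NoiseScalingFit:
    """Extrinsic coefficient c in sd = c * mean, with robust outlier calls."""

    slope_c: float
    residual_scale: float
    outlier_ids: Tuple[str, ...]
    threshold_k: float
    n_clones: int
    free_slope: float
    free_slope_stderr: float


@dataclass(frozen=True)
class GrowthTrend:
    slope: float
    intercept: float
    label: str  # increasing | decreasing | flat


def clone_stats(cells: Sequence[float], clone_id: str, copy_number: int = 1) -> CloneStats:
    """Mean, sample (n-1) standard deviation and CV^2 of one clone's cells."""
    cells = np.asarray(cells, dtype=float)
    if cells.size < 2:
        raise InsufficientDataError("clone statistics need at least 2 cells")
    if copy_number < 1:
        raise ValidationError("copy_number must be >= 1")
    mean = float(cells.mean())
    sd = float(cells.std(ddof=1))
    if mean > 0:
        return CloneStats(clone_id, mean, sd, (sd / mean) ** 2, cells.size, copy_number)
    return CloneStats(clone_id, mean, sd, None, cells.size, copy_number, cv2_defined=False)


def fit_noise_scaling(stats_list: Sequence[CloneStats], threshold_k: float = 3.5) -> NoiseScalingFit:
    """Robust fit of the extrinsic line sd = c * mean over a clone cohort.

    The slope is fixed at 1 in log space (pure extrinsic regime); c is the
    exponentiated median of log(sd/mean), the residual scale is the MAD of
    the log-residuals rescaled to a sigma equivalent, and outliers are the
    clones with positive residual beyond threshold_k * scale.
    """
    usable = [s for s in stats_list if s.mean > 0 and s.sd > 0]
    if len(usable) < 5:
        raise InsufficientDataError("noise-scaling fit needs >= 5 clones with mean > 0")
    log_ratio = np.log([s.sd / s.mean for s in usable])
    center = float(np.median(log_ratio))
    resid = log_ratio - center
    scale = float(np.median(np.abs(resid)) * _MAD_TO_SIGMA)
    if scale > 0:
        outliers = tuple(s.clone_id for s, r in zip(usable, resid) if r > threshold_k * scale)
    else:
        outliers = tuple(s.clone_id for s, r in zip(usable, resid) if r > 0)
    log_mean = np.log([s.mean for s in usable])
    log_sd = np.log([s.sd for s in usable])
    free = stats.linregress(log_mean, log_sd)
    return NoiseScalingFit(
        slope_c=float(np.exp(center)),
        residual_scale=scale,
        outlier_ids=outliers,
        threshold_k=threshold_k,
        n_clones=len(usable),
        free_slope=float(free.slope),
        free_slope_stderr=float(free.stderr),
    )


def normalize_by_copy_number(s: CloneStats) -> CloneStats:
    """Express mean and sd per promoter copy. CV^2 is unchanged by construction."""
    if s.copy_number < 1:
        raise ValidationError("copy_number must be >= 1")
    k = s.copy_number
    return replace(s, mean=s.mean / k, sd=s.sd / k, copy_number=1)


def growth_trend(
    points: Sequence[Tuple[float, float]],
    flat_fraction: float = 0.05,
) -> GrowthTrend:
    """Least-squares slope of mean expression on growth rate, with a sign label.

    The label is "flat" when |slope| is below ``flat_fraction`` of the mean
    expression per unit growth rate (1/h).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise InsufficientDataError("growth trend needs >= 2 points")
    rates, means = pts[:, 0], pts[:, 1]
    if np.unique(rates).size < 2:
        raise ValidationError("all growth rates identical")
    res = stats.linregress(rates, means)
    slope = float(res.slope)
    tol = flat_fraction * float(np.abs(means).mean())
    if abs(slope) <= tol:
        label = "flat"
    elif slope > 0:
        label = "increasing"
    else:
        label = "decreasing"
    return GrowthTrend(slope, float(res.intercept), label)
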