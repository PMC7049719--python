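"""Circular sliding-window insertion coverage and origin-symmetry diagnostics.

The coverage profile is the sliding average of insertion weight per base
pair, computed on the circle so windows wrap around the origin. The same
``CoverageProfile`` container also carries binned dosage predictions and
serves as the background density for the shuffling null.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import GenomeSpec, InsertionSet
from .errors import ValidationError

__all__ = ["CoverageProfile", "sliding_coverage", "normalize_profile", "oriter_asymmetry"]


@dataclass
class CoverageProfile:
    """Values sampled at window centers on the circular genome."""

    window_bp: int
    step_bp: int
    centers: np.ndarray
    values: np.ndarray
    genome: GenomeSpec
    normalized: bool = False

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.centers.size < 1:
            raise ValidationError("profile needs at least one center")
        if np.any(np.diff(self.centers) <= 0):
            raise ValidationError("centers must be strictly increasing")
        if self.centers[0] < 0 or self.centers[-1] >= self.genome.length_bp:
            raise ValidationError("centers outside [0, length_bp)")
        if self.values.shape != self.centers.shape:
            raise ValidationError("values length differs from centers")
        if np.any(self.values < 0):
            raise ValidationError("negative coverage value")

    def __len__(self) -> int:
        return len(self.centers)

    def bin_widths(self) -> np.ndarray:
        """Circular Voronoi widths around the centers (tile the genome)."""
        L = self.genome.length_bp
        c = self.centers
        if len(c) == 1:
            return np.array([float(L)])
        nxt = np.roll(c, -1).copy()
        nxt[-1] += L
        gaps = nxt - c  # gap to the next center, circularly
        prev_gaps = np.roll(gaps, 1)
        return (gaps + prev_gaps) / 2.0

    def bin_left_edges(self) -> np.ndarray:
        L = self.genome.length_bp
        c = self.centers
        if len(c) == 1:
            return np.array([0.0])
        prev = np.roll(c, 1).copy()
        prev[0] -= L
        return (c + prev) / 2.0  # may be negative for the first bin (wraps)


def sliding_coverage(
    insertions: InsertionSet,
    genome: GenomeSpec,
    window_bp: int = 3000,
    step_bp: int = 1000,
) -> CoverageProfile:
    """Circular sliding average of insertion weight per bp.

    The window at center ``c`` is the half-open span
    ``[c - window_bp//2, c - window_bp//2 + window_bp)`` on the circle.
    """
    L = genome.length_bp
    if window_bp < 1 or step_bp < 1:
        raise ValidationError("window_bp and step_bp must be >= 1")
    if window_bp > L:
        raise ValidationError("window_bp exceeds genome length")
    per_bp = np.bincount(insertions.positions, weights=insertions.effective_weights(), minlength=L)
    # circular cumulative sum over two genome copies
    cs = np.concatenate([[0.0], np.cumsum(np.concatenate([per_bp, per_bp]))])
    centers = np.arange(0, L, step_bp, dtype=np.int64)
    left = (centers - window_bp // 2) % L
    right = left + window_bp
    values = (cs[right] - cs[left]) / float(window_bp)
    return CoverageProfile(window_bp, step_bp, centers.astype(float), values, genome)


def normalize_profile(profile: CoverageProfile) -> CoverageProfile:
    """Divide values by their mean (idempotent up to numerics)."""
    m = profile.values.mean()
    if m <= 0:
        raise ValidationError("cannot normalize an all-zero profile")
    return replace(profile, values=profile.values / m, normalized=True)


def oriter_asymmetry(profile: CoverageProfile, genome: GenomeSpec) -> float:
    """Left-right insertion-density asymmetry with respect to the origin.

    Returns (mean over right replichore - mean over left replichore) divided
    by the overall mean, where "right" is the arc from ori to ter in
    increasing coordinate. Computed on the normalized profile so the result
    is scale-free.
    """
    prof = profile if profile.normalized else normalize_profile(profile)
    L = genome.length_bp
    d_fwd = (prof.centers - genome.ori_pos) % L
    right_len = genome.right_replichore_bp
    on_right = (d_fwd > 0) & (d_fwd < right_len)
    on_left = d_fwd > right_len
    overall = prof.values.mean()
    if overall <= 0:
        raise ValidationError("zero overall mean")
    if not on_right.any() or not on_left.any():
        raise ValidationError("profile does not cover both replichores")
    return float((prof.values[on_right].mean() - prof.values[on_left].mean()) / overall)
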