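"""Sister-lineage divergence of gene expression in microcolonies.

For every division in a lineage tree, the two descendant sub-lineages are
compared: at each shared time point the expression of each side is the mean
over its live descendants, and the pair divergence is the time average of
the absolute difference between the two sides. The colony divergence is the
mean over division pairs. A "sisters" mode restricts each side to the
immediate daughter cell (until its own division); the default follows full
sub-lineages, which keeps the statistic well-defined after further divisions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Sequence, Tuple

import numpy as np
from scipy import stats

from .core import LineageTree
from .errors import InsufficientDataError, ValidationError

__all__ = ["DivergenceResult", "ComparisonResult", "sister_divergence", "compare_divergence"]


@dataclass(frozen=True)
class DivergenceResult:
    colony_id: str
    per_pair: Tuple[Tuple[str, float], ...]
    colony_divergence: float
    n_pairs: int


@dataclass(frozen=True)
class ComparisonResult:
    ratio: float
    p_value: float
    n_a: int
    n_b: int


def _lineage_mean(tree: LineageTree, head: str, times: np.ndarray, sublineages: bool) -> np.ndarray:
    """Mean expression over live sampled descendants of ``head`` at each time."""
    cells = tree.descendants(head, inclusive=True) if sublineages else [head]
    total = np.zeros_like(times)
    count = np.zeros_like(times)
    for cid in cells:
        if cid not in tree.series:
            continue
        t, x = tree.series[cid]
        if len(t) == 0:
            continue
        idx = np.searchsorted(t, times)
        idx_ok = np.clip(idx, 0, len(t) - 1)
        hit = (idx < len(t)) & np.isclose(t[idx_ok], times)
        total[hit] += x[idx_ok[hit]]
        count[hit] += 1
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return mean


def sister_divergence(
    tree: LineageTree,
    mode: str = "sublineages",
    normalize_by_mean: bool = False,
) -> DivergenceResult:
    """Time-averaged absolute expression difference between sister lineages.

    With ``normalize_by_mean`` the divergence is divided by the colony mean
    expression, giving a dimensionless value comparable across clones.
    """
    if mode not in {"sublineages", "sisters"}:
        raise ValidationError("mode must be 'sublineages' or 'sisters'")
    divisions = tree.dividing_cells()
    if not divisions:
        raise InsufficientDataError("tree has no divisions")
    all_times = np.unique(np.concatenate([np.asarray(t) for t, _ in tree.series.values()]))
    per_pair: List[Tuple[str, float]] = []
    for parent in divisions:
        c1, c2 = sorted(tree.children[parent])
        e1 = _lineage_mean(tree, c1, all_times, mode == "sublineages")
        e2 = _lineage_mean(tree, c2, all_times, mode == "sublineages")
        shared = ~np.isnan(e1) & ~np.isnan(e2)
        if not shared.any():
            warnings.warn(f"pair under {parent}: no shared time points, skipped")
            continue
        per_pair.append((parent, float(np.mean(np.abs(e1[shared] - e2[shared])))))
    if not per_pair:
        raise InsufficientDataError("no division pair has shared time points")
    values = np.array([d for _, d in per_pair])
    colony = float(values.mean())
    if normalize_by_mean:
        grand = float(np.mean(np.concatenate([np.asarray(x) for _, x in tree.series.values()])))
        if grand <= 0:
            raise ValidationError("colony mean expression is not positive")
        per_pair = [(p, d / grand) for p, d in per_pair]
        colony /= grand
    return DivergenceResult(tree.colony_id, tuple(per_pair), colony, len(per_pair))


def compare_divergence(
    results_a: Sequence[DivergenceResult],
    results_b: Sequence[DivergenceResult],
) -> ComparisonResult:
    """Ratio of mean colony divergence (a/b) with a two-sample rank-sum p-value."""
    if not results_a or not results_b:
        raise ValidationError("both result lists must be non-empty")
    a = np.array([r.colony_divergence for r in results_a])
    b = np.array([r.colony_divergence for r in results_b])
    if b.mean() <= 0:
        raise ValidationError("reference divergences have non-positive mean")
    if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
        p = 1.0  # identical constant samples: no evidence either way
    else:
        p = float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    return ComparisonResult(float(a.mean() / b.mean()), p, len(a), len(b))
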