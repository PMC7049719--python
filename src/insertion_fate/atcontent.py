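"""AT-content bias of insertion-flanking sequence versus genomic background.

Compares the AT fraction of windows centered on insertion sites with windows
centered at uniform random positions, using a one-sided two-sample
Kolmogorov-Smirnov test with the alternative "insertion windows are
stochastically richer in AT". The KS statistic is computed by an exact ECDF
sweep (no binning); the p-value uses the one-sided asymptotic formula
exp(-2 D^2 nA nB / (nA + nB)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import GenomeSpec, InsertionSet
from .errors import InsufficientDataError, ValidationError

__all__ = ["KSResult", "at_fraction", "one_sided_ks", "window_at_fractions", "insertion_at_bias_test"]

_AT = frozenset("AT")
_VALID = frozenset("ACGT")


@dataclass(frozen=True)
class KSResult:
    """One-sided KS comparison of insertion-window vs background AT fractions."""

    d_stat: float
    p_value: float
    n_insertion: int
    n_background: int
    window_bp: int


def at_fraction(seq: str) -> float:
    """(A+T) / (A+C+G+T) of a nucleotide string; N is excluded entirely."""
    seq = seq.upper()
    n_at = sum(1 for c in seq if c in _AT)
    n_valid = sum(1 for c in seq if c in _VALID)
    if n_valid == 0:
        raise ValidationError("sequence has no non-N bases")
    bad = set(seq) - _VALID - {"N"}
    if bad:
        raise ValidationError(f"unexpected characters in sequence: {sorted(bad)}")
    return n_at / n_valid


def _seq_arrays(genome_seq: str):
    arr = np.frombuffer(genome_seq.upper().encode("ascii"), dtype=np.uint8)
    is_at = (arr == ord("A")) | (arr == ord("T"))
    is_valid = is_at | (arr == ord("C")) | (arr == ord("G"))
    return is_at.astype(float), is_valid.astype(float)


def window_at_fractions(positions, genome_seq: str, window_bp: int, genome: GenomeSpec) -> np.ndarray:
    """AT fraction of the circular window of width window_bp centered on each position."""
    L = genome.length_bp
    if len(genome_seq) != L:
        raise ValidationError("sequence length differs from genome length")
    if window_bp > L:
        raise ValidationError("window exceeds genome length")
    is_at, is_valid = _seq_arrays(genome_seq)
    cs_at = np.concatenate([[0.0], np.cumsum(np.concatenate([is_at, is_at]))])
    cs_ok = np.concatenate([[0.0], np.cumsum(np.concatenate([is_valid, is_valid]))])
    left = np.mod(np.asarray(positions, dtype=np.int64) - window_bp // 2, L)
    right = left + window_bp
    n_at = cs_at[right] - cs_at[left]
    n_ok = cs_ok[right] - cs_ok[left]
    if np.any(n_ok == 0):
        raise ValidationError("a window contains no non-N bases")
    return n_at / n_ok


def one_sided_ks(sample_a: np.ndarray, sample_b: np.ndarray):
    """One-sided KS statistic D = sup_x (F_b(x) - F_a(x)) by exact ECDF sweep.

    D > 0 is evidence that sample_a is stochastically greater than sample_b.
    Returns (D, p) with the asymptotic p = exp(-2 D^2 nA nB / (nA + nB)).
    """
    a = np.sort(np.asarray(sample_a, dtype=float))
    b = np.sort(np.asarray(sample_b, dtype=float))
    na, nb = len(a), len(b)
    if na == 0 or nb == 0:
        raise InsufficientDataError("empty sample in KS test")
    xs = np.unique(np.concatenate([a, b]))
    f_a = np.searchsorted(a, xs, side="right") / na
    f_b = np.searchsorted(b, xs, side="right") / nb
    d = float(np.max(f_b - f_a))
    d = max(d, 0.0)
    p = float(np.exp(-2.0 * d * d * na * nb / (na + nb)))
    return d, min(p, 1.0)


def insertion_at_bias_test(
    insertions: InsertionSet,
    genome_seq: str,
    genome: GenomeSpec,
    window_bp: int = 1000,
    n_background: int = 5000,
    seed: int = 0,
) -> KSResult:
    """Test whether insertion-flanking windows are AT-richer than background.

    Background windows are centered at uniform random positions on the circle
    (not density-matched). Window size defaults to 1 kb, the scale of H-NS
    binding tracts.
    """
    if window_bp < 10:
        raise ValidationError("window_bp must be >= 10")
    rng = np.random.default_rng(seed)
    sample_a = window_at_fractions(insertions.positions, genome_seq, window_bp, genome)
    bg_pos = rng.integers(0, genome.length_bp, size=n_background)
    sample_b = window_at_fractions(bg_pos, genome_seq, window_bp, genome)
    if len(sample_a) < 5 or len(sample_b) < 5:
        raise InsufficientDataError("fewer than 5 windows in a sample")
    d, p = one_sided_ks(sample_a, sample_b)
    return KSResult(d, p, len(sample_a), len(sample_b), window_bp)
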