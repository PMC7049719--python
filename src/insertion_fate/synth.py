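"""Synthetic data with the statistical structure the analysis assumes.

Generates annotated circular genomes (AT-rich islands standing in for H-NS
binding tracts, essential genes, seven rRNA operons), insertion landscapes
with dosage and AT biases and essential-gene depletion, clone expression with
shared extrinsic noise plus telegraph-switching ribosomal-interference
clones, fluorescence-gated sorting of clone populations, and microcolony
lineage trees — so every analysis stage is testable without downloads.

Identifying H-NS binding with AT islands is a generative modeling choice
mirroring the empirical correlation between the two, not a biological claim.
All generators are deterministic given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .core import CellNode, CloneExpression, GenomeSpec, InsertionSet, IntervalSet, LineageTree
from .dosage import DosageParams, locus_relative_position, mean_copy_number
from .enrichment import _FULL, _inside, _merged_segments
from .errors import ValidationError

__all__ = [
    "SwitchParams",
    "SynthConfig",
    "AnnotatedGenome",
    "ClonePhenotype",
    "make_genome",
    "sample_insertions",
    "assign_clone_phenotypes",
    "sample_cell_expression",
    "sort_population",
    "simulate_microcolony",
]


@dataclass(frozen=True)
class SwitchParams:
    """Two-state telegraph promoter: slow ON excursions out of a stable OFF state."""

    k_on: float = 0.01  # 1/min
    k_off: float = 0.05  # 1/min
    level_on: float = 400.0  # a.u.
    level_off: float = 20.0  # a.u.

    def __post_init__(self) -> None:
        if self.k_on < 0 or self.k_off < 0:
            raise ValidationError("switching rates must be >= 0")
        if not (self.level_on > self.level_off >= 0):
            raise ValidationError("need level_on > level_off >= 0")

    @property
    def p_on(self) -> float:
        """Stationary occupancy of the ON state."""
        if self.k_on + self.k_off == 0:
            return 0.0
        return self.k_on / (self.k_on + self.k_off)

    @property
    def stationary_mean(self) -> float:
        return self.p_on * self.level_on + (1 - self.p_on) * self.level_off


@dataclass
class SynthConfig:
    """Study conditions for the synthetic world (scaled-down 500 kb genome).

    The full 4.6 Mb scale is supported by raising ``length_bp`` and the
    interval counts proportionally.
    """

    # genome and annotation
    length_bp: int = 500_000
    ori_pos: int = 0
    ter_pos: Optional[int] = None
    at_island_count: int = 20
    at_island_mean_bp: int = 2500
    at_island_min_bp: int = 800
    island_at: float = 0.70
    background_at: float = 0.50
    essential_count: int = 30
    essential_len_bp: int = 1000
    rrn_count: int = 7  # E. coli carries seven ribosomal operons
    rrn_len_bp: int = 3000
    regulator_count: int = 40
    regulator_len_bp: int = 800
    # insertion landscape
    dosage: DosageParams = field(default_factory=DosageParams)
    n_insertions: int = 10_000
    alpha: float = 3.0
    at_boost: float = 2.0
    essential_survival: float = 0.1
    # clone phenotypes
    hns_proximity_bp: int = 1000
    opposite_orientation_prob: float = 0.8
    silencing_factor: float = 0.1
    multi_insertion_fraction: float = 0.05
    # expression model
    mu0: float = 200.0  # a.u., normal clone mean at the reference growth rate
    gr_ref: float = 2.0  # 1/h
    media: Dict[str, float] = field(
        default_factory=lambda: {"LB": 2.0, "M9glu": 1.0, "M9glyc": 0.6}
    )
    cv_ext: float = 0.3
    switch: SwitchParams = field(default_factory=SwitchParams)
    cells_per_clone: int = 1000
    # microcolony dynamics
    lineage_cv: float = 0.2
    ou_tau_min: float = 60.0
    meas_cv: float = 0.02
    dt_min: float = 3.0
    generations: int = 3
    # sorting gates as pooled-fluorescence quantiles
    low_gate_q: Tuple[float, float] = (0.0, 0.3)
    high_gate_q: Tuple[float, float] = (0.7, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("island_at", "background_at", "essential_survival", "cv_ext",
                     "multi_insertion_fraction", "opposite_orientation_prob"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must be in [0, 1]")
        if self.alpha < 0 or self.at_boost < 0:
            raise ValidationError("alpha and at_boost must be >= 0")

    def genome_spec(self) -> GenomeSpec:
        return GenomeSpec(self.length_bp, self.ori_pos, self.ter_pos)


@dataclass
class AnnotatedGenome:
    spec: GenomeSpec
    sequence: str
    intervals: Dict[str, IntervalSet]


@dataclass
class ClonePhenotype:
    """Insertion positions of one clone with per-site regulatory context."""

    clone_id: str
    positions: List[int]
    site_classes: List[str]  # normal | silenced | rrn_switching per position
    orientations: List[str]  # +/- relative to the host rrn promoter ('.' outside)

    @property
    def clone_class(self) -> str:
        if "rrn_switching" in self.site_classes:
            return "rrn_switching"
        if "silenced" in self.site_classes:
            return "silenced"
        return "normal"

    @property
    def copy_number(self) -> int:
        return len(self.positions)


def _place_intervals(
    rng: np.random.Generator,
    count: int,
    lengths: np.ndarray,
    L: int,
    forbidden: List[Tuple[int, int]],
    name: str,
    genome: GenomeSpec,
    strands: Optional[List[str]] = None,
    max_tries: int = 20000,
) -> IntervalSet:
    """Rejection-place non-wrapping intervals avoiding existing placements."""
    placed: List[Tuple[int, int]] = []
    taken = list(forbidden)
    for i in range(count):
        ln = int(lengths[i])
        for _ in range(max_tries):
            s = int(rng.integers(0, L - ln))
            e = s + ln
            if all(e <= a or s >= b for a, b in taken):
                placed.append((s, e))
                taken.append((s, e))
                break
        else:
            raise ValidationError(f"infeasible placement for interval set {name!r}")
    records = [
        (s, e, f"{name}_{i}", strands[i] if strands else ".")
        for i, (s, e) in enumerate(placed)
    ]
    return IntervalSet.from_records(name, records, genome)


def make_genome(config: SynthConfig, seed: Optional[int] = None) -> AnnotatedGenome:
    """Annotated genome: sequence with AT islands plus labeled interval sets.

    Essential genes are never placed inside AT islands; rrn operons avoid
    both and carry an orientation strand label.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    genome = config.genome_spec()
    L = config.length_bp
    requested = (
        config.at_island_count * config.at_island_mean_bp
        + config.essential_count * config.essential_len_bp
        + config.rrn_count * config.rrn_len_bp
    )
    if requested > 0.5 * L:
        raise ValidationError("requested intervals exceed half the genome; infeasible")
    island_len = config.at_island_min_bp + rng.exponential(
        max(config.at_island_mean_bp - config.at_island_min_bp, 1), config.at_island_count
    )
    islands = _place_intervals(
        rng, config.at_island_count, island_len.astype(int), L, [], "hns_islands", genome
    )
    taken = list(zip(islands.starts.tolist(), islands.ends.tolist()))
    essential = _place_intervals(
        rng,
        config.essential_count,
        np.full(config.essential_count, config.essential_len_bp),
        L,
        taken,
        "essential",
        genome,
    )
    taken += list(zip(essential.starts.tolist(), essential.ends.tolist()))
    rrn_strands = ["+" if rng.random() < 0.5 else "-" for _ in range(config.rrn_count)]
    rrn = _place_intervals(
        rng,
        config.rrn_count,
        np.full(config.rrn_count, config.rrn_len_bp),
        L,
        taken,
        "rrn",
        genome,
        strands=rrn_strands,
    )
    regulators = _place_intervals(
        rng,
        config.regulator_count,
        np.full(config.regulator_count, config.regulator_len_bp),
        L,
        [],
        "regulator_targets",
        genome,
    )
    at_prob = np.full(L, config.background_at)
    for s, e in zip(islands.starts, islands.ends):
        at_prob[s:e] = config.island_at
    r = rng.random(L)
    half = rng.random(L) < 0.5
    bases = np.where(r < at_prob, np.where(half, ord("A"), ord("T")),
                     np.where(half, ord("G"), ord("C")))
    sequence = bases.astype(np.uint8).tobytes().decode("ascii")
    return AnnotatedGenome(
        spec=genome,
        sequence=sequence,
        intervals={
            "hns_islands": islands,
            "essential": essential,
            "rrn": rrn,
            "regulator_targets": regulators,
        },
    )


def _indicator(intervals: IntervalSet, L: int) -> np.ndarray:
    out = np.zeros(L, dtype=bool)
    for s, e in zip(intervals.starts, intervals.ends):
        out[s:e] = True
    return out


def sample_insertions(
    ann: AnnotatedGenome, config: SynthConfig, seed: Optional[int] = None
) -> InsertionSet:
    """Insertion positions with dosage^alpha and AT-island biases.

    The per-bp density is dosage(m)^alpha * (1 + at_boost * island); each
    candidate falling inside an essential gene is retained with the
    configured survival probability, and sampling continues until n
    insertions are accepted.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    genome = ann.spec
    L = genome.length_bp
    x = np.arange(L)
    dens = mean_copy_number(locus_relative_position(x, genome), config.dosage) ** config.alpha
    dens = dens * (1.0 + config.at_boost * _indicator(ann.intervals["hns_islands"], L))
    probs = dens / dens.sum()
    essential = _indicator(ann.intervals["essential"], L)
    accepted: List[np.ndarray] = []
    remaining = config.n_insertions
    while remaining > 0:
        batch = rng.choice(L, size=max(remaining * 2, 100), p=probs)
        keep = ~essential[batch] | (rng.random(batch.size) < config.essential_survival)
        got = batch[keep][:remaining]
        accepted.append(got)
        remaining -= got.size
        if config.essential_survival == 0 and essential.all():
            raise ValidationError("no insertable position available")
    positions = np.concatenate(accepted) if accepted else np.empty(0, dtype=np.int64)
    labels = [f"cl{i:05d}" for i in range(len(positions))]
    return InsertionSet(positions.astype(np.int64), labels=labels, genome=genome)


def _in_segments(pos: int, segs) -> bool:
    if segs == _FULL:
        return True
    starts, ends = segs
    return bool(_inside(np.array([float(pos)]), starts, ends)[0])


def _site_class(pos: int, orientation: str, rrn_segs, island_flanked) -> str:
    if _in_segments(pos, rrn_segs) and orientation == "-":
        return "rrn_switching"
    if _in_segments(pos, island_flanked):
        return "silenced"
    return "normal"


def assign_clone_phenotypes(
    insertions: InsertionSet,
    ann: AnnotatedGenome,
    config: SynthConfig,
    seed: Optional[int] = None,
) -> List[ClonePhenotype]:
    """Classify each clone by the regulatory context of its insertion site(s).

    A site within ``hns_proximity_bp`` of an AT island is silenced; a site
    inside an rrn operon with orientation opposite to the operon (drawn with
    ``opposite_orientation_prob``) switches by transcriptional interference.
    A configured fraction of clones receives 1-2 extra insertion positions
    resampled from the landscape.
    """
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed + 1)
    rrn_segs = _merged_segments(ann.intervals["rrn"], ann.spec, flank_bp=0)
    island_flanked = _merged_segments(
        ann.intervals["hns_islands"], ann.spec, flank_bp=config.hns_proximity_bp
    )
    clones: List[ClonePhenotype] = []
    n = len(insertions)
    labels = insertions.labels or [f"cl{i:05d}" for i in range(n)]
    extra_pool = insertions.positions
    for i in range(n):
        positions = [int(insertions.positions[i])]
        if config.multi_insertion_fraction > 0 and rng.random() < config.multi_insertion_fraction:
            n_extra = int(rng.integers(1, 3))  # clone ends up with 2-3 insertions
            positions += [int(p) for p in rng.choice(extra_pool, size=n_extra)]
        site_classes, orientations = [], []
        for pos in positions:
            orientation = "-" if rng.random() < config.opposite_orientation_prob else "+"
            cls = _site_class(pos, orientation, rrn_segs, island_flanked)
            orientations.append(orientation if cls == "rrn_switching" else ".")
            site_classes.append(cls)
        clones.append(ClonePhenotype(labels[i], positions, site_classes, orientations))
    return clones


def _mean_dosage(params: DosageParams) -> float:
    """Genome-average locus dosage: integral of 2**((C(1-m)+D)/tau) over m."""
    c, d, tau = params.C_min, params.D_min, params.tau_min
    if c == 0:
        return 2.0 ** (d / tau)
    ln2 = np.log(2.0)
    return 2.0 ** (d / tau) * (2.0 ** (c / tau) - 1.0) * tau / (c * ln2)


def _site_mean(
    cls: str, pos: int, growth_rate: float, config: SynthConfig, genome: GenomeSpec
) -> float:
    """Mean contribution of one insertion: promoter strength x relative dosage.

    The ribosomal promoter goes up with growth rate; expression also scales
    with the local gene dosage, so ori-proximal clones are brighter.
    """
    base = config.mu0 * growth_rate / config.gr_ref
    rel_dosage = mean_copy_number(
        locus_relative_position(pos, genome), config.dosage
    ) / _mean_dosage(config.dosage)
    base *= rel_dosage
    if cls == "silenced":
        return base * config.silencing_factor
    return base


def _switch_level_factor(growth_rate: float, config: SynthConfig) -> float:
    """Interference strengthens with growth rate, so the ON level declines."""
    return max(0.2, 2.0 - growth_rate / config.gr_ref)


def sample_cell_expression(
    clone: ClonePhenotype,
    n_cells: int,
    medium: str,
    config: SynthConfig,
    seed: Optional[int] = None,
) -> CloneExpression:
    """Per-cell fluorescence for one clone in one medium.

    All of a cell's insertions share the same extrinsic factor (1 + eta),
    eta ~ Normal(0, cv_ext); switching sites additionally draw a telegraph
    state per cell from the stationary occupancy. Values are truncated at 0.
    """
    if n_cells < 1:
        raise ValidationError("n_cells must be >= 1")
    if medium not in config.media:
        raise ValidationError(f"unknown medium {medium!r}")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    gr = config.media[medium]
    eta = rng.normal(0.0, config.cv_ext, n_cells)
    total = np.zeros(n_cells)
    sw = config.switch
    for cls, pos in zip(clone.site_classes, clone.positions):
        if cls == "rrn_switching":
            on = rng.random(n_cells) < sw.p_on
            factor = _switch_level_factor(gr, config)
            total += np.where(on, sw.level_on * factor, sw.level_off)
        else:
            total += _site_mean(cls, pos, gr, config, config.genome_spec())
    cells = np.clip(total * (1.0 + eta), 0.0, None)
    return CloneExpression(clone.clone_id, list(clone.positions), medium, gr, cells)


def sort_population(
    clones: Sequence[CloneExpression],
    frequencies: Sequence[float],
    gate: Tuple[float, float],
) -> np.ndarray:
    """FACS-like gate: reweight clone frequencies by their in-gate cell fraction.

    The new frequency is proportional to old frequency times the fraction of
    the clone's cells with fluorescence in [low, high); repeated calls
    emulate successive sorting rounds.
    """
    low, high = gate
    if not low < high:
        raise ValidationError("gate low must be < high")
    freqs = np.asarray(frequencies, dtype=float)
    if len(freqs) != len(clones):
        raise ValidationError("frequencies length differs from clones")
    if not np.isclose(freqs.sum(), 1.0):
        raise ValidationError("frequencies must sum to 1")
    frac = np.array([np.mean((c.cells >= low) & (c.cells < high)) for c in clones])
    new = freqs * frac
    if new.sum() <= 0:
        raise ValidationError("no cell in any clone passes the gate")
    return new / new.sum()


def _binary_tree_nodes(generations: int, tau: float) -> Dict[str, CellNode]:
    nodes = {"1": CellNode("1", None, 0.0, tau)}
    frontier = ["1"]
    for depth in range(1, generations + 1):
        new_frontier = []
        for parent in frontier:
            for bit in "01":
                cid = parent + bit
                nodes[cid] = CellNode(cid, parent, depth * tau, (depth + 1) * tau)
                new_frontier.append(cid)
        frontier = new_frontier
    return nodes


def simulate_microcolony(
    clone: ClonePhenotype,
    config: SynthConfig,
    generations: Optional[int] = None,
    dt_min: Optional[float] = None,
    seed: Optional[int] = None,
    mu_override: Optional[float] = None,
) -> LineageTree:
    """Grow a binary microcolony and record per-cell expression time series.

    Division happens every tau minutes (no size control). Normal and
    silenced clones follow a mean-reverting (Ornstein-Uhlenbeck)
    multiplicative fluctuation inherited at division, so sisters start
    correlated and decorrelate with time constant ``ou_tau_min``; switching
    clones follow the two-state telegraph process with the configured rates,
    state inherited at division. Leaves are observed for one extra tau.
    """
    generations = config.generations if generations is None else generations
    dt = config.dt_min if dt_min is None else dt_min
    if not (1 <= generations <= 6):
        raise ValidationError("generations must be in [1, 6]")
    seed = config.seed if seed is None else seed
    rng = np.random.default_rng(seed)
    tau = config.dosage.tau_min
    nodes = _binary_tree_nodes(generations, tau)
    sw = config.switch
    switching = clone.clone_class == "rrn_switching"
    if mu_override is not None:
        mu = mu_override
    elif switching:
        mu = sw.stationary_mean
    else:
        mu = sum(
            _site_mean(cls, pos, config.gr_ref, config, config.genome_spec())
            for cls, pos in zip(clone.site_classes, clone.positions)
        )
    # initial state of the founder cell
    state: Dict[str, tuple] = {}
    if switching:
        state["1"] = (rng.random() < sw.p_on,)
    else:
        state["1"] = (rng.normal(0.0, config.lineage_cv),)
    series: Dict[str, tuple] = {}
    p_flip_on = 1.0 - np.exp(-sw.k_on * dt)
    p_flip_off = 1.0 - np.exp(-sw.k_off * dt)
    decay = dt / config.ou_tau_min
    kick = np.sqrt(2.0 * dt / config.ou_tau_min) * config.lineage_cv
    for cid in sorted(nodes, key=len):
        node = nodes[cid]
        times = np.arange(node.birth_min, node.end_min + 1e-9, dt)
        values = np.empty(len(times))
        cur = state[cid]
        for j in range(len(times)):
            if switching:
                on = cur[0]
                level = sw.level_on if on else sw.level_off
                values[j] = max(0.0, level * (1.0 + rng.normal(0.0, config.meas_cv)))
                flip = rng.random() < (p_flip_off if on else p_flip_on)
                cur = ((not on) if flip else on,)
            else:
                f = cur[0]
                values[j] = max(0.0, mu * (1.0 + f) * (1.0 + rng.normal(0.0, config.meas_cv)))
                f = f - decay * f + kick * rng.standard_normal()
                cur = (f,)
        series[cid] = (times, values)
        for kid in (cid + "0", cid + "1"):
            if kid in nodes:
                state[kid] = cur  # daughters inherit the parent's end state
    return LineageTree(colony_id=clone.clone_id, nodes=nodes, series=series)
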