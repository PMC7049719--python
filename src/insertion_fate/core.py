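"""Domain types shared by all analysis stages.

All coordinates are 0-based, half-open, on a single circular replicon.
Position arithmetic is modulo the genome length. An interval crossing the
origin is stored as two records sharing an ``id``; overlap logic treats
shared-id records as one feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import ValidationError

__all__ = [
    "GenomeSpec",
    "IntervalSet",
    "InsertionSet",
    "CloneExpression",
    "CellNode",
    "LineageTree",
    "circular_distance",
]


@dataclass(frozen=True)
class GenomeSpec:
    """A circular chromosome with a replication origin and terminus.

    Parameters
    ----------
    length_bp : int
        Genome length in base pairs.
    ori_pos : int
        Position of the replication origin (oriC).
    ter_pos : int, optional
        Position of the replication terminus. Defaults to the antipode of
        ``ori_pos``; real genomes have slightly unequal replichores, so it
        is an explicit field.
    """

    length_bp: int
    ori_pos: int = 0
    ter_pos: Optional[int] = None
    circular: bool = True

    def __post_init__(self) -> None:
        if self.length_bp <= 0:
            raise ValidationError("genome length must be positive")
        if not (0 <= self.ori_pos < self.length_bp):
            raise ValidationError("ori_pos outside [0, length_bp)")
        if self.ter_pos is None:
            object.__setattr__(
                self, "ter_pos", (self.ori_pos + self.length_bp // 2) % self.length_bp
            )
        if not (0 <= self.ter_pos < self.length_bp):
            raise ValidationError("ter_pos outside [0, length_bp)")
        if self.ter_pos == self.ori_pos:
            raise ValidationError("ori_pos and ter_pos must differ")
        if not self.circular:
            raise ValidationError("only circular genomes are supported")

    @property
    def right_replichore_bp(self) -> int:
        """Length of the replichore running ori -> ter in increasing coordinate."""
        return (self.ter_pos - self.ori_pos) % self.length_bp

    @property
    def left_replichore_bp(self) -> int:
        return self.length_bp - self.right_replichore_bp


def circular_distance(a, b, genome: GenomeSpec):
    """Shortest distance between positions on the circle (<= L/2). Vectorized."""
    L = genome.length_bp
    a = np.asarray(a)
    b = np.asarray(b)
    d = (a - b) % L
    out = np.minimum(d, L - d)
    if out.ndim == 0:
        return int(out)
    return out


@dataclass
class IntervalSet:
    """A named collection of genomic intervals (0-based, half-open)."""

    name: str
    starts: np.ndarray
    ends: np.ndarray
    ids: list
    strands: list
    genome: GenomeSpec

    @classmethod
    def from_records(
        cls,
        name: str,
        records: Sequence[tuple],
        genome: GenomeSpec,
    ) -> "IntervalSet":
        """Build from (start, end[, id[, strand]]) tuples, validating invariants."""
        starts, ends, ids, strands = [], [], [], []
        for i, rec in enumerate(records):
            s, e = int(rec[0]), int(rec[1])
            iid = str(rec[2]) if len(rec) > 2 else f"{name}_{i}"
            strand = str(rec[3]) if len(rec) > 3 else "."
            if not (0 <= s < genome.length_bp):
                raise ValidationError(f"interval start {s} outside genome")
            if e <= s:
                raise ValidationError(f"interval end {e} <= start {s}")
            if e > genome.length_bp:
                raise ValidationError(f"interval end {e} exceeds genome length")
            if strand not in {"+", "-", "."}:
                raise ValidationError(f"bad strand {strand!r}")
            starts.append(s)
            ends.append(e)
            ids.append(iid)
            strands.append(strand)
        return cls(
            name=name,
            starts=np.asarray(starts, dtype=np.int64),
            ends=np.asarray(ends, dtype=np.int64),
            ids=ids,
            strands=strands,
            genome=genome,
        )

    def __len__(self) -> int:
        return len(self.starts)

    def records(self):
        return list(zip(self.starts.tolist(), self.ends.tolist(), self.ids, self.strands))

    def total_bp(self) -> int:
        return int(np.sum(self.ends - self.starts))


@dataclass
class InsertionSet:
    """Insertion positions on the circular genome, optionally read-weighted."""

    positions: np.ndarray
    weights: Optional[np.ndarray] = None
    labels: Optional[list] = None
    genome: Optional[GenomeSpec] = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        if self.genome is not None and self.positions.size:
            if self.positions.min() < 0 or self.positions.max() >= self.genome.length_bp:
                raise ValidationError("insertion position outside [0, length_bp)")
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.positions.shape:
                raise ValidationError("weights length differs from positions")
            if np.any(self.weights < 0):
                raise ValidationError("negative insertion weight")
        if self.labels is not None and len(self.labels) != len(self.positions):
            raise ValidationError("labels length differs from positions")

    def __len__(self) -> int:
        return len(self.positions)

    def effective_weights(self) -> np.ndarray:
        """Weights with the all-1.0 default applied."""
        if self.weights is None:
            return np.ones(len(self.positions))
        return self.weights

    def total_weight(self) -> float:
        return float(self.effective_weights().sum())

    def as_sites(self) -> "InsertionSet":
        """Drop weights: one unit count per insertion site."""
        return InsertionSet(self.positions.copy(), None, self.labels, self.genome)


@dataclass
class CloneExpression:
    """Per-clone single-cell fluorescence sample.

    ``copy_number`` (promoter copies in the clone) is the number of insertion
    positions; fluorescence is in arbitrary units.
    """

    clone_id: str
    insertion_positions: list
    medium: str
    growth_rate: float
    cells: np.ndarray

    def __post_init__(self) -> None:
        if len(self.insertion_positions) < 1:
            raise ValidationError("a clone needs at least one insertion position")
        self.cells = np.asarray(self.cells, dtype=float)
        if self.cells.size and self.cells.min() < 0:
            raise ValidationError("negative fluorescence value")

    @property
    def copy_number(self) -> int:
        return len(self.insertion_positions)


@dataclass(frozen=True)
class CellNode:
    """One cell in a lineage tree. ``end_min`` is division or observation end."""

    cell_id: str
    parent_id: Optional[str]
    birth_min: float
    end_min: float

    def __post_init__(self) -> None:
        if self.end_min < self.birth_min:
            raise ValidationError(f"cell {self.cell_id}: end before birth")


@dataclass
class LineageTree:
    """Binary division tree with per-cell expression time series.

    ``series`` maps cell id -> (times_min, expression) arrays sampled on a
    common grid; each cell's samples lie within its [birth, end] span.
    """

    colony_id: str
    nodes: dict
    series: dict
    children: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.children = {}
        roots = []
        for cid, node in self.nodes.items():
            if node.parent_id is None:
                roots.append(cid)
            else:
                if node.parent_id not in self.nodes:
                    raise ValidationError(f"cell {cid}: unknown parent {node.parent_id}")
                self.children.setdefault(node.parent_id, []).append(cid)
        if len(roots) != 1:
            raise ValidationError("lineage tree must have exactly one root")
        self.root_id = roots[0]
        for pid, kids in self.children.items():
            if len(kids) != 2:
                raise ValidationError(f"cell {pid} divides into {len(kids)} != 2 children")
        for cid, (t, _x) in self.series.items():
            node = self.nodes[cid]
            t = np.asarray(t, dtype=float)
            if t.size and (t.min() < node.birth_min - 1e-9 or t.max() > node.end_min + 1e-9):
                raise ValidationError(f"series of cell {cid} outside its lifespan")

    def dividing_cells(self) -> list:
        return sorted(self.children.keys(), key=lambda c: self.nodes[c].end_min)

    def descendants(self, cell_id: str, inclusive: bool = True) -> list:
        out = [cell_id] if inclusive else []
        stack = list(self.children.get(cell_id, []))
        while stack:
            c = stack.pop()
            out.append(c)
            stack.extend(self.children.get(c, []))
        return out

    def n_divisions(self) -> int:
        return len(self.children)

    def leaves(self) -> list:
        return [c for c in self.nodes if c not in self.children]
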