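"""Readers and writers for the standard file formats the pipeline touches.

Intervals are BED (3+ columns, 0-based half-open); genome sequences are
FASTA; insertions, per-cell expression tables, lineage edge lists and
long-format series are TSV. All TSV outputs carry a header line and a
``#``-prefixed comment block recording seed and parameters.
"""

from __future__ import annotations

import io as _io
from typing import Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import CellNode, GenomeSpec, InsertionSet, IntervalSet, LineageTree
from .errors import ParseError, ValidationError

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_insertions",
    "write_insertions",
    "read_fasta",
    "write_fasta",
    "read_cell_table",
    "write_cell_table",
    "read_lineage",
    "write_lineage",
    "write_tsv",
    "read_tsv",
]


def _comment_block(params: Optional[dict]) -> str:
    if not params:
        return ""
    lines = [f"# {k}={v}" for k, v in params.items()]
    return "\n".join(lines) + "\n"


def write_tsv(df: pd.DataFrame, path, params: Optional[dict] = None) -> None:
    """Write a DataFrame as TSV with a parameter comment block."""
    with open(path, "w") as fh:
        fh.write(_comment_block(params))
        df.to_csv(fh, sep="\t", index=False, float_format="%.10g")


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def read_intervals(path, genome: GenomeSpec, name: Optional[str] = None) -> IntervalSet:
    """Read a BED file into an :class:`IntervalSet`.

    The chromosome column is accepted but only validated to carry a single
    name; coordinates beyond the genome length are rejected.
    """
    records = []
    chrom_seen = None
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(path, line_no, "BED line has fewer than 3 columns")
            chrom = fields[0]
            if chrom_seen is None:
                chrom_seen = chrom
            elif chrom != chrom_seen:
                raise ParseError(path, line_no, "multiple chromosome names in BED")
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                raise ParseError(path, line_no, "non-integer BED coordinate") from None
            iid = fields[3] if len(fields) > 3 else f"iv_{line_no}"
            strand = fields[5] if len(fields) > 5 else "."
            try:
                # validate one record at a time so errors carry the line number
                IntervalSet.from_records("_probe", [(start, end, iid, strand)], genome)
            except ValidationError as exc:
                raise ParseError(path, line_no, str(exc)) from None
            records.append((start, end, iid, strand))
    return IntervalSet.from_records(name or str(path), records, genome)


def write_intervals(intervals: IntervalSet, path, chrom: str = "chr") -> None:
    with open(path, "w") as fh:
        for s, e, iid, strand in intervals.records():
            fh.write(f"{chrom}\t{s}\t{e}\t{iid}\t0\t{strand}\n")


def read_insertions(path, genome: GenomeSpec) -> InsertionSet:
    """Read an insertion TSV with columns position[, weight][, clone_id]."""
    df = read_tsv(path)
    if "position" not in df.columns:
        raise ParseError(path, 1, "missing 'position' column")
    positions = df["position"].to_numpy(dtype=np.int64)
    weights = df["weight"].to_numpy(dtype=float) if "weight" in df.columns else None
    labels = df["clone_id"].astype(str).tolist() if "clone_id" in df.columns else None
    return InsertionSet(positions, weights, labels, genome)


def write_insertions(ins: InsertionSet, path, params: Optional[dict] = None) -> None:
    data = {"position": ins.positions}
    if ins.weights is not None:
        data["weight"] = ins.weights
    if ins.labels is not None:
        data["clone_id"] = ins.labels
    write_tsv(pd.DataFrame(data), path, params)


def read_fasta(path) -> str:
    """Read the single record of a FASTA file as an uppercase string."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValidationError(f"expected exactly one FASTA record, found {len(records)}")
    return str(records[0].seq).upper()


def write_fasta(seq: str, path, record_id: str = "synthetic_genome") -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=record_id, description="")], str(path), "fasta")


def read_cell_table(path) -> pd.DataFrame:
    """Per-cell expression TSV: clone_id, cell_id, fluorescence, medium, growth_rate."""
    df = read_tsv(path)
    required = {"clone_id", "cell_id", "fluorescence", "medium", "growth_rate"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(path, 1, f"missing columns: {sorted(missing)}")
    return df


def write_cell_table(df: pd.DataFrame, path, params: Optional[dict] = None) -> None:
    write_tsv(df, path, params)


def write_lineage(tree: LineageTree, edges_path, series_path, params: Optional[dict] = None) -> None:
    """Write a lineage tree as an edge-list TSV plus a long-format series TSV."""
    rows = [
        {
            "cell_id": cid,
            "parent_id": node.parent_id if node.parent_id is not None else "",
            "birth_min": node.birth_min,
            "end_min": node.end_min,
        }
        for cid, node in sorted(tree.nodes.items())
    ]
    write_tsv(pd.DataFrame(rows), edges_path, params)
    srows = []
    for cid in sorted(tree.series):
        t, x = tree.series[cid]
        for ti, xi in zip(np.asarray(t), np.asarray(x)):
            srows.append({"cell_id": cid, "time_min": ti, "expression": xi})
    write_tsv(pd.DataFrame(srows), series_path, params)


def read_lineage(edges_path, series_path, colony_id: str = "colony") -> LineageTree:
    edges = pd.read_csv(edges_path, sep="\t", comment="#",
                        dtype={"cell_id": str, "parent_id": str}, keep_default_na=False)
    series = pd.read_csv(series_path, sep="\t", comment="#", dtype={"cell_id": str})
    nodes = {}
    for _, row in edges.iterrows():
        parent = row["parent_id"]
        parent = None if (pd.isna(parent) or str(parent) == "") else str(parent)
        nodes[str(row["cell_id"])] = CellNode(
            cell_id=str(row["cell_id"]),
            parent_id=parent,
            birth_min=float(row["birth_min"]),
            end_min=float(row["end_min"]),
        )
    ser = {}
    for cid, grp in series.groupby("cell_id"):
        grp = grp.sort_values("time_min")
        ser[str(cid)] = (
            grp["time_min"].to_numpy(dtype=float),
            grp["expression"].to_numpy(dtype=float),
        )
    return LineageTree(colony_id=colony_id, nodes=nodes, series=ser)
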