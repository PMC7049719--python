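"""End-to-end orchestration: simulate -> coverage -> dosage fit -> enrichment
-> AT bias -> noise -> lineage, with one master seed and a run manifest.

Per-stage seeds are derived deterministically as
``crc32(f"{seed}:{stage}") % 2**31`` so reordering or disabling stages cannot
change the substream any other stage sees. The manifest records inputs,
parameters, the seed and a sha256 checksum of every output, which makes
byte-identical reruns checkable.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
import yaml

from . import io as ifio
from .atcontent import insertion_at_bias_test
from .core import GenomeSpec, InsertionSet
from .coverage import oriter_asymmetry, sliding_coverage
from .dosage import fit_dosage_exponent
from .enrichment import enrichment_z
from .errors import ValidationError
from .noise import clone_stats, fit_noise_scaling
from .lineage import sister_divergence
from .synth import (
    SynthConfig,
    assign_clone_phenotypes,
    make_genome,
    sample_cell_expression,
    sample_insertions,
    simulate_microcolony,
)

__all__ = ["PipelineConfig", "run_pipeline", "stage_seed", "load_config"]

ALL_STAGES = ("simulate", "coverage", "dosage_fit", "enrich", "atbias", "noise", "lineage")


def stage_seed(seed: int, stage: str) -> int:
    return zlib.crc32(f"{seed}:{stage}".encode()) % (2**31)


@dataclass
class PipelineConfig:
    outdir: str
    seed: int = 0
    stages: List[str] = field(default_factory=lambda: list(ALL_STAGES))
    synth: Dict = field(default_factory=dict)  # SynthConfig field overrides
    coverage: Dict = field(default_factory=lambda: {"window_bp": 3000, "step_bp": 1000})
    dosage_fit: Dict = field(default_factory=lambda: {"n_bins": 100})
    enrich: Dict = field(
        default_factory=lambda: {
            "n_shuffles": 5000,
            "flank_bp": 0,
            "background_window_bp": 25000,
            "lists": ["hns_islands", "essential", "regulator_targets"],
        }
    )
    atbias: Dict = field(default_factory=lambda: {"window_bp": 1000, "n_background": 5000})
    noise: Dict = field(default_factory=lambda: {"threshold_k": 3.5, "n_clones": 80,
                                                 "cells_per_clone": 300})
    lineage: Dict = field(default_factory=lambda: {"n_colonies_per_class": 3})
    inputs: Dict = field(default_factory=dict)  # used when 'simulate' is disabled

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValidationError(f"unknown stages: {sorted(unknown)}")


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return PipelineConfig(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in dependency order and return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    outputs: Dict[str, Path] = {}
    ctx: dict = {}

    synth_cfg = SynthConfig(**{**config.synth, "seed": stage_seed(config.seed, "simulate")})
    genome: Optional[GenomeSpec] = None

    def register(stage: str, paths: List[Path], params: dict) -> None:
        manifest["stages"][stage] = {
            "params": params,
            "outputs": {p.name: _sha256(p) for p in paths},
        }
        for p in paths:
            outputs[p.name] = p

    def need(stage: str, key: str):
        if key not in ctx:
            raise ValidationError(
                f"stage '{stage}' requires '{key}'; enable the producing stage "
                "or provide it under 'inputs'"
            )
        return ctx[key]

    # resolve externally provided inputs when simulate is off
    if "simulate" not in config.stages:
        if "genome_length_bp" in config.inputs:
            genome = GenomeSpec(
                int(config.inputs["genome_length_bp"]),
                int(config.inputs.get("ori_pos", 0)),
                config.inputs.get("ter_pos"),
            )
            ctx["genome"] = genome
        if "insertions" in config.inputs and "genome" in ctx:
            ctx["insertions"] = ifio.read_insertions(config.inputs["insertions"], ctx["genome"])
        if "genome_fasta" in config.inputs:
            ctx["sequence"] = ifio.read_fasta(config.inputs["genome_fasta"])

    for stage in ALL_STAGES:
        if stage not in config.stages:
            continue
        sseed = stage_seed(config.seed, stage)
        if stage == "simulate":
            ann = make_genome(synth_cfg)
            ins = sample_insertions(ann, synth_cfg)
            ctx.update(genome=ann.spec, sequence=ann.sequence, insertions=ins, annotated=ann)
            paths = [outdir / "genome.fasta"]
            ifio.write_fasta(ann.sequence, paths[0])
            for name, iset in ann.intervals.items():
                p = outdir / f"{name}.bed"
                ifio.write_intervals(iset, p)
                paths.append(p)
            p = outdir / "insertions.tsv"
            ifio.write_insertions(ins, p, params={"seed": sseed, "stage": stage})
            paths.append(p)
            clones = assign_clone_phenotypes(ins, ann, synth_cfg)
            ctx["clones"] = clones
            rows = []
            ncfg = config.noise
            rng = np.random.default_rng(sseed + 2)
            chosen = rng.choice(len(clones), size=min(ncfg["n_clones"], len(clones)),
                                replace=False)
            for j, ci in enumerate(sorted(chosen)):
                clone = clones[ci]
                expr = sample_cell_expression(
                    clone, ncfg["cells_per_clone"], "LB", synth_cfg, seed=sseed + 10 + j
                )
                for k, v in enumerate(expr.cells):
                    rows.append(
                        {
                            "clone_id": expr.clone_id,
                            "cell_id": f"{expr.clone_id}_c{k}",
                            "fluorescence": v,
                            "medium": expr.medium,
                            "growth_rate": expr.growth_rate,
                            "copy_number": expr.copy_number,
                        }
                    )
            p = outdir / "cells.tsv"
            ifio.write_cell_table(pd.DataFrame(rows), p, params={"seed": sseed})
            paths.append(p)
            ctx["cells_table"] = p
            trees = []
            lcfg = config.lineage
            normal = next(c for c in clones if c.clone_class == "normal")
            switching = next((c for c in clones if c.clone_class == "rrn_switching"), None)
            for label, proto in (("normal", normal), ("switching", switching)):
                if proto is None:
                    continue
                for r in range(lcfg["n_colonies_per_class"]):
                    tree = simulate_microcolony(proto, synth_cfg, seed=sseed + 100 + r)
                    tree.colony_id = f"{label}_{r}"
                    ep = outdir / f"lineage_{label}_{r}_edges.tsv"
                    sp = outdir / f"lineage_{label}_{r}_series.tsv"
                    ifio.write_lineage(tree, ep, sp, params={"seed": sseed})
                    paths += [ep, sp]
                    trees.append(tree)
            ctx["trees"] = trees
            register(stage, paths, {"seed": sseed, **{k: v for k, v in asdict(synth_cfg).items()
                                                      if not isinstance(v, dict)}})
        elif stage == "coverage":
            ins = need(stage, "insertions")
            g = need(stage, "genome")
            prof = sliding_coverage(ins, g, **config.coverage)
            ctx["coverage_profile"] = prof
            asym = oriter_asymmetry(prof, g)
            p = outdir / "coverage.tsv"
            df = pd.DataFrame(
                {"bin_start": prof.centers - prof.window_bp // 2,
                 "bin_center": prof.centers, "value": prof.values}
            )
            ifio.write_tsv(df, p, params={**config.coverage, "oriter_asymmetry": asym})
            register(stage, [p], {**config.coverage, "oriter_asymmetry": asym})
        elif stage == "dosage_fit":
            ins = need(stage, "insertions")
            g = need(stage, "genome")
            n_bins = config.dosage_fit["n_bins"]
            width = g.length_bp // n_bins
            obs = sliding_coverage(ins, g, window_bp=width, step_bp=width)
            from .dosage import dosage_prediction_for
            pred = dosage_prediction_for(obs, synth_cfg.dosage)
            fit = fit_dosage_exponent(obs, pred)
            ctx["dosage_fit"] = fit
            p = outdir / "dosage_fit.tsv"
            ifio.write_tsv(pd.DataFrame([asdict(fit)]), p, params=config.dosage_fit)
            register(stage, [p], config.dosage_fit)
        elif stage == "enrich":
            ins = need(stage, "insertions")
            g = need(stage, "genome")
            ecfg = config.enrich
            bg = sliding_coverage(
                ins.as_sites(), g, window_bp=ecfg["background_window_bp"],
                step_bp=max(ecfg["background_window_bp"] // 10, 1)
            )
            rows = []
            for li, name in enumerate(ecfg["lists"]):
                if "annotated" in ctx and name in ctx["annotated"].intervals:
                    iset = ctx["annotated"].intervals[name]
                else:
                    iset = ifio.read_intervals(name, g)
                res = enrichment_z(
                    ins.as_sites(), iset, bg,
                    flank_bp=ecfg["flank_bp"], n_shuffles=ecfg["n_shuffles"],
                    seed=sseed + li,
                )
                rows.append(asdict(res) if hasattr(res, "__dataclass_fields__") else res.__dict__)
            p = outdir / "enrichment.tsv"
            ifio.write_tsv(pd.DataFrame(rows), p, params={"seed": sseed, **{
                k: v for k, v in ecfg.items() if k != "lists"}})
            ctx["enrichment"] = rows
            register(stage, [p], {"seed": sseed, "n_shuffles": ecfg["n_shuffles"]})
        elif stage == "atbias":
            ins = need(stage, "insertions")
            g = need(stage, "genome")
            seq = need(stage, "sequence")
            res = insertion_at_bias_test(
                ins, seq, g, window_bp=config.atbias["window_bp"],
                n_background=config.atbias["n_background"], seed=sseed,
            )
            p = outdir / "atbias.tsv"
            ifio.write_tsv(pd.DataFrame([res.__dict__]), p, params={"seed": sseed})
            ctx["atbias"] = res
            register(stage, [p], {"seed": sseed, **config.atbias})
        elif stage == "noise":
            table = need(stage, "cells_table")
            df = ifio.read_cell_table(table)
            stats_rows = []
            stats_list = []
            for cid, grp in df.groupby("clone_id"):
                cn = int(grp["copy_number"].iloc[0]) if "copy_number" in grp.columns else 1
                s = clone_stats(grp["fluorescence"].to_numpy(), str(cid), copy_number=cn)
                stats_list.append(s)
                stats_rows.append(s.__dict__)
            fit = fit_noise_scaling(stats_list, threshold_k=config.noise["threshold_k"])
            ctx["noise_fit"] = fit
            p1 = outdir / "clone_stats.tsv"
            ifio.write_tsv(pd.DataFrame(stats_rows), p1, params={"seed": sseed})
            p2 = outdir / "noise_fit.tsv"
            fit_row = {**{k: v for k, v in fit.__dict__.items() if k != "outlier_ids"},
                       "outlier_ids": ",".join(fit.outlier_ids)}
            ifio.write_tsv(pd.DataFrame([fit_row]), p2, params={"seed": sseed})
            register(stage, [p1, p2], {"threshold_k": config.noise["threshold_k"]})
        elif stage == "lineage":
            trees = need(stage, "trees")
            rows = []
            for tree in trees:
                res = sister_divergence(tree)
                rows.append(
                    {"colony_id": res.colony_id, "colony_divergence": res.colony_divergence,
                     "n_pairs": res.n_pairs}
                )
            p = outdir / "divergence.tsv"
            ifio.write_tsv(pd.DataFrame(rows), p, params={"seed": sseed})
            register(stage, [p], {})

    manifest["outputs"] = {name: _sha256(path) for name, path in outputs.items()}
    mpath = outdir / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
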