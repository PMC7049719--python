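"""Run every stage end to end from one config and inspect the manifest.

simulate -> coverage -> dosage fit -> enrichment -> AT bias -> noise ->
lineage, all seeded from one master seed; rerunning with the same config
reproduces byte-identical outputs (sha256-checked).
"""

import tempfile
from pathlib import Path

from insertion_fate.pipeline import PipelineConfig, run_pipeline

with tempfile.TemporaryDirectory() as tmp:
    cfg = PipelineConfig(
        outdir=str(Path(tmp) / "run"),
        seed=42,
        synth={"length_bp": 200_000, "at_island_count": 10, "essential_count": 12,
               "n_insertions": 4000},
        enrich={"n_shuffles": 1000, "flank_bp": 0, "background_window_bp": 25_000,
                "lists": ["hns_islands", "essential"]},
        noise={"threshold_k": 3.5, "n_clones": 40, "cells_per_clone": 200},
        lineage={"n_colonies_per_class": 2},
        atbias={"window_bp": 1000, "n_background": 2000},
    )
    manifest = run_pipeline(cfg)
    print(f"stages run: {', '.join(manifest['stages'])}")
    print(f"outputs written: {len(manifest['outputs'])} files")
    fit = manifest["stages"]["dosage_fit"]
    print(f"dosage_fit params: {fit['params']}")
    rerun = run_pipeline(PipelineConfig(**{**cfg.__dict__,
                                           "outdir": str(Path(tmp) / "rerun")}))
    print("byte-identical rerun:", manifest["outputs"] == rerun["outputs"])
print("-> the manifest records parameters, per-stage seeds and sha256 checksums,")
print("   so any result can be traced and reproduced exactly.")
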