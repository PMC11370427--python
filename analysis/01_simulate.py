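#!/usr/bin/env python
"""Generate the synthetic study inputs.

Produces, under results/run/: a cell-candidate cloud with planted sub-9-μm
duplicates, a Voronoi label volume with gray/white/clear regions, a
143-region × 13-animal count matrix with planted community structure, and a
per-animal whole-brain density table for the euthanasia time course
(rack/HT/5/15/30/60/120 min, 7 female + 6 male per group).
"""

from pathlib import Path

from cfosnet.pipeline import PipelineConfig, run_pipeline

OUT = Path(__file__).resolve().parent.parent / "results" / "run"

config = PipelineConfig(
    out_dir=str(OUT),
    seed=20240915,
    stages=("simulate",),
    n_regions=143,
    n_white=12,
    volume_shape=(72, 72, 72),
    n_cells=400,
    n_duplicates=80,
    n_animals=13,
)

if __name__ == "__main__":
    run_pipeline(config)
    print(f"synthetic inputs written to {OUT}")
    print(
        f"  {config.n_cells} true cells + {config.n_duplicates} planted duplicates, "
        f"{config.n_regions} gray + {config.n_white} white regions, "
        f"{config.n_animals} animals in the 15-min group"
    )
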