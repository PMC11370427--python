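#!/usr/bin/env python
"""Build the functional connectome for the 15-min group.

Computes Pearson correlations between all gray-matter regions across
animals, sweeps the efficiency-cost quality function J = (E_g + Ē_l)/ρ over
the density grid, and thresholds the matrix at the J-maximizing density,
keeping signed correlations on the surviving edges.
"""

import dataclasses
import importlib.util
from pathlib import Path

import pandas as pd

from cfosnet.pipeline import run_pipeline

_spec = importlib.util.spec_from_file_location(
    "sim", Path(__file__).resolve().parent / "01_simulate.py"
)
_sim = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_sim)

OUT = _sim.OUT

if __name__ == "__main__":
    config = dataclasses.replace(_sim.config, stages=("counts", "connectome"))
    run_pipeline(config)

    curve = pd.read_csv(OUT / "eco_curve.tsv", sep="\t")
    best = curve.loc[curve["j"].idxmax()]
    edges = pd.read_csv(OUT / "network_edges.tsv", sep="\t")
    print(f"ECO sweep over {len(curve)} densities "
          f"({curve['density'].min():.3f}-{curve['density'].max():.3f})")
    print(f"selected density {best['density']:.3f} "
          f"(J={best['j']:.2f}, E_g={best['e_global']:.3f}, "
          f"mean E_l={best['e_local_mean']:.3f})")
    n_neg = int((edges['r'] < 0).sum())
    print(f"network: {len(edges)} edges, {n_neg} with negative correlation; "
          f"mean degree {2 * len(edges) / 143:.2f}")
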