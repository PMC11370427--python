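# cfosnet

Whole-brain activity mapping and functional-connectome analysis for adult
zebrafish.

Immediate-early-gene (*cfos*) labelling in cleared whole brains yields, per
animal, a cloud of detected cell candidates and a registered atlas
parcellation. This package implements everything downstream of detection
and registration:

1. **Candidate post-processing** — greedy minimum-separation deduplication
   (default 9 μm, computed in physical units from anisotropic voxel
   spacing) and label-volume lookup into per-region counts and whole-brain
   densities (cells/mm³ over gray matter).
2. **Connectome construction** — region × region Pearson correlations
   across the animals of a group, thresholded into a sparse network by
   efficiency-cost optimization: choose the density ρ maximizing
   J(ρ) = (E_g + Ē_l)/ρ, with E_g the global efficiency and Ē_l the mean
   local efficiency of the binarized |r| network.
3. **Network characterisation** — degree and eigenvector centrality,
   seeded Louvain communities, node-role cartography from the
   within-module degree z-score z_i = (κ_i − κ̄_s)/σ_κs and participation
   coefficient P_i = 1 − Σ_s (K_is/K_i)², and the small-world coefficient
   σ = (C_g/C_rand)/(L_g/L_rand) against 1,000 Erdős–Rényi G(n, m) graphs
   matched in nodes and edges.
4. **Time-course statistics** — sex × time ANOVA with η², Monte-Carlo
   Dunnett comparisons against the home-tank control, Cohen's d, and
   BH-FDR-corrected paired t-tests.
5. **Synthetic data** — generators for candidate clouds with planted
   duplicates, label volumes, count matrices with planted community
   structure, and time-course tables, each returning ground truth for
   recovery testing.

See `docs/methods.md` for conventions and modelling choices.

## Worked example

The numbered scripts under `analysis/` run the whole pipeline on synthetic
data with known ground truth, writing artifacts to `results/run/`:

```sh
python analysis/01_simulate.py
python analysis/02_count_cells.py
python analysis/03_connectome.py
python analysis/04_network_metrics.py
python analysis/05_timecourse_stats.py
```

Output of a run (seed 20240915):

```
dedup: 480 candidates -> 400 kept (80 removed; planted duplicates recovered exactly: True)
aggregation: 180 candidates discarded (white matter / clear / out of volume); whole-brain density 18727.9 cells/mm^3
ECO sweep over 100 densities (0.005-0.500)
selected density 0.015 (J=21.46, E_g=0.023, mean E_l=0.299)
network: 152 edges, 0 with negative correlation; mean degree 2.13
82 communities found (ARI vs planted partition: 0.48)
role counts: {'peripheral node': 143}
small-world: L_g=1.69 vs L_rand=5.80, C_g=0.664 vs C_rand=0.0148 -> sigma=153.9
sex x time ANOVA:
  sex       F=1.43  p=0.24  eta^2=0.012
  group     F=6.52  p=1.4e-05  eta^2=0.330
  sex:group F=0.16  p=0.99  eta^2=0.008
Dunnett vs home tank: peak at 15 min (adj p=0.00025, d=1.44)
```

Reading this: all 80 planted sub-9-μm duplicates were removed and no true
cell was lost; ECO selected a 1.5% density, keeping only the strongest
within-community correlations, so the network is a handful of near-cliques
plus many isolated regions (hence the partial partition recovery, the
all-peripheral role classification, and the very high σ — see the caveat
on equicorrelated blocks at small sample size in `docs/methods.md`); and
the time-course analysis recovers the planted 15-minute activity peak
against the home-tank control with a large effect size.

The same stages are available as a CLI (`cfosnet run --seed 7 --out run/`,
or per stage: `cfosnet dedup`, `cfosnet aggregate`, `cfosnet connectome`,
`cfosnet metrics`, `cfosnet stats`), all thin wrappers over the library
modules in `src/cfosnet/`.

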