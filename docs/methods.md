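# Methods

`cfosnet` post-processes whole-brain immediate-early-gene activity maps of
adult zebrafish and analyses them as functional networks. This note records
the models and procedures implemented, the conventions chosen where the
underlying methods literature leaves freedom, and what the synthetic data do
and do not establish.

## Candidate deduplication

Spot-detection algorithms applied to cleared light-sheet volumes report the
same soma repeatedly. We enforce a minimum separation of 9 μm (about one
soma diameter) between retained candidates. "Remove candidates within 9 μm
of one another" is ambiguous about *which* member of a close pair survives;
pairwise deletion would discard genuinely distinct cells that happen to sit
near a duplicate, so we implement greedy retention: candidates are visited
in a deterministic priority order — descending detection intensity, ties by
(z, y, x) coordinates, then id — and kept iff no already-kept candidate
lies strictly within 9 μm. This keeps exactly one representative per
conflict cluster, is idempotent, and matches a brute-force O(n²)
implementation of the same rule on every fixture we test.

Distances are physical. Candidates detected on the anisotropic acquisition
grid (3.990 μm axial × 0.943 μm in-plane) are converted to μm before any
distance is computed, because a 9-μm criterion only makes sense in physical
units: two detections 3 voxels apart along the coarse axis are 11.97 μm
apart and must both survive.

## Regional aggregation

Surviving candidates are assigned to atlas regions by direct lookup in a
registered integer label volume (4 μm isotropic). The voxel of a point is
`floor((point − origin)/voxel_size)` with 0-based indices and the voxel
origin at its minimum corner; a point exactly on the upper boundary of the
volume is outside. Candidates landing outside the array, on label 0
("clear") or on white-matter labels are tallied as discarded, never
counted, and counts + discarded always equals the number of input
candidates. Whole-brain density is total gray-matter count divided by total
gray-matter volume (cells/mm³). Registration itself is upstream and out of
scope; candidates are assumed to be in the label volume's space.

## Connectome construction

For one experimental group, the edge weight between two regions is the
Pearson correlation of their counts across animals (minimum three animals;
zero-variance regions get correlation 0 and are flagged rather than dropped,
keeping the matrix total and the exclusion auditable).

The matrix is thresholded at a network density ρ by keeping the
`round(ρ·R(R−1)/2)` edges of largest |r|, ties broken by lexicographic node
pair so the edge set is a pure function of the matrix. Signed correlations
are carried on kept edges for reporting and export; **all** topological
metrics run on the binarized |r| view. The density is chosen by
efficiency-cost optimization (ECO): maximize

    J(ρ) = (E_g + Ē_l) / ρ

over a density grid, where E_g is global efficiency (mean over ordered node
pairs of 1/shortest-path-length, unreachable pairs contributing 0) and Ē_l
the mean local efficiency (each node's score is the global efficiency of
its neighbour-induced subgraph; degree < 2 scores 0). The default grid is
0.5%–50% in 0.5% steps; ties in J go to the sparsest density. A quoted
density of 2.5% over 143 regions implies 253.8 pairs while the matched
network has 256 edges, so nominal density and realized edge count cannot
both be exact; we treat the grid density as nominal and report the realized
edge count and density alongside.

## Network metrics

* **Centralities.** Degree on the binary view; eigenvector centrality as
  the leading eigenvector of the binary adjacency (symmetric
  eigendecomposition), taken nonnegative and max-normalized to 1. On
  disconnected graphs the centrality concentrates on the component with the
  largest adjacency eigenvalue; we compute on the full graph rather than
  restricting to the giant component.
* **Communities.** Louvain modularity maximisation (seeded, so the sweep
  order and hence the partition are reproducible); community ids renumbered
  contiguously; modularity reported.
* **Node roles.** Within-module degree z-score
  z_i = (κ_i − κ̄_s)/σ_κs, with κ the within-community degree and σ the
  *population* (÷n) standard deviation (÷(n−1) available via `ddof`);
  communities with σ = 0 assign z = 0. Participation coefficient
  P_i = 1 − Σ_s (K_is/K_i)², P = 0 for isolated nodes. Roles follow the
  hub/connector cartography with the paper-standard boundaries collapsed to
  four classes: hubs at z ≥ 2.5, split provincial vs connector at P = 0.30;
  non-hubs split peripheral vs non-hub connector at P = 0.62. All three
  thresholds are configurable and echoed into outputs.
* **Small-worldness.** σ = (C_g/C_rand)/(L_g/L_rand). The average shortest
  path L is taken over *reachable* ordered pairs only — necessary because
  ECO-selected networks are usually disconnected, yet the statistic is still
  quoted for them. The clustering coefficient C averages local clustering
  over nodes of degree ≥ 2 by default; the alternative convention (count
  low-degree nodes as 0) is available because published null values sit
  between the two. Null values L_rand, C_rand are means over 1,000
  Erdős–Rényi G(n, m) graphs — uniform over simple graphs with *exactly*
  the observed node and edge counts, not an edge-probability model —
  skipping (and counting) replicates where a statistic is undefined.

## Time-course statistics

Whole-brain densities across euthanasia delays are analysed with a
sex × time fixed-effects ANOVA (statsmodels OLS; Type II sums of squares by
default, appropriate for the mildly unbalanced 7 F + 6 M cells; Types I and
III available and logged) with classical η² = SS_effect/SS_total. Group
comparisons against the home-tank control use Dunnett's many-to-one
procedure: pooled variance across all groups, and familywise adjustment by
referring each |t| to the Monte-Carlo distribution of max_j |T_j| under the
equicorrelated multivariate-t implied by the shared control (20,000 seeded
draws by default; the Monte-Carlo standard error of each adjusted p is
reported). Effect sizes are Cohen's d with the (n₁+n₂−2)-pooled SD. Nuclear
vs cytoplasmic comparisons use two-sided paired t-tests with
Benjamini–Hochberg FDR adjustment.

## Synthetic data

No per-animal raw data accompany the study this package targets, so every
stage is validated on generated inputs with known ground truth:

* **Candidate clouds.** Parents placed by dart throwing at ≥ 25 μm mutual
  separation; duplicates strictly within 4 μm of a random parent, with
  intensities drawn strictly below all parent intensities. Under these
  conditions the greedy 9-μm rule removes exactly the planted duplicates,
  which the tests assert.
* **Label volumes.** Voronoi parcellation of an ellipsoidal mask; outside
  voxels are "clear" (label 0), a subset of regions is flagged white
  matter, and per-region volumes are tabulated from voxel counts.
* **Count matrices.** A latent animal × region Gaussian with equicorrelated
  block covariance (within-community correlation 0.8, between 0.0 by
  default; positive semi-definiteness checked at construction) is pushed
  through an exponential link scaled to a marginal mean of 200 counts
  (latent log-SD 0.5, giving overdispersed lognormal-like marginals) and
  rounded to nonnegative integers. The link is monotone, so the planted
  correlation ordering survives; the default emulates 143 gray regions ×
  13 animals. The count-distribution family is a modelling choice — only
  the correlation structure matters downstream — and counts are *not*
  calibrated to any real per-region distribution.
* **Time course.** Normal densities per animal with group means peaking at
  15 min at ≈ 3.5× the home-tank baseline (defaults: HT 34, peak 120
  cells/mm³, SD 40, 7 F + 6 M per group), chosen to sit in the d ≈ 2
  effect-size regime the published design detects; negative draws are
  clipped at zero, which slightly truncates the low-baseline groups.

**What passing tests show — and what they do not.** The synthetic data
establish that each algorithm implements its definition (against
independent brute-force oracles), that planted duplicates and planted
correlation blocks are recoverable under favourable conditions, and that
the statistical procedures are calibrated (Dunnett familywise error 5% at
the nominal level). They do not establish robustness to registration error,
detection sensitivity differences across brain regions, or non-lognormal
count dispersion, none of which the generators model.

A caveat worth stating explicitly: with an equicorrelated block covariance
estimated from ~13–40 animals, the sample correlations of all pairs inside
one community are strongly mutually dependent (they share the community's
realized factor), so the largest |r| values concentrate in a few "lucky"
communities. ECO's J then peaks at very sparse densities (0.5–3%) where the
kept edges form near-cliques of those communities, and Louvain on the
ECO-selected network recovers only part of the planted partition (median
ARI ≈ 0.5 at 40 animals). At a fixed 5% density — enough to cover the
within-community pairs — recovery is nearly exact (median ARI ≈ 0.94),
which is what the generator tests assert. Full recovery through the ECO
density itself should not be expected under this sampling regime.

## Numerical conventions and problem sizes

Shortest paths use Dijkstra on sparse adjacency (scipy.sparse.csgraph) with
unit weights; eigencentrality uses dense symmetric eigendecomposition
(networks here have ≤ a few hundred nodes). Determinism: every random
component (generators, Louvain sweep, ER ensemble, Dunnett Monte-Carlo)
takes an explicit seed, and the pipeline derives per-stage seeds from one
global seed by hashing, so a config + seed pair reproduces every artifact
byte-for-byte. Default problem sizes — 1,000-replicate ER ensembles,
20,000-draw Dunnett integration, 2,000-replicate calibration simulations,
20-seed recovery medians — keep a full test-and-analysis cycle to a few
minutes on one core while leaving Monte-Carlo error well below the decision
thresholds they support.

## Known limitations

* Cell detection, nuclear/cytoplasmic classification and image registration
  are upstream and out of scope; an optional staining-category column is
  passed through untouched.
* No partial correlations, covariance shrinkage, or edge-significance
  permutation tests: edges are raw Pearson correlations thresholded by
  density, as in the analysis this package reimplements.
* Efficiency and clustering are unweighted; weighted generalizations are
  deliberately not offered.
* The Erdős–Rényi null preserves node and edge counts only, not the degree
  sequence; configuration-model nulls are out of scope.
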