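"""Functional-connectome construction from regional activity counts.

Nodes are atlas gray-matter regions; the edge weight between two regions is
the Pearson correlation of their cfos-positive cell counts across the animals
of one experimental group. The full correlation matrix is thresholded into a
sparse network by efficiency-cost optimization (ECO): sweep the network
density ρ, and keep the density maximizing

    J(ρ) = (E_g + Ē_l) / ρ

where E_g is the global efficiency of the binarized network (edge present iff
|r| is above the density cut) and Ē_l the mean local efficiency. Signed
correlations are retained on the kept edges for reporting; every topological
metric runs on the binary |r| view.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path

from .candidates import CountMatrix

#: Default ECO density sweep: 0.5% to 50% in 0.5% steps.
DEFAULT_ECO_GRID = tuple(np.round(np.arange(0.005, 0.5001, 0.005), 10))


class InsufficientSampleError(ValueError):
    """Too few animals to estimate correlations."""


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric region × region Pearson correlation matrix.

    ``values`` is an R×R DataFrame with unit diagonal, indexed by region
    abbreviation both ways; ``n_animals`` records the sample size behind every
    entry; ``zero_variance`` lists regions whose counts did not vary across
    animals (their correlations are recorded as 0).
    """

    values: pd.DataFrame
    n_animals: int
    zero_variance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        a = self.values.to_numpy(dtype=float)
        if a.shape[0] != a.shape[1]:
            raise ValueError("correlation matrix must be square")
        if not np.allclose(a, a.T, atol=1e-12):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(a), 1.0):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.nanmax(np.abs(a)) > 1 + 1e-12:
            raise ValueError("correlations must lie in [-1, 1]")

    @property
    def region_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_regions(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class BrainNetwork:
    """Thresholded functional network over brain regions.

    ``weights`` holds the signed correlation on kept edges (0 elsewhere);
    ``adjacency`` is the binary |r| view used for all path-based metrics.
    """

    region_ids: tuple[str, ...]
    weights: np.ndarray
    nominal_density: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.shape != (len(self.region_ids),) * 2:
            raise ValueError("weights shape must match region_ids")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.any(np.diag(w) != 0):
            raise ValueError("self-loops are not allowed")
        object.__setattr__(self, "weights", w)

    @property
    def adjacency(self) -> np.ndarray:
        return self.weights != 0

    @property
    def n_nodes(self) -> int:
        return len(self.region_ids)

    @property
    def n_edges(self) -> int:
        return int(np.count_nonzero(np.triu(self.adjacency, k=1)))

    @property
    def realized_density(self) -> float:
        n = self.n_nodes
        n_pairs = n * (n - 1) // 2
        return self.n_edges / n_pairs if n_pairs else 0.0

    def edge_list(self) -> pd.DataFrame:
        iu, ju = np.nonzero(np.triu(self.adjacency, k=1))
        ids = np.asarray(self.region_ids)
        return pd.DataFrame(
            {"source": ids[iu], "target": ids[ju], "r": self.weights[iu, ju]}
        )

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.region_ids)
        for row in self.edge_list().itertuples(index=False):
            g.add_edge(row.source, row.target, r=float(row.r))
        return g


@dataclass(frozen=True)
class ECOResult:
    """Full efficiency-cost sweep and the selected density."""

    curve: pd.DataFrame  # columns: density, e_global, e_local_mean, j, n_edges
    selected_density: float

    @property
    def selected_row(self) -> pd.Series:
        return self.curve.loc[self.curve["density"] == self.selected_density].iloc[0]


def correlation_matrix(counts: CountMatrix, group=None) -> CorrelationMatrix:
    """Pearson correlations between regions across the animals of one group.

    Regions with zero variance across animals get correlation 0 with every
    other region (flagged in the result) so the matrix stays total and the
    exclusion auditable.
    """
    sub = counts if group is None else counts.subset_group(group)
    x = sub.values.to_numpy(dtype=float)
    n_animals = x.shape[0]
    if n_animals < 3:
        raise InsufficientSampleError(
            f"need >= 3 animals for correlations, got {n_animals}"
        )
    sd = x.std(axis=0)
    zero_var = sd == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(x, rowvar=False)
    r[zero_var, :] = 0.0
    r[:, zero_var] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    values = pd.DataFrame(r, index=sub.values.columns, columns=sub.values.columns)
    flagged = tuple(np.asarray(sub.values.columns)[zero_var])
    return CorrelationMatrix(values=values, n_animals=n_animals, zero_variance=flagged)


def threshold_at_density(c: CorrelationMatrix, density: float) -> BrainNetwork:
    """Keep the ``round(ρ · R(R−1)/2)`` edges of largest absolute correlation.

    Ties in |r| at the cut are broken by lexicographic (i, j) index order, so
    the edge set is a deterministic function of the matrix alone. Signed r is
    retained on kept edges.
    """
    if not (0 < density <= 1):
        raise ValueError(f"density must be in (0, 1], got {density}")
    r = c.values.to_numpy(dtype=float)
    n = r.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    n_pairs = len(iu)
    m = int(round(density * n_pairs))
    vals = r[iu, ju]
    # sort by (-|r|, i, j): descending magnitude, deterministic tie-break
    order = np.lexsort((ju, iu, -np.abs(vals)))
    keep = order[:m]
    w = np.zeros_like(r)
    w[iu[keep], ju[keep]] = vals[keep]
    w += w.T
    return BrainNetwork(
        region_ids=tuple(c.region_ids), weights=w, nominal_density=float(density)
    )


def _pairwise_hops(adj: np.ndarray) -> np.ndarray:
    """All-pairs unweighted shortest-path lengths (inf where unreachable)."""
    n = adj.shape[0]
    if n == 0:
        return np.zeros((0, 0))
    return shortest_path(
        csr_matrix(adj.astype(np.int8)), method="D", unweighted=True, directed=False
    )


def global_efficiency_adj(adj: np.ndarray) -> float:
    """Global efficiency of a binary adjacency matrix.

    Mean over ordered node pairs of 1/d(i, j); unreachable pairs contribute 0.
    A graph with fewer than two nodes has efficiency 0.
    """
    n = adj.shape[0]
    if n < 2:
        return 0.0
    d = _pairwise_hops(adj)
    off = ~np.eye(n, dtype=bool)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & off, 1.0 / np.where(d == 0, np.inf, d), 0.0)
    return float(inv[off].sum() / (n * (n - 1)))


def local_efficiency_adj(adj: np.ndarray) -> tuple[np.ndarray, float]:
    """Per-node local efficiency and its mean over all nodes.

    A node's local efficiency is the global efficiency of the subgraph induced
    by its neighbours (the node itself excluded); nodes of degree < 2 score 0.
    """
    n = adj.shape[0]
    eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if len(nb) < 2:
            continue
        eff[i] = global_efficiency_adj(adj[np.ix_(nb, nb)])
    return eff, (float(eff.mean()) if n else 0.0)


def global_efficiency(net: BrainNetwork) -> float:
    return global_efficiency_adj(net.adjacency)


def local_efficiency(net: BrainNetwork) -> tuple[np.ndarray, float]:
    return local_efficiency_adj(net.adjacency)


def eco_quality(c: CorrelationMatrix, density: float) -> tuple[float, float, float]:
    """Evaluate (E_g, Ē_l, J) of the network thresholded at ``density``."""
    net = threshold_at_density(c, density)
    e_g = global_efficiency(net)
    _, e_l = local_efficiency(net)
    return e_g, e_l, (e_g + e_l) / density


def eco_optimize(
    c: CorrelationMatrix, grid: tuple[float, ...] = DEFAULT_ECO_GRID
) -> ECOResult:
    """Sweep the density grid and select the J-maximizing density.

    The grid must be nonempty, strictly increasing and within (0, 1]. Ties in
    J go to the first (sparsest) attaining density.
    """
    grid = tuple(float(g) for g in grid)
    if not grid:
        raise ValueError("density grid is empty")
    if any(not (0 < g <= 1) for g in grid):
        raise ValueError("grid densities must lie in (0, 1]")
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    rows = []
    for rho in grid:
        net = threshold_at_density(c, rho)
        e_g = global_efficiency(net)
        _, e_l = local_efficiency(net)
        rows.append(
            {
                "density": rho,
                "e_global": e_g,
                "e_local_mean": e_l,
                "j": (e_g + e_l) / rho,
                "n_edges": net.n_edges,
                "realized_density": net.realized_density,
            }
        )
    curve = pd.DataFrame(rows)
    best = int(np.argmax(curve["j"].to_numpy()))
    return ECOResult(curve=curve, selected_density=float(curve["density"].iloc[best]))
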