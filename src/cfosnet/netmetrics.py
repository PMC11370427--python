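"""Graph metrics on the thresholded functional network.

Covers the node-level and whole-network statistics used to characterise the
regional activity network: degree and eigenvector centrality, Louvain
communities, Guimerà–Amaral node-role cartography (within-module degree
z-score z_i and participation coefficient P_i), and small-worldness

    σ = (C_g / C_rand) / (L_g / L_rand)

where the random-network reference values are means over an ensemble of
Erdős–Rényi G(n, m) graphs with the same node and edge counts as the observed
network. Everything runs on the binary |r| view of the network.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .connectome import BrainNetwork, _pairwise_hops

PROVINCIAL_HUB = "provincial hub"
CONNECTOR_HUB = "connector hub"
PERIPHERAL = "peripheral node"
NONHUB_CONNECTOR = "non-hub connector"
ROLES = (PROVINCIAL_HUB, CONNECTOR_HUB, PERIPHERAL, NONHUB_CONNECTOR)

#: Hub boundary on the within-module degree z-score.
DEFAULT_Z_HUB = 2.5
#: Participation boundary separating peripheral nodes from non-hub connectors.
DEFAULT_P_CONNECTOR_NONHUB = 0.62
#: Participation boundary separating provincial from connector hubs.
DEFAULT_P_CONNECTOR_HUB = 0.30


class UndefinedMetricError(ValueError):
    """The requested statistic is undefined on this graph."""


@dataclass(frozen=True)
class CommunityPartition:
    """A hard partition of network nodes into communities.

    Community ids are contiguous integers starting at 1; ``modularity`` is
    Newman modularity of the partition on the binary view.
    """

    assignment: dict
    modularity: float

    def __post_init__(self) -> None:
        ids = sorted(set(self.assignment.values()))
        if ids != list(range(1, len(ids) + 1)):
            raise ValueError("community ids must be contiguous from 1")

    @property
    def n_communities(self) -> int:
        return len(set(self.assignment.values()))

    def labels_for(self, nodes) -> np.ndarray:
        return np.array([self.assignment[v] for v in nodes])


@dataclass(frozen=True)
class ERNullStats:
    """Ensemble-mean path length and clustering of G(n, m) random graphs."""

    l_rand: float
    c_rand: float
    n_rep: int
    n_undefined_l: int
    n_undefined_c: int
    seed: int


@dataclass(frozen=True)
class SmallWorldResult:
    l_g: float
    c_g: float
    l_rand: float
    c_rand: float
    sigma: float
    n_rand: int
    seed: int


def degree_centrality(net: BrainNetwork) -> pd.Series:
    """Binary-view degree of every region."""
    k = net.adjacency.sum(axis=1).astype(int)
    return pd.Series(k, index=list(net.region_ids), name="degree")


def eigenvector_centrality(net: BrainNetwork) -> pd.Series:
    """Leading-eigenvector centrality on the binary adjacency, max-normalized.

    For disconnected graphs the centrality concentrates on the component with
    the largest adjacency eigenvalue; other components score near 0.
    """
    if net.n_edges == 0:
        raise UndefinedMetricError("eigenvector centrality undefined on an edgeless graph")
    a = net.adjacency.astype(float)
    w, v = np.linalg.eigh(a)
    lead = np.abs(v[:, -1])
    lead = lead / lead.max()
    return pd.Series(lead, index=list(net.region_ids), name="eigenvector")


def louvain(net: BrainNetwork, seed: int = 0) -> CommunityPartition:
    """Louvain modularity maximisation on the binary view.

    The seed fixes the node sweep order, making the partition reproducible.
    Community ids are renumbered 1..N_c in order of first appearance along the
    region ordering.
    """
    g = net.to_networkx()
    comms = nx.community.louvain_communities(g, weight=None, seed=seed)
    q = nx.community.modularity(g, comms, weight=None)
    raw = {}
    for cid, members in enumerate(comms):
        for v in members:
            raw[v] = cid
    relabel, nxt = {}, 1
    assignment = {}
    for v in net.region_ids:
        c = raw[v]
        if c not in relabel:
            relabel[c] = nxt
            nxt += 1
        assignment[v] = relabel[c]
    return CommunityPartition(assignment=assignment, modularity=float(q))


def _check_partition(net: BrainNetwork, part: CommunityPartition) -> None:
    if set(part.assignment) != set(net.region_ids):
        raise ValueError("partition must cover exactly the network's nodes")


def within_module_zscore(
    net: BrainNetwork, part: CommunityPartition, ddof: int = 0
) -> pd.Series:
    """Within-module degree z-score z_i.

    z_i standardises the number of edges node i has inside its own community
    against that community's mean and standard deviation (population sd by
    default). Communities whose within-degrees do not vary give z = 0.
    """
    _check_partition(net, part)
    adj = net.adjacency
    labels = part.labels_for(net.region_ids)
    z = np.zeros(net.n_nodes)
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        kappa = adj[np.ix_(members, members)].sum(axis=1).astype(float)
        sd = kappa.std(ddof=ddof) if len(kappa) > ddof else 0.0
        if sd > 0:
            z[members] = (kappa - kappa.mean()) / sd
    return pd.Series(z, index=list(net.region_ids), name="z_within")


def participation_coefficient(
    net: BrainNetwork, part: CommunityPartition
) -> pd.Series:
    """Participation coefficient P_i = 1 − Σ_s (K_is / K_i)².

    P_i is 0 when all of a node's edges stay inside one community and
    approaches 1 − 1/N_c when they spread evenly; isolated nodes score 0.
    """
    _check_partition(net, part)
    adj = net.adjacency
    labels = part.labels_for(net.region_ids)
    k = adj.sum(axis=1).astype(float)
    p = np.zeros(net.n_nodes)
    nz = k > 0
    for c in np.unique(labels):
        k_is = adj[:, labels == c].sum(axis=1).astype(float)
        p[nz] += (k_is[nz] / k[nz]) ** 2
    p[nz] = 1.0 - p[nz]
    return pd.Series(np.where(nz, p, 0.0), index=list(net.region_ids), name="participation")


def classify_roles(
    z: pd.Series,
    p: pd.Series,
    z_hub: float = DEFAULT_Z_HUB,
    p_connector_nonhub: float = DEFAULT_P_CONNECTOR_NONHUB,
    p_connector_hub: float = DEFAULT_P_CONNECTOR_HUB,
) -> pd.Series:
    """Assign each node one of four roles in the (z, P) plane.

    Hubs (z ≥ z_hub) split into provincial (P ≤ p_connector_hub) versus
    connector hubs; non-hubs split into peripheral nodes (P ≤
    p_connector_nonhub) versus non-hub connectors.
    """
    if not z.index.equals(p.index):
        raise ValueError("z and P must be aligned on the same node set")
    roles = []
    for zi, pi in zip(z.to_numpy(), p.to_numpy()):
        if zi >= z_hub:
            roles.append(PROVINCIAL_HUB if pi <= p_connector_hub else CONNECTOR_HUB)
        else:
            roles.append(PERIPHERAL if pi <= p_connector_nonhub else NONHUB_CONNECTOR)
    return pd.Series(roles, index=z.index, name="role")


def node_metrics_table(
    net: BrainNetwork,
    part: CommunityPartition,
    z_hub: float = DEFAULT_Z_HUB,
    p_connector_nonhub: float = DEFAULT_P_CONNECTOR_NONHUB,
    p_connector_hub: float = DEFAULT_P_CONNECTOR_HUB,
) -> pd.DataFrame:
    """Per-region metric table: degree, eigenvector, community, z_i, P_i, role."""
    deg = degree_centrality(net)
    try:
        eig = eigenvector_centrality(net)
    except UndefinedMetricError:
        eig = pd.Series(np.nan, index=deg.index, name="eigenvector")
    z = within_module_zscore(net, part)
    p = participation_coefficient(net, part)
    role = classify_roles(z, p, z_hub, p_connector_nonhub, p_connector_hub)
    comm = pd.Series(
        part.labels_for(net.region_ids), index=deg.index, name="community"
    )
    return pd.DataFrame(
        {
            "degree": deg,
            "eigenvector": eig,
            "community": comm,
            "z_within": z,
            "participation": p,
            "role": role,
        }
    )


def _avg_shortest_path_adj(adj: np.ndarray) -> float:
    n = adj.shape[0]
    d = _pairwise_hops(adj)
    off = ~np.eye(n, dtype=bool)
    reachable = np.isfinite(d) & off
    if not reachable.any():
        raise UndefinedMetricError("no connected node pair; path length undefined")
    return float(d[reachable].mean())


def avg_shortest_path(net: BrainNetwork) -> float:
    """Mean shortest-path length over reachable ordered node pairs.

    Unreachable pairs are excluded from both numerator and denominator, so the
    statistic is defined on disconnected networks (as sparse thresholded
    connectomes usually are).
    """
    return _avg_shortest_path_adj(net.adjacency)


def _clustering_adj(adj: np.ndarray, low_degree: str = "exclude") -> float:
    a = adj.astype(float)
    k = a.sum(axis=1)
    tri2 = np.einsum("ij,jk,ki->i", a, a, a)  # 2 × triangles through each node
    eligible = k >= 2
    if low_degree == "exclude":
        if not eligible.any():
            raise UndefinedMetricError("all nodes have degree < 2; clustering undefined")
        c = tri2[eligible] / (k[eligible] * (k[eligible] - 1))
        return float(c.mean())
    if low_degree == "zero":
        c = np.zeros(len(k))
        c[eligible] = tri2[eligible] / (k[eligible] * (k[eligible] - 1))
        return float(c.mean()) if len(k) else 0.0
    raise ValueError(f"low_degree must be 'exclude' or 'zero', got {low_degree!r}")


def clustering_coefficient(net: BrainNetwork, low_degree: str = "exclude") -> float:
    """Mean local clustering coefficient.

    By default nodes of degree < 2 (whose local clustering is undefined) are
    excluded from the average; ``low_degree='zero'`` counts them as 0 instead.
    """
    return _clustering_adj(net.adjacency, low_degree=low_degree)


def _gnm_adjacency(n: int, m: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform simple graph with n nodes and exactly m edges."""
    iu, ju = np.triu_indices(n, k=1)
    pick = rng.choice(len(iu), size=m, replace=False)
    adj = np.zeros((n, n), dtype=bool)
    adj[iu[pick], ju[pick]] = True
    return adj | adj.T


def er_ensemble(
    n: int,
    m: int,
    n_rep: int = 1000,
    seed: int = 0,
    low_degree: str = "exclude",
) -> ERNullStats:
    """Mean path length and clustering over an Erdős–Rényi G(n, m) ensemble.

    Graphs are drawn uniformly from simple graphs with exactly ``m`` edges
    (matching the observed node and edge counts, not an edge probability).
    Replicates where a statistic is undefined — no connected pair, or no node
    of degree ≥ 2 under the exclusion convention — are skipped for that
    statistic and counted.
    """
    max_m = n * (n - 1) // 2
    if not (0 <= m <= max_m):
        raise ValueError(f"m must be in [0, {max_m}], got {m}")
    rng = np.random.default_rng(seed)
    ls, cs = [], []
    und_l = und_c = 0
    for _ in range(n_rep):
        adj = _gnm_adjacency(n, m, rng)
        try:
            ls.append(_avg_shortest_path_adj(adj))
        except UndefinedMetricError:
            und_l += 1
        try:
            cs.append(_clustering_adj(adj, low_degree=low_degree))
        except UndefinedMetricError:
            und_c += 1
    return ERNullStats(
        l_rand=float(np.mean(ls)) if ls else float("nan"),
        c_rand=float(np.mean(cs)) if cs else float("nan"),
        n_rep=n_rep,
        n_undefined_l=und_l,
        n_undefined_c=und_c,
        seed=seed,
    )


def small_worldness(l_g: float, c_g: float, l_rand: float, c_rand: float) -> float:
    """Small-world coefficient σ = (C_g/C_rand)/(L_g/L_rand).

    σ substantially above 1 means the network is much more clustered than a
    size-matched random graph while keeping comparably short paths.
    """
    vals = (l_g, c_g, l_rand, c_rand)
    if any(not np.isfinite(v) or v <= 0 for v in vals):
        raise ValueError(f"all inputs must be positive and finite, got {vals}")
    return (c_g / c_rand) / (l_g / l_rand)


def small_world_analysis(
    net: BrainNetwork, n_rand: int = 1000, seed: int = 0, low_degree: str = "exclude"
) -> SmallWorldResult:
    """Score a network against its own G(n, m) null ensemble."""
    l_g = avg_shortest_path(net)
    c_g = clustering_coefficient(net, low_degree=low_degree)
    null = er_ensemble(
        net.n_nodes, net.n_edges, n_rep=n_rand, seed=seed, low_degree=low_degree
    )
    sigma = small_worldness(l_g, c_g, null.l_rand, null.c_rand)
    return SmallWorldResult(
        l_g=l_g,
        c_g=c_g,
        l_rand=null.l_rand,
        c_rand=null.c_rand,
        sigma=sigma,
        n_rand=n_rand,
        seed=seed,
    )
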