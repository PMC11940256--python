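"""Network statistics: IVI influence scores, degree mixing, null models.

All functions operate on simple undirected :class:`networkx.Graph`
objects (use :meth:`InteractionNetwork.to_networkx` to analyse a
predicted network).

The integrated value of influence (IVI) of a node combines six
centralities into three multiplied factors:

    factor1 = degree + h-index + sum of neighbors' h-indices
    factor2 = neighborhood connectivity + ClusterRank
    factor3 = betweenness + collective influence

Each component is min-max scaled to [1, 100] before summation within its
factor, and the product is scaled to [1, 100] again, so the most
influential node of any non-degenerate network scores exactly 100.
ClusterRank is the degree-plus-one sum over neighbors damped by the local
clustering coefficient through f(c) = 10^(-c); collective influence is
(k_i - 1) times the sum of (k_j - 1) over the shell of nodes at distance
exactly ell (default 3, capped at the node's eccentricity within its
component).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

UNDEFINED = None  # sentinel for statistics with zero variance

COMPONENT_COLUMNS = [
    "degree", "h_index", "lh_sum", "neighborhood_connectivity",
    "cluster_rank", "betweenness", "collective_influence",
]


def _h_index(values: list[int]) -> int:
    """Largest h such that at least h of the values are >= h."""
    vals = sorted(values, reverse=True)
    h = 0
    for i, v in enumerate(vals, start=1):
        if v >= i:
            h = i
        else:
            break
    return h


def centrality_components(g: nx.Graph, ell: int = 3) -> pd.DataFrame:
    """Per-node table of the six IVI component centralities.

    Path-based terms (betweenness, shells, eccentricity) are computed per
    connected component; unreachable pairs contribute nothing.
    """
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = list(g.nodes)
    deg = dict(g.degree())
    h = {i: _h_index([deg[j] for j in g.neighbors(i)]) for i in nodes}
    lh_sum = {i: sum(h[j] for j in g.neighbors(i)) for i in nodes}
    nc = {
        i: (sum(deg[j] for j in g.neighbors(i)) / deg[i]) if deg[i] else 0.0
        for i in nodes
    }
    clustering = nx.clustering(g)
    cr = {
        i: 10.0 ** (-clustering[i]) * sum(deg[j] + 1 for j in g.neighbors(i))
        for i in nodes
    }
    bc = nx.betweenness_centrality(g, normalized=False)

    ci = {}
    for i in nodes:
        if deg[i] == 0:
            ci[i] = 0.0
            continue
        lengths = nx.single_source_shortest_path_length(g, i)
        ecc = max(lengths.values())
        radius = min(ell, ecc)
        shell = [j for j, d in lengths.items() if d == radius and j != i]
        ci[i] = (deg[i] - 1) * sum(deg[j] - 1 for j in shell)

    return pd.DataFrame(
        {
            "degree": [deg[i] for i in nodes],
            "h_index": [h[i] for i in nodes],
            "lh_sum": [lh_sum[i] for i in nodes],
            "neighborhood_connectivity": [nc[i] for i in nodes],
            "cluster_rank": [cr[i] for i in nodes],
            "local_clustering": [clustering[i] for i in nodes],
            "betweenness": [bc[i] for i in nodes],
            "collective_influence": [ci[i] for i in nodes],
        },
        index=pd.Index(nodes, name="node"),
    )


def _minmax_1_100(x: np.ndarray) -> np.ndarray:
    """Scale to [1, 100]; a constant column maps to all-1 (degenerate rule).

    Ranges within floating-point noise of zero (relative 1e-9) count as
    constant, so accumulation jitter in path counts cannot masquerade as
    structure.
    """
    x = np.asarray(x, dtype=float)
    lo, hi = x.min(), x.max()
    if hi - lo <= 1e-9 * max(1.0, abs(hi), abs(lo)):
        return np.ones_like(x)
    return 1.0 + 99.0 * (x - lo) / (hi - lo)


def ivi(report: pd.DataFrame) -> pd.Series:
    """Integrated value of influence per node, scaled to [1, 100]."""
    scaled = {c: _minmax_1_100(report[c].to_numpy()) for c in COMPONENT_COLUMNS}
    factor1 = scaled["degree"] + scaled["h_index"] + scaled["lh_sum"]
    factor2 = scaled["neighborhood_connectivity"] + scaled["cluster_rank"]
    factor3 = scaled["betweenness"] + scaled["collective_influence"]
    raw = factor1 * factor2 * factor3
    return pd.Series(_minmax_1_100(raw), index=report.index, name="ivi")


def centrality_report(g: nx.Graph, ell: int = 3) -> pd.DataFrame:
    """Component centralities plus the final IVI column."""
    report = centrality_components(g, ell=ell)
    report["ivi"] = ivi(report)
    return report


def assortativity_r(g: nx.Graph) -> float | None:
    """Degree assortativity: Pearson correlation of remaining degrees
    across edges. Regular graphs (zero remaining-degree variance) return
    the undefined sentinel ``None``.
    """
    if g.number_of_edges() == 0:
        raise ValueError("assortativity requires at least one edge")
    deg = dict(g.degree())
    xs, ys = [], []
    for u, v in g.edges():
        xs.extend((deg[u] - 1, deg[v] - 1))
        ys.extend((deg[v] - 1, deg[u] - 1))
    x = np.asarray(xs, dtype=float)
    y = np.asarray(ys, dtype=float)
    if np.var(x) < 1e-300:
        return UNDEFINED
    return float(np.mean(x * y) - np.mean(x) * np.mean(y)) / float(np.var(x))


def remaining_degree_distributions(g: nx.Graph) -> tuple[dict, dict]:
    """(q_k, e_jk): remaining-degree distribution and the joint
    distribution of remaining degrees at the two ends of a random edge."""
    deg = dict(g.degree())
    m2 = 2 * g.number_of_edges()
    q: dict[int, float] = {}
    e: dict[tuple[int, int], float] = {}
    for u, v in g.edges():
        ju, jv = deg[u] - 1, deg[v] - 1
        q[ju] = q.get(ju, 0.0) + 1.0 / m2
        q[jv] = q.get(jv, 0.0) + 1.0 / m2
        e[(ju, jv)] = e.get((ju, jv), 0.0) + 1.0 / m2
        e[(jv, ju)] = e.get((jv, ju), 0.0) + 1.0 / m2
    return q, e


def degree_distribution(g: nx.Graph) -> dict[int, float]:
    """P(k) = n_k / n."""
    n = g.number_of_nodes()
    out: dict[int, float] = {}
    for _, k in g.degree():
        out[k] = out.get(k, 0.0) + 1.0 / n
    return out


def knn_by_degree(g: nx.Graph) -> dict[int, float]:
    """Average nearest-neighbor degree of nodes with degree k (unit weights)."""
    deg = dict(g.degree())
    per_node = {}
    isolated = 0
    for i in g.nodes:
        if deg[i] == 0:
            isolated += 1
            continue
        per_node[i] = sum(deg[j] for j in g.neighbors(i)) / deg[i]
    if isolated:
        warnings.warn(f"excluded {isolated} isolated nodes from knn(k)")
    out: dict[int, list[float]] = {}
    for i, v in per_node.items():
        out.setdefault(deg[i], []).append(v)
    return {k: float(np.mean(vs)) for k, vs in out.items()}


def _is_bipartite_by_side(g: nx.Graph) -> dict | None:
    sides = nx.get_node_attributes(g, "side")
    if len(sides) == g.number_of_nodes() and len(set(sides.values())) == 2:
        return sides
    return None


def randomize_preserving_degrees(
    g: nx.Graph, seed: int, n_attempts: int | None = None
) -> nx.Graph:
    """Degree-preserving double-edge-swap rewiring.

    Attempts ``10 * |E|`` swaps by default, rejecting any swap that would
    create a self-loop or parallel edge. Graphs whose nodes carry a
    two-valued ``side`` attribute are treated as bipartite and rewired
    within the bipartition (each edge keeps one endpoint per side).
    """
    if g.number_of_edges() < 2:
        warnings.warn("no valid degree-preserving swap; returning the input")
        return g.copy()
    rng = np.random.default_rng(seed)
    if n_attempts is None:
        n_attempts = 10 * g.number_of_edges()
    sides = _is_bipartite_by_side(g)

    if sides is not None:
        left_tag = sorted(set(sides.values()))[0]
        edges = [
            (u, v) if sides[u] == left_tag else (v, u) for u, v in g.edges()
        ]
    else:
        edges = list(g.edges())
    edge_set = {frozenset(e) for e in edges}

    for _ in range(n_attempts):
        i, j = rng.integers(0, len(edges), size=2)
        if i == j:
            continue
        (a, b), (c, d) = edges[i], edges[j]
        if sides is not None:
            new1, new2 = (a, d), (c, b)
        else:
            if rng.integers(0, 2):
                c, d = d, c
            new1, new2 = (a, d), (c, b)
        if new1[0] == new1[1] or new2[0] == new2[1]:
            continue
        f1, f2 = frozenset(new1), frozenset(new2)
        if f1 in edge_set or f2 in edge_set or f1 == f2:
            continue
        edge_set.discard(frozenset(edges[i]))
        edge_set.discard(frozenset(edges[j]))
        edge_set.update((f1, f2))
        edges[i], edges[j] = new1, new2

    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    out.add_edges_from(edges)
    return out


def _degree_bin(k: int, binning: str) -> int:
    if binning == "log2":
        return int(math.floor(math.log2(k))) if k > 0 else -1
    if binning == "linear":
        return k
    raise ValueError(f"unknown binning {binning!r}")


def _edge_bin_fractions(g: nx.Graph, binning: str) -> dict[tuple[int, int], float]:
    deg = dict(g.degree())
    m2 = 2 * g.number_of_edges()
    out: dict[tuple[int, int], float] = {}
    for u, v in g.edges():
        b1, b2 = _degree_bin(deg[u], binning), _degree_bin(deg[v], binning)
        out[(b1, b2)] = out.get((b1, b2), 0.0) + 1.0 / m2
        out[(b2, b1)] = out.get((b2, b1), 0.0) + 1.0 / m2
    return out


@dataclass
class CorrelationProfile:
    """Z-scores of the linked-degree-bin distribution against a
    degree-preserving randomized ensemble; bins with zero ensemble
    variance are reported as missing."""

    z: dict[tuple[int, int], float]
    observed: dict[tuple[int, int], float]
    ensemble_mean: dict[tuple[int, int], float]
    ensemble_std: dict[tuple[int, int], float]
    binning: str = "log2"
    missing: list[tuple[int, int]] = field(default_factory=list)

    def mean_abs_z(self) -> float:
        return float(np.mean([abs(v) for v in self.z.values()])) if self.z else 0.0


def correlation_profile(
    g: nx.Graph,
    n_rand: int = 1000,
    seed: int = 0,
    binning: str = "log2",
) -> CorrelationProfile:
    """Compare the observed joint degree-bin distribution of linked nodes
    with its mean and standard deviation over ``n_rand`` degree-preserving
    randomized networks: Z = (P - E[P_r]) / sigma."""
    if n_rand < 2:
        raise ValueError("n_rand must be >= 2")
    observed = _edge_bin_fractions(g, binning)
    seeds = np.random.SeedSequence(seed).spawn(n_rand)
    samples: list[dict[tuple[int, int], float]] = []
    for s in seeds:
        gr = randomize_preserving_degrees(g, seed=int(s.generate_state(1)[0] % (2**31)))
        samples.append(_edge_bin_fractions(gr, binning))

    keys = set(observed)
    for sample in samples:
        keys |= set(sample)
    z, mean_d, std_d, missing = {}, {}, {}, []
    for key in sorted(keys):
        vals = np.array([sample.get(key, 0.0) for sample in samples])
        mu, sigma = float(vals.mean()), float(vals.std(ddof=0))
        mean_d[key], std_d[key] = mu, sigma
        if sigma < 1e-15:
            missing.append(key)
            continue
        z[key] = (observed.get(key, 0.0) - mu) / sigma
    return CorrelationProfile(
        z=z, observed=observed, ensemble_mean=mean_d, ensemble_std=std_d,
        binning=binning, missing=missing,
    )


def pearson(x, y) -> float | None:
    """Product-moment correlation; ``None`` when either variance is zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson requires equal-length inputs of length >= 3")
    if np.var(x) < 1e-300 or np.var(y) < 1e-300:
        return UNDEFINED
    return float(stats.pearsonr(x, y)[0])


def mean_degree_by_strain(
    network, catalog, abundances: dict[str, float]
) -> tuple[pd.DataFrame, float | None]:
    """Mean network degree of each strain's proteins, paired with its
    abundance, plus the Pearson correlation of the two columns."""
    degrees: dict[str, list[int]] = {}
    for node_id in network.side_nodes("bacterial"):
        strain = network.nodes[node_id].organism
        if strain not in abundances:
            raise ValueError(f"strain {strain!r} missing from the abundance table")
        degrees.setdefault(strain, []).append(network.degree(node_id))
    absent = sorted(set(abundances) - set(degrees))
    if absent:
        warnings.warn(f"strains without network proteins omitted: {absent}")
    rows = [
        {"strain": s, "mean_degree": float(np.mean(ks)), "abundance": abundances[s]}
        for s, ks in sorted(degrees.items())
    ]
    table = pd.DataFrame(rows)
    r = (
        pearson(table["mean_degree"], table["abundance"])
        if len(table) >= 3 else UNDEFINED
    )
    return table, r


def disorder_summary(
    table: dict[str, float], sides: dict[str, str]
) -> pd.DataFrame:
    """Fraction of proteins per side whose disorder fraction reaches each
    threshold on the grid {0+, 0.05, ..., 1.0} ("0+" means any disorder)."""
    for pid, v in table.items():
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"disorder fraction outside [0, 1] for {pid}")
    thresholds = [0.0] + [round(0.05 * i, 2) for i in range(1, 21)]
    rows = []
    for side in sorted(set(sides.values())):
        values = np.array([v for pid, v in table.items() if sides.get(pid) == side])
        for t in thresholds:
            if len(values) == 0:
                frac = 0.0
            elif t == 0.0:
                frac = float(np.mean(values > 0))
            else:
                frac = float(np.mean(values >= t))
            rows.append({"side": side, "threshold": t, "fraction": frac})
    return pd.DataFrame(rows)
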