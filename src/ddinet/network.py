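"""Bipartite host x bacteria network assembly and clustering.

All host x bacterial protein pairs are scored with the trained
classifier; only pairs whose interaction probability clears a high
cutoff (default 0.99, "approaching 1") enter the network. The network is
then optionally collapsed twice: through a precomputed sequence-identity
cluster map (UniRef90-style, an *input*, not a computation), and through
"fuzzy" clusters that merge same-side clusters with >= 70% similar gene
names sharing at least one Pfam ID.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Iterable, Iterator

import edlib
import networkx as nx
import numpy as np

from ddinet.classifier import TrainedClassifier
from ddinet.core import Protein, ProteinCatalog
from ddinet.embedding import DDIWeightTable, EmbeddingModel, pair_vector

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NodeInfo:
    side: str  # "host" | "bacterial"
    organism: str = ""
    gene_name: str = ""
    pfam_ids: tuple[str, ...] = ()
    members: tuple[str, ...] = ()  # protein ids behind a cluster node

    def __post_init__(self) -> None:
        if self.side not in ("host", "bacterial"):
            raise ValueError(f"invalid side {self.side!r}")


class InteractionNetwork:
    """Strictly bipartite scored network; edges keyed (bacterial, host)."""

    def __init__(self) -> None:
        self.nodes: dict[str, NodeInfo] = {}
        self.edges: dict[tuple[str, str], float] = {}

    def add_node(self, node_id: str, info: NodeInfo) -> None:
        existing = self.nodes.get(node_id)
        if existing is not None and existing.side != info.side:
            raise ValueError(f"node {node_id} re-added with a different side")
        self.nodes[node_id] = info

    def add_edge(self, bacterial: str, host: str, score: float) -> None:
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"score outside [0, 1]: {score}")
        if self.nodes[bacterial].side != "bacterial" or self.nodes[host].side != "host":
            raise ValueError(f"edge ({bacterial}, {host}) is not host-bacterial")
        key = (bacterial, host)
        if key in self.edges:
            raise ValueError(f"duplicate edge {key}")
        self.edges[key] = score

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def side_nodes(self, side: str) -> list[str]:
        return sorted(n for n, info in self.nodes.items() if info.side == side)

    def degree(self, node_id: str) -> int:
        return sum(1 for key in self.edges if node_id in key)

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node_id, info in self.nodes.items():
            g.add_node(node_id, side=info.side, organism=info.organism,
                       gene_name=info.gene_name)
        for (bact, host), score in self.edges.items():
            g.add_edge(bact, host, weight=score)
        return g


def _node_info_for(protein: Protein) -> NodeInfo:
    return NodeInfo(
        side="host" if protein.is_human else "bacterial",
        organism=protein.organism,
        gene_name=protein.gene_name,
        pfam_ids=protein.pfam_ids,
        members=(protein.id,),
    )


def score_all_pairs(
    host_pool: list[Protein],
    bacterial_pool: list[Protein],
    classifier: TrainedClassifier,
    embeddings: EmbeddingModel,
    weights: DDIWeightTable,
    batch_size: int = 2048,
) -> Iterator[tuple[str, str, float]]:
    """Stream interaction probabilities for every host x bacterial pair.

    Enumeration order is deterministic (sorted pools, host-major); memory
    is bounded by ``batch_size``. Proteins without any in-vocabulary
    domain are skipped once, with a log line.
    """
    def usable(pool: list[Protein]) -> list[Protein]:
        kept = []
        for p in sorted(pool, key=lambda p: p.id):
            if any(d in embeddings for d in p.pfam_ids):
                kept.append(p)
            else:
                logger.warning("skipping unembeddable protein %s", p.id)
        return kept

    hosts, bacts = usable(host_pool), usable(bacterial_pool)
    batch: list[tuple[str, str, np.ndarray]] = []

    def flush() -> Iterator[tuple[str, str, float]]:
        if not batch:
            return
        X = np.vstack([v for _, _, v in batch])
        probs = classifier.predict_proba(X)
        for (bact, host, _), p in zip(batch, probs):
            yield bact, host, float(p)
        batch.clear()

    n_emitted = 0
    for h in hosts:
        for b in bacts:
            batch.append((b.id, h.id, pair_vector(b, h, embeddings, weights)))
            if len(batch) >= batch_size:
                yield from flush()
                n_emitted += batch_size
                logger.info("scored %d pairs", n_emitted)
    yield from flush()


def build_network(
    scored: Iterable[tuple[str, str, float]],
    catalog: ProteinCatalog,
    cutoff: float = 0.99,
) -> InteractionNetwork:
    """Keep pairs with probability >= cutoff; isolated proteins are not added."""
    if not 0.0 < cutoff < 1.0 + 1e-12:
        raise ValueError("cutoff must be in (0, 1]")
    net = InteractionNetwork()
    for bact, host, score in scored:
        if score >= cutoff:
            net.add_node(bact, _node_info_for(catalog[bact]))
            net.add_node(host, _node_info_for(catalog[host]))
            net.add_edge(bact, host, score)
    return net


@dataclass
class ClusterMap:
    """protein/cluster id -> fuzzy or identity cluster id, with payloads."""

    mapping: dict[str, str]
    payloads: dict[str, NodeInfo] = field(default_factory=dict)

    def __getitem__(self, node_id: str) -> str:
        return self.mapping[node_id]

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.mapping

    @classmethod
    def from_plain(cls, mapping: dict[str, str]) -> "ClusterMap":
        return cls(mapping=dict(mapping))


def _representative_gene_name(names: list[str]) -> str:
    """Most frequent nonempty name; ties resolve lexicographically."""
    nonempty = [n for n in names if n]
    if not nonempty:
        return ""
    counts: dict[str, int] = {}
    for n in nonempty:
        counts[n] = counts.get(n, 0) + 1
    return min(counts, key=lambda n: (-counts[n], n))


def collapse_by_cluster_map(
    network: InteractionNetwork, cmap: ClusterMap
) -> InteractionNetwork:
    """Merge network nodes into their clusters; parallel edges keep the max score."""
    missing = sorted(n for n in network.nodes if n not in cmap)
    if missing:
        raise ValueError(f"cluster map missing {len(missing)} network nodes: "
                         f"{missing[:5]}")
    # build cluster payloads
    members: dict[str, list[str]] = {}
    for node_id in network.nodes:
        members.setdefault(cmap[node_id], []).append(node_id)

    out = InteractionNetwork()
    cluster_info: dict[str, NodeInfo] = {}
    for cid, node_ids in members.items():
        infos = [network.nodes[n] for n in node_ids]
        sides = {i.side for i in infos}
        if len(sides) > 1:
            raise ValueError(f"cluster {cid} mixes host and bacterial proteins")
        all_members = tuple(sorted({m for i in infos for m in i.members}))
        pfams = tuple(sorted({d for i in infos for d in i.pfam_ids}))
        organisms = sorted({i.organism for i in infos})
        cluster_info[cid] = NodeInfo(
            side=sides.pop(),
            organism=organisms[0] if len(organisms) == 1 else ";".join(organisms),
            gene_name=_representative_gene_name([i.gene_name for i in infos]),
            pfam_ids=pfams,
            members=all_members,
        )

    merged: dict[tuple[str, str], float] = {}
    for (bact, host), score in network.edges.items():
        key = (cmap[bact], cmap[host])
        merged[key] = max(merged.get(key, 0.0), score)
    for (bact_c, host_c), score in merged.items():
        out.add_node(bact_c, cluster_info[bact_c])
        out.add_node(host_c, cluster_info[host_c])
        out.add_edge(bact_c, host_c, score)
    return out


def gene_name_similarity(a: str, b: str) -> float:
    """Normalized Levenshtein similarity on case-folded names, in [0, 1]."""
    a, b = a.casefold(), b.casefold()
    if not a or not b:
        return 0.0
    if a == b:
        return 1.0
    dist = edlib.align(a, b)["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def fuzzy_cluster(
    network: InteractionNetwork, similarity_cutoff: float = 0.70
) -> ClusterMap:
    """Single-linkage merger of same-side clusters by gene-name similarity.

    Two same-side nodes join when their gene names are at least
    ``similarity_cutoff`` similar AND they share at least one Pfam ID;
    components are labeled by their lexicographically smallest member.
    Nodes with empty gene names only join other empty-name nodes with an
    identical Pfam set (logged), never named ones.
    """
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for side in ("host", "bacterial"):
        nodes = network.side_nodes(side)
        infos = {n: network.nodes[n] for n in nodes}
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                iu, iv = infos[u], infos[v]
                if not set(iu.pfam_ids) & set(iv.pfam_ids):
                    continue
                if iu.gene_name and iv.gene_name:
                    if gene_name_similarity(iu.gene_name, iv.gene_name) >= similarity_cutoff:
                        g.add_edge(u, v)
                elif not iu.gene_name and not iv.gene_name:
                    if set(iu.pfam_ids) == set(iv.pfam_ids):
                        logger.info("merging unnamed clusters %s, %s on exact "
                                    "Pfam match", u, v)
                        g.add_edge(u, v)

    mapping: dict[str, str] = {}
    for component in nx.connected_components(g):
        label = min(component)
        for node in component:
            mapping[node] = label
    return ClusterMap(mapping=mapping)


def compose_maps(first: ClusterMap, second: ClusterMap) -> ClusterMap:
    """The map sending x -> second[first[x]]."""
    return ClusterMap(mapping={k: second[v] for k, v in first.mapping.items()})


def network_from_edges(
    edges: Iterable[tuple[str, str, float | None]],
    catalog: ProteinCatalog | None = None,
) -> InteractionNetwork:
    """Rebuild a network from (bacterial, host[, score]) rows.

    Node payloads are pulled from the catalog when available; otherwise
    only the side tag (inferred from the column) is carried.
    """
    net = InteractionNetwork()
    for bact, host, score in edges:
        for node_id, side in ((bact, "bacterial"), (host, "host")):
            if catalog is not None and node_id in catalog:
                net.add_node(node_id, _node_info_for(catalog[node_id]))
            elif node_id not in net.nodes:
                net.add_node(node_id, NodeInfo(side=side))
        net.add_edge(bact, host, 1.0 if score is None else score)
    return net
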