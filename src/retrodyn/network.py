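"""TF-seeded PPI network growth, scoring and selection.

Starting from a seed of transcription factors, subnetworks grow layer by
layer by greedily adding the outside node with the strongest summed edge
confidence to the current network.  Each layer is profiled for enriched GO
terms and scored against the DET-derived term set: sensitivity is the
percentage of DET terms the network recovers, specificity the percentage of
the network's terms shared with the DET set.  The balanced network — the
layer passing the sensitivity and growth floors with maximal specificity —
is selected and partitioned into core / secondary / peripheral tiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from sklearn.cluster import KMeans

from .go import filter_terms, hypergeom_enrich

DEFAULT_SCHEDULE = (5, 5, 10, 10, 10)


class InteractionGraph:
    """Undirected PPI graph with per-edge confidence in (0, 1]."""

    def __init__(self, graph: nx.Graph):
        self.g = graph

    @classmethod
    def from_edges(cls, edges: Iterable[tuple[str, str, float]]) -> "InteractionGraph":
        g = nx.Graph()
        for u, v, conf in edges:
            if u == v:
                raise ValueError(f"self-loop on {u!r}")
            if not (0.0 < conf <= 1.0):
                raise ValueError(f"confidence {conf} outside (0, 1] on edge {u}-{v}")
            if g.has_edge(u, v):
                raise ValueError(f"duplicate edge {u}-{v}")
            g.add_edge(u, v, confidence=float(conf))
        return cls(g)

    def edge_list(self) -> list[tuple[str, str, float]]:
        return sorted((u, v, d["confidence"]) if u <= v else (v, u, d["confidence"])
                      for u, v, d in self.g.edges(data=True))

    @property
    def nodes(self) -> set[str]:
        return set(self.g.nodes)

    def __contains__(self, node) -> bool:
        return node in self.g


@dataclass
class LayerRecord:
    layer: int
    nodes: frozenset
    nodes_added: int
    growth_pct: float
    enriched_terms: set[str] = field(default_factory=set)
    sensitivity_pct: float = float("nan")
    specificity_pct: float = float("nan")


@dataclass
class GrowthTrajectory:
    tf_group: int
    layers: list[LayerRecord]
    saturated: bool = False


def expand_network(
    graph: InteractionGraph,
    seed_nodes: Iterable[str],
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
) -> tuple[list[frozenset], bool]:
    """Greedy layer-by-layer expansion.

    Layer 0 is the seed ("initial network").  At every step of a layer the
    external node with maximal summed edge confidence into the current
    network joins; ties break toward higher total degree, then the
    lexicographically smaller id.  Returns the per-layer node sets and a
    saturation flag (no external neighbour left before the schedule ended).
    """
    seed = set(seed_nodes)
    if not seed:
        raise ValueError("seed set is empty")
    missing = seed - graph.nodes
    if missing:
        raise ValueError(f"seed nodes not in graph: {sorted(missing)[:5]}")
    g = graph.g
    current = set(seed)
    layers = [frozenset(current)]
    saturated = False

    # summed confidence from each external node into the current network
    score: dict[str, float] = {}
    for node in current:
        for nb, d in g[node].items():
            if nb not in current:
                score[nb] = score.get(nb, 0.0) + d["confidence"]

    for step in schedule:
        for _ in range(step):
            if not score:
                saturated = True
                break
            best = min(
                score, key=lambda n: (-score[n], -g.degree(n), n)
            )
            current.add(best)
            del score[best]
            for nb, d in g[best].items():
                if nb not in current:
                    score[nb] = score.get(nb, 0.0) + d["confidence"]
        layers.append(frozenset(current))
        if saturated:
            # remaining layers repeat the saturated set
            continue
    return layers, saturated


def growth_percent(layers: Sequence[frozenset]) -> list[float]:
    """Node-count increase of each layer relative to the seed network."""
    n0 = len(layers[0])
    if n0 == 0:
        raise ValueError("layer 0 is empty")
    return [100.0 * (len(layer) - n0) / n0 for layer in layers]


def network_go_profile(
    node_set: Iterable[str],
    term_map: dict[str, set[str]],
    universe: Iterable[str],
    fdr_max: float = 1e-4,
) -> set[str]:
    """Enriched GO terms of a network's nodes (non-annotatable nodes dropped)."""
    universe = set(universe)
    mapped = set(node_set) & universe
    if not mapped:
        return set()
    records = hypergeom_enrich(mapped, term_map, universe)
    kept = filter_terms(records, fdr_max=fdr_max)
    return set(kept["term"])


def sensitivity_specificity(net_terms: set[str], det_terms: set[str]) -> tuple[float, float]:
    """Shared-term percentages: of the DET terms (sensitivity) and of the
    network terms (specificity; 0 when the network predicts none)."""
    if not det_terms:
        raise ValueError("det_terms is empty")
    shared = len(set(net_terms) & set(det_terms))
    sens = 100.0 * shared / len(det_terms)
    spec = 100.0 * shared / len(net_terms) if net_terms else 0.0
    return sens, spec


def build_trajectory(
    tf_group: int,
    graph: InteractionGraph,
    seed_nodes: Iterable[str],
    term_map: dict[str, set[str]],
    universe: Iterable[str],
    det_terms: set[str],
    schedule: Sequence[int] = DEFAULT_SCHEDULE,
    fdr_max: float = 1e-4,
) -> GrowthTrajectory:
    """Expand, profile and score one TF group's nested networks."""
    layers, saturated = expand_network(graph, seed_nodes, schedule)
    growth = growth_percent(layers)
    records = []
    prev = len(layers[0])
    for i, nodes in enumerate(layers):
        terms = network_go_profile(nodes, term_map, universe, fdr_max=fdr_max)
        sens, spec = sensitivity_specificity(terms, det_terms)
        records.append(
            LayerRecord(i, nodes, len(nodes) - prev if i else 0, growth[i], terms, sens, spec)
        )
        prev = len(nodes)
    return GrowthTrajectory(tf_group=tf_group, layers=records, saturated=saturated)


@dataclass
class NetworkSelection:
    tf_group: int
    layer: int
    nodes: frozenset
    sensitivity_pct: float
    specificity_pct: float
    growth_pct: float
    relaxed: bool


def select_network(
    trajectories: Sequence[GrowthTrajectory],
    sens_min: float = 40.0,
    growth_min: float = 150.0,
) -> NetworkSelection:
    """Pick the balanced network.

    Candidates are layers with sensitivity >= ``sens_min`` and growth >=
    ``growth_min``; the winner maximises specificity, ties breaking toward
    fewer nodes, then the lower TF-group index.  With no candidate the layer
    of maximal sensitivity is returned flagged ``relaxed``.
    """
    if not trajectories:
        raise ValueError("no trajectories")
    candidates = [
        (tr, rec)
        for tr in trajectories
        for rec in tr.layers
        if rec.sensitivity_pct >= sens_min and rec.growth_pct >= growth_min
    ]
    relaxed = not candidates
    if relaxed:
        candidates = [(tr, rec) for tr in trajectories for rec in tr.layers]
        tr, rec = max(candidates, key=lambda c: (c[1].sensitivity_pct, -len(c[1].nodes), -c[0].tf_group))
    else:
        tr, rec = max(
            candidates,
            key=lambda c: (c[1].specificity_pct, -len(c[1].nodes), -c[0].tf_group),
        )
    return NetworkSelection(
        tf_group=tr.tf_group,
        layer=rec.layer,
        nodes=rec.nodes,
        sensitivity_pct=rec.sensitivity_pct,
        specificity_pct=rec.specificity_pct,
        growth_pct=rec.growth_pct,
        relaxed=relaxed,
    )


TIER_NAMES = ("core", "secondary", "peripheral")


def partition_network_kmeans(
    node_set: Iterable[str],
    graph: InteractionGraph,
    k: int = 3,
    seed: int = 0,
    n_init: int = 50,
) -> dict[str, str]:
    """K-means split of a subnetwork into core / secondary / peripheral.

    Features per node: within-network degree, summed edge confidence and
    closeness centrality of the induced subgraph (standardized).  Clusters
    are ranked by mean degree: the densest is the core.
    """
    nodes = sorted(node_set)
    if len(nodes) < k:
        raise ValueError(f"need at least k={k} nodes, got {len(nodes)}")
    sub = graph.g.subgraph(nodes)
    degree = np.array([sub.degree(n) for n in nodes], dtype=float)
    strength = np.array(
        [sum(d["confidence"] for _, _, d in sub.edges(n, data=True)) for n in nodes]
    )
    closeness = nx.closeness_centrality(sub)
    close = np.array([closeness[n] for n in nodes])
    X = np.column_stack([degree, strength, close])
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    X = (X - X.mean(axis=0)) / sd

    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points can leave a cluster empty
        km = KMeans(n_clusters=k, n_init=n_init, random_state=seed)
        labels = km.fit_predict(X)
    occupied = [c for c in range(k) if (labels == c).any()]
    occupied.sort(key=lambda c: -degree[labels == c].mean())
    tier_of_cluster = {c: TIER_NAMES[min(rank, len(TIER_NAMES) - 1)] for rank, c in enumerate(occupied)}
    return {n: tier_of_cluster[int(c)] for n, c in zip(nodes, labels)}
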