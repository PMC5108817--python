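"""Multi-layer gene-network data model.

A single omic relation (functional similarity, chromatin conformation,
protein interaction) is a :class:`Layer`: an undirected weighted gene graph
whose weights are probabilities of the relation existing, hence constrained
to [0, 1].  Several layers over a shared gene universe form a
:class:`MultilayerNetwork`, the quadruplet (V_M, E_M, V, L): the gene
universe V, the layer list L, the node-layer presence set V_M, and the edge
set E_M split into intra-layer edges (each layer's own graph) and
inter-layer couplings between replicas of the same gene.

Couplings are *categorical* (every replica pair of a shared gene is coupled
with one uniform weight) and are excluded from degree/strength/aggregate
computations unless explicitly requested, because the per-layer descriptors
are reported as stacked per-layer quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

logger = logging.getLogger(__name__)


class StructuralError(ValueError):
    """A graph or multilayer structure violates a model invariant."""


class Layer:
    """A named, undirected, weighted gene graph.

    Parameters
    ----------
    name
        Layer label (unique within a multilayer network).
    probabilistic
        If True (the default), every edge weight must lie in [0, 1]
        (weights are relation probabilities).  The aggregate layer
        produced by :func:`aggregate_layer` relaxes this, since its
        weights are sums across layers.
    """

    def __init__(self, name: str, probabilistic: bool = True):
        self.name = str(name)
        self.probabilistic = bool(probabilistic)
        self.graph = nx.Graph()

    # -- construction -------------------------------------------------

    @classmethod
    def from_edges(cls, name, edges, nodes=(), probabilistic=True):
        """Build a layer from ``(gene_a, gene_b, weight)`` triples.

        Extra isolated ``nodes`` may be supplied; duplicate unordered
        pairs and self-loops are rejected (ingest handles dirty input).
        """
        layer = cls(name, probabilistic=probabilistic)
        for g in nodes:
            layer.add_node(g)
        for u, v, w in edges:
            if layer.graph.has_edge(u, v):
                raise StructuralError(
                    f"layer {name!r}: duplicate edge ({u}, {v})"
                )
            layer.add_edge(u, v, w)
        return layer

    def add_node(self, gene: str) -> None:
        self.graph.add_node(str(gene))

    def add_edge(self, u: str, v: str, weight: float) -> None:
        u, v = str(u), str(v)
        if u == v:
            raise StructuralError(f"layer {self.name!r}: self-loop on {u!r}")
        w = float(weight)
        if self.probabilistic and not (0.0 <= w <= 1.0):
            raise StructuralError(
                f"layer {self.name!r}: weight {w} for ({u}, {v}) "
                "outside [0, 1]"
            )
        if w < 0:
            raise StructuralError(
                f"layer {self.name!r}: negative weight {w} for ({u}, {v})"
            )
        self.graph.add_edge(u, v, weight=w)

    # -- views ---------------------------------------------------------

    @property
    def nodes(self) -> frozenset:
        return frozenset(self.graph.nodes)

    @property
    def edges(self):
        """Unordered gene pairs, each as a sorted tuple."""
        return {tuple(sorted(e)) for e in self.graph.edges}

    def weight(self, u: str, v: str) -> float:
        return self.graph.edges[u, v]["weight"]

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def sorted_nodes(self) -> list:
        return sorted(self.graph.nodes)

    def adjacency(self, ordering=None) -> np.ndarray:
        """Dense symmetric weighted adjacency over ``ordering``.

        Genes in ``ordering`` absent from the layer get all-zero
        rows/columns.  Default ordering is the layer's sorted node list.
        """
        if ordering is None:
            ordering = self.sorted_nodes()
        idx = {g: i for i, g in enumerate(ordering)}
        A = np.zeros((len(ordering), len(ordering)))
        for u, v, data in self.graph.edges(data=True):
            if u in idx and v in idx:
                A[idx[u], idx[v]] = A[idx[v], idx[u]] = data["weight"]
        return A

    def copy(self) -> "Layer":
        out = Layer(self.name, probabilistic=self.probabilistic)
        out.graph = self.graph.copy()
        return out

    def __repr__(self):
        return (
            f"Layer({self.name!r}, {self.n_nodes} genes, "
            f"{self.n_edges} edges)"
        )


@dataclass
class MultilayerNetwork:
    """The quadruplet M = (V_M, E_M, V, L).

    ``layers`` keeps declaration order; ``interlayer_edges`` holds
    categorical couplings as ``((gene, layer_a), (gene, layer_b), weight)``
    with layer_a before layer_b in declaration order.  ``tracks`` holds
    per-gene scalar omic tracks attached by the ingest module, keyed by
    track name.
    """

    layers: list
    coupling_weight: float = 1.0
    interlayer_edges: list = field(default_factory=list)
    tracks: dict = field(default_factory=dict)

    @property
    def layer_names(self) -> list:
        return [ly.name for ly in self.layers]

    @property
    def gene_universe(self) -> frozenset:
        out = set()
        for ly in self.layers:
            out |= ly.nodes
        return frozenset(out)

    @property
    def node_layer_pairs(self) -> frozenset:
        return frozenset(
            (g, ly.name) for ly in self.layers for g in ly.nodes
        )

    def layer(self, name: str) -> Layer:
        for ly in self.layers:
            if ly.name == name:
                return ly
        raise KeyError(f"no layer named {name!r}")

    def validate(self) -> None:
        """Check the quadruplet invariants; raise StructuralError."""
        names = self.layer_names
        if len(set(names)) != len(names):
            raise StructuralError("duplicate layer names")
        pairs = self.node_layer_pairs
        for (a, b, w) in self.interlayer_edges:
            for nl in (a, b):
                if nl not in pairs:
                    raise StructuralError(
                        f"coupling references absent node-layer {nl}"
                    )
            if a[0] != b[0]:
                raise StructuralError(
                    f"coupling joins different genes {a[0]!r}, {b[0]!r}"
                )
            if w < 0:
                raise StructuralError("negative coupling weight")


def build_multilayer(layers, coupling_weight: float = 1.0) -> MultilayerNetwork:
    """Assemble a multilayer network with node-aligned categorical couplings.

    Every gene present in two or more layers gets pairwise couplings of
    weight ``coupling_weight`` between all of its node-layer replicas.

    Raises
    ------
    StructuralError
        If the layer list is empty, layer names collide, or the
        coupling weight is negative.
    """
    layers = list(layers)
    if not layers:
        raise StructuralError("a multilayer network needs at least one layer")
    names = [ly.name for ly in layers]
    if len(set(names)) != len(names):
        raise StructuralError(f"duplicate layer names: {names}")
    if coupling_weight < 0:
        raise StructuralError("coupling_weight must be >= 0")

    couplings = []
    membership = {}
    for ly in layers:
        for g in ly.nodes:
            membership.setdefault(g, []).append(ly.name)
    for g in sorted(membership):
        present = membership[g]
        for i in range(len(present)):
            for j in range(i + 1, len(present)):
                couplings.append(
                    ((g, present[i]), (g, present[j]), float(coupling_weight))
                )

    M = MultilayerNetwork(
        layers=layers,
        coupling_weight=float(coupling_weight),
        interlayer_edges=couplings,
    )
    M.validate()
    return M


def aggregate_layer(M: MultilayerNetwork, normalize: bool = False) -> Layer:
    """Single-layer projection: sum the layers' adjacency entries.

    The node set is the full gene universe; for each gene pair the
    aggregate weight is the sum of its intra-layer weights (a pair absent
    from a layer contributes 0).  Inter-layer couplings are excluded.
    Sums may exceed 1, so the returned layer is non-probabilistic; with
    ``normalize=True`` the sums are divided by the layer count instead.
    """
    M.validate()
    agg = Layer("aggregate", probabilistic=False)
    for g in sorted(M.gene_universe):
        agg.add_node(g)
    sums: dict = {}
    for ly in M.layers:
        for u, v, data in ly.graph.edges(data=True):
            key = (u, v) if u <= v else (v, u)
            sums[key] = sums.get(key, 0.0) + data["weight"]
    denom = len(M.layers) if normalize else 1
    for (u, v), w in sums.items():
        agg.add_edge(u, v, w / denom)
    return agg


@dataclass
class SupraStructure:
    """Dense symmetric block matrix over node-layer replicas.

    Diagonal blocks are the per-layer adjacencies; off-diagonal entries
    are coupling weights.  ``ordering`` lists the node-layer pairs row by
    row: layers in declaration order, genes lexicographic within each
    layer.
    """

    ordering: list
    matrix: np.ndarray

    @property
    def size(self) -> int:
        return len(self.ordering)

    def index(self, gene: str, layer_name: str) -> int:
        return self.ordering.index((gene, layer_name))


def supra_structure(M: MultilayerNetwork) -> SupraStructure:
    """Assemble the supra-adjacency matrix of a multilayer network."""
    M.validate()
    ordering = [
        (g, ly.name) for ly in M.layers for g in sorted(ly.nodes)
    ]
    idx = {nl: i for i, nl in enumerate(ordering)}
    n = len(ordering)
    S = np.zeros((n, n))
    for ly in M.layers:
        for u, v, data in ly.graph.edges(data=True):
            i, j = idx[(u, ly.name)], idx[(v, ly.name)]
            S[i, j] = S[j, i] = data["weight"]
    for a, b, w in M.interlayer_edges:
        i, j = idx[a], idx[b]
        S[i, j] = S[j, i] = w
    return SupraStructure(ordering=ordering, matrix=S)


# -- exchange formats -------------------------------------------------


def write_graphml(layer: Layer, path) -> None:
    nx.write_graphml(layer.graph, path)


def read_graphml(path, name: str, probabilistic: bool = True) -> Layer:
    g = nx.read_graphml(path)
    layer = Layer(name, probabilistic=probabilistic)
    for node in g.nodes:
        layer.add_node(node)
    for u, v, data in g.edges(data=True):
        layer.add_edge(u, v, data.get("weight", 1.0))
    return layer


def write_extended_edgelist(M: MultilayerNetwork, edges_path, manifest_path) -> None:
    """Write a multilayer exchange pair: extended edge list + manifest.

    Edge list: one tab-separated line per edge,
    ``layer_from  gene_from  layer_to  gene_to  weight`` (intra-layer
    edges then couplings); manifest maps 1-based layer index to name.
    """
    with open(manifest_path, "w") as fh:
        for i, name in enumerate(M.layer_names, start=1):
            fh.write(f"{i}\t{name}\n")
    with open(edges_path, "w") as fh:
        for ly in M.layers:
            for u, v in sorted(ly.edges):
                w = ly.weight(u, v)
                fh.write(f"{ly.name}\t{u}\t{ly.name}\t{v}\t{w:.10g}\n")
        for (g, la), (_, lb), w in M.interlayer_edges:
            fh.write(f"{la}\t{g}\t{lb}\t{g}\t{w:.10g}\n")


def read_extended_edgelist(edges_path, manifest_path) -> MultilayerNetwork:
    """Read the exchange pair written by :func:`write_extended_edgelist`."""
    order = []
    with open(manifest_path) as fh:
        for line in fh:
            if line.strip():
                _, name = line.rstrip("\n").split("\t")
                order.append(name)
    layers = {name: Layer(name) for name in order}
    couplings = []
    with open(edges_path) as fh:
        for line in fh:
            if not line.strip():
                continue
            la, ga, lb, gb, w = line.rstrip("\n").split("\t")
            w = float(w)
            if la == lb:
                layers[la].add_edge(ga, gb, w)
            else:
                couplings.append(((ga, la), (gb, lb), w))
    M = MultilayerNetwork(layers=[layers[n] for n in order],
                          interlayer_edges=couplings)
    for (g, la), (_, lb), _ in couplings:
        layers[la].add_node(g)
        layers[lb].add_node(g)
    M.validate()
    return M
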