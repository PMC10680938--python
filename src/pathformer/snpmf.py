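"""Signaling Network Pathway Modeling Framework (SNPMF).

Each gene v in a signaling network gets a sparse binary vector p(v) of length
B*|S| that records, block by graph distance, which universe genes lie around
it: entry ``(d-1)*|S| + h(u)`` is 1 iff the shortest-path distance from v to
u in the sample's network is exactly d, for 1 <= d <= B.  Because the
interaction network is shared across samples and the order function h is
global, the same gene receives the same encoding in every sample network it
appears in; the vectors act both as pathway context for the attention
mechanism and as positional encodings in the first encoder layer.

Distance semantics: each gene is marked once, at its shortest distance
(marking a gene at every achievable path length would break the B*|S| size
bound and the gene-appears-at-most-once property).  A ``strict_lt`` flag
restricts to d < B, leaving the last block empty, for users who prefer the
strict reading of the bound.
"""

from __future__ import annotations

import networkx as nx
import numpy as np
import scipy.sparse as sp

from .cohort_io import GeneUniverse, Sample, SignalingCohort

__all__ = [
    "sample_network",
    "bfs_distance_map",
    "build_pathway_vector",
    "build_pathway_matrix",
    "injectivity_check",
    "PathwayEncoder",
]


def sample_network(cohort: SignalingCohort, sample: Sample) -> nx.Graph:
    """The sample's signaling network: induced subgraph of the shared edges."""
    g = nx.Graph()
    g.add_nodes_from(sample.present_genes)
    pg = sample.present_genes
    for e in cohort.edges:
        u, v = tuple(e)
        if u in pg and v in pg:
            g.add_edge(u, v)
    return g


def full_network(cohort: SignalingCohort) -> nx.Graph:
    """The shared network over the whole universe."""
    g = nx.Graph()
    g.add_nodes_from(cohort.universe.genes)
    g.add_edges_from(tuple(e) for e in cohort.edges)
    return g


def bfs_distance_map(network: nx.Graph, source_gene: str, bound: int) -> dict[str, int]:
    """Shortest-path distances from `source_gene`, restricted to [1, bound].

    The source itself is excluded.  Raises ``KeyError`` if the source is not
    in the network.
    """
    if source_gene not in network:
        raise KeyError(f"source gene {source_gene!r} not in network")
    if bound < 1:
        raise ValueError("distance bound must be >= 1")
    dist = nx.single_source_shortest_path_length(network, source_gene, cutoff=bound)
    return {g: d for g, d in dist.items() if d >= 1}


def _indices(
    network: nx.Graph, gene: str, bound: int, universe: GeneUniverse, strict_lt: bool
) -> list[int]:
    d_max = bound - 1 if strict_lt else bound
    s = len(universe)
    out = []
    if d_max >= 1:
        for u, d in bfs_distance_map(network, gene, d_max).items():
            out.append((d - 1) * s + universe.h(u))
    return sorted(out)


def build_pathway_vector(
    network: nx.Graph,
    gene: str,
    bound: int,
    universe: GeneUniverse,
    strict_lt: bool = False,
) -> sp.csr_matrix:
    """The sparse binary pathway vector p(gene), shape (1, bound*|S|)."""
    idx = _indices(network, gene, bound, universe, strict_lt)
    n = bound * len(universe)
    data = np.ones(len(idx))
    return sp.csr_matrix((data, (np.zeros(len(idx), dtype=int), idx)), shape=(1, n))


def build_pathway_matrix(
    network: nx.Graph,
    subset: list[str],
    bound: int,
    universe: GeneUniverse,
    strict_lt: bool = False,
) -> sp.csr_matrix:
    """Stack p(v) for v in `subset` (selection order), shape (K, bound*|S|)."""
    n = bound * len(universe)
    rows, cols = [], []
    for k, gene in enumerate(subset):
        for j in _indices(network, gene, bound, universe, strict_lt):
            rows.append(k)
            cols.append(j)
    data = np.ones(len(rows))
    return sp.csr_matrix((data, (rows, cols)), shape=(len(subset), n))


def injectivity_check(
    network: nx.Graph, bound: int, universe: GeneUniverse, strict_lt: bool = False
) -> list[tuple[str, str]]:
    """Report distinct gene pairs with identical pathway encodings.

    An empty report means p(.) is injective on this network at this bound —
    the encoding distinguishes every pair of genes by its bounded
    neighborhood.
    """
    sigs: dict[tuple[int, ...], list[str]] = {}
    for gene in network.nodes:
        key = tuple(_indices(network, gene, bound, universe, strict_lt))
        sigs.setdefault(key, []).append(gene)
    collisions = []
    for genes in sigs.values():
        genes = sorted(genes, key=universe.h)
        for i in range(len(genes)):
            for j in range(i + 1, len(genes)):
                collisions.append((genes[i], genes[j]))
    return sorted(collisions)


class PathwayEncoder:
    """Per-gene p(v) cache for one shared network.

    Sample networks in a cohort differ only by which genes are present; when
    all genes are present (the common case) every sample shares one network
    and the per-gene vectors can be computed once.  Keyed by the present-gene
    set of each sample.
    """

    def __init__(
        self,
        cohort: SignalingCohort,
        bound: int,
        strict_lt: bool = False,
        on_subset: bool = False,
    ):
        self.cohort = cohort
        self.bound = bound
        self.strict_lt = strict_lt
        self.on_subset = on_subset
        self._networks: dict[frozenset[str], nx.Graph] = {}
        self._cache: dict[tuple[frozenset[str], str], list[int]] = {}

    def network_for(self, sample: Sample) -> nx.Graph:
        key = sample.present_genes
        if key not in self._networks:
            self._networks[key] = sample_network(self.cohort, sample)
        return self._networks[key]

    def matrix(self, sample: Sample, subset: list[str]) -> sp.csr_matrix:
        """P matrix (K x bound*|S|) for the sample's selected subset.

        By default p(v) is computed on the sample's full network (selection
        does not amputate pathway context); with ``on_subset=True`` it is
        computed on the subgraph induced by the subset.
        """
        if self.on_subset:
            net = self.network_for(sample).subgraph(subset)
            return build_pathway_matrix(
                net, subset, self.bound, self.cohort.universe, self.strict_lt
            )
        net_key = sample.present_genes
        net = self.network_for(sample)
        n = self.bound * len(self.cohort.universe)
        rows, cols = [], []
        for k, gene in enumerate(subset):
            ck = (net_key, gene)
            if ck not in self._cache:
                self._cache[ck] = _indices(
                    net, gene, self.bound, self.cohort.universe, self.strict_lt
                )
            for j in self._cache[ck]:
                rows.append(k)
                cols.append(j)
        return sp.csr_matrix(
            (np.ones(len(rows)), (rows, cols)), shape=(len(subset), n)
        )
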