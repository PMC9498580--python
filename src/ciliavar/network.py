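"""Markov Clustering, per-patient subnetworks, and permutation enrichment.

The Markov Clustering Algorithm (MCL) simulates a random walk on the
weighted gene-interaction graph: the column-stochastic transition matrix is
alternately *expanded* (matrix power, letting flow spread) and *inflated*
(elementwise power followed by column renormalization, strengthening
already-strong flow) until a fixed point; clusters are the attractor basins
of the limit.  Edge confidences act as transition weights directly, with
unit self-loops added for convergence.

Interaction enrichment replaces the analytic enrichment p-value of the
external network database with a seedable, distribution-free permutation
test: the observed number of edges within a gene set is compared against
the same count in degree-preserving randomizations of the whole graph
(double-edge swaps), with the add-one correction
p = (1 + #{null >= observed}) / (1 + permutations).
"""

from __future__ import annotations

from typing import Iterable, Set

import networkx as nx
import numpy as np
from scipy.sparse.csgraph import connected_components

from .errors import ValidationError
from .models import ClusterPartition, EnrichmentResult, InteractionGraph

#: Double-edge swaps attempted per graph edge in each permutation.
SWAPS_PER_EDGE = 10


def mcl(
    graph: InteractionGraph,
    inflation: float = 2.0,
    expansion: int = 2,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> ClusterPartition:
    """Cluster a weighted graph with the Markov Clustering Algorithm.

    Deterministic for fixed inputs: nodes are ordered lexicographically and
    clusters are numbered by their lowest-ordered member.  Non-convergence
    within *max_iter* returns the current partition with ``converged=False``.
    """
    if graph.number_of_nodes() == 0:
        raise ValidationError("cannot cluster an empty graph")
    if inflation <= 1.0:
        raise ValidationError(f"inflation must exceed 1, got {inflation}")
    if expansion < 2:
        raise ValidationError(f"expansion must be >= 2, got {expansion}")

    nodes = sorted(graph.nodes)
    adj = nx.to_numpy_array(graph, nodelist=nodes, weight="confidence")
    np.fill_diagonal(adj, 1.0)  # unit self-loops
    matrix = adj / adj.sum(axis=0, keepdims=True)

    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        new = np.linalg.matrix_power(matrix, expansion)
        np.power(new, inflation, out=new)
        new /= new.sum(axis=0, keepdims=True)
        change = np.abs(new - matrix).max()
        matrix = new
        if change < tol:
            converged = True
            break

    # Attractor structure: any residual flow i<->j ties the nodes together;
    # clusters are the weakly connected components of the support.
    support = (matrix > tol) | (matrix.T > tol)
    _, raw_labels = connected_components(support, directed=False)

    # Renumber so cluster ids are contiguous and ordered by lowest member.
    remap: dict = {}
    labels = {}
    for idx, node in enumerate(nodes):
        raw = int(raw_labels[idx])
        if raw not in remap:
            remap[raw] = len(remap)
        labels[node] = remap[raw]
    return ClusterPartition(
        labels=labels,
        inflation=inflation,
        iterations_run=iterations,
        converged=converged,
    )


def patient_subnetwork(
    graph: InteractionGraph,
    patient_deleterious_genes: Iterable[str],
    min_confidence: float = 0.15,
) -> nx.Graph:
    """Induced subgraph on a patient's deleterious-variant genes.

    Edges below *min_confidence* are dropped; genes without any retained
    interaction stay in the result as singletons (they are real findings,
    just unconnected at this confidence tier).  Genes absent from the
    background network are also retained as singletons.
    """
    if not (0.0 <= min_confidence <= 1.0):
        raise ValidationError(f"min_confidence={min_confidence} outside [0, 1]")
    genes = set(patient_deleterious_genes)
    sub = nx.Graph()
    sub.add_nodes_from(genes)
    for u, v, data in graph.subgraph(genes & set(graph.nodes)).edges(data=True):
        if data["confidence"] >= min_confidence:
            sub.add_edge(u, v, confidence=data["confidence"])
    return sub


def _count_internal_edges(graph: nx.Graph, node_set: Set[str]) -> int:
    return sum(1 for u, v in graph.edges if u in node_set and v in node_set)


def interaction_enrichment(
    graph: InteractionGraph,
    node_set: Iterable[str],
    n_permutations: int = 1000,
    seed: int = 0,
    swaps_per_edge: int = SWAPS_PER_EDGE,
) -> EnrichmentResult:
    """Permutation test for edge enrichment within a gene set.

    The null preserves every node's degree exactly (double-edge-swap
    randomization of the whole graph, ``swaps_per_edge x |E|`` swaps per
    permutation).  Reproducible for a fixed seed.
    """
    node_set = set(node_set)
    if len(node_set) < 2:
        raise ValidationError("node_set must contain at least 2 genes")
    missing = node_set - set(graph.nodes)
    if missing:
        raise ValidationError(f"genes absent from the graph: {sorted(missing)}")
    if n_permutations < 100:
        raise ValidationError("need at least 100 permutations")

    observed = _count_internal_edges(graph, node_set)
    degrees = dict(graph.degree)
    m = graph.number_of_edges()
    rng = np.random.default_rng(seed)
    n_at_least = 0
    null_total = 0.0
    for _ in range(n_permutations):
        null_graph = graph.copy()
        if m >= 2 and null_graph.number_of_nodes() >= 4:
            try:
                nx.double_edge_swap(
                    null_graph,
                    nswap=swaps_per_edge * m,
                    max_tries=100 * swaps_per_edge * m,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
            except nx.NetworkXAlgorithmError:
                pass  # near-complete graphs admit few swaps; keep what succeeded
        if dict(null_graph.degree) != degrees:  # contract: degrees preserved
            raise AssertionError("double-edge swap changed the degree sequence")
        null_edges = _count_internal_edges(null_graph, node_set)
        null_total += null_edges
        if null_edges >= observed:
            n_at_least += 1
    return EnrichmentResult(
        node_set=frozenset(node_set),
        observed_edges=observed,
        null_mean=null_total / n_permutations,
        p_value=(1 + n_at_least) / (1 + n_permutations),
        n_permutations=n_permutations,
        seed=seed,
    )
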