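"""Median-joining haplotype networks over called allele sequences.

Implements the Bandelt-style median-joining construction: starting from
the minimum spanning network (MSN, the union of all minimum spanning
trees within tolerance epsilon) over the observed sequences, median
(per-column consensus) vectors of connected triples are added whenever
they can shorten connections, and obsolete medians (degree <= 2) are
pruned, iterating to a fixpoint. With epsilon = 0 the result is the
sparsest network. Edge weights are Hamming distances with the alignment
gap treated as a fifth character state.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "HaplotypeNetwork",
    "ConvergenceError",
    "hamming",
    "median_vector",
    "minimum_spanning_network",
    "build_mjn",
    "annotate_counts",
    "write_graphml",
    "write_edge_list",
]

STATE_ORDER = "ACGT-"


class ConvergenceError(RuntimeError):
    """Raised when median generation does not reach a fixpoint."""


def hamming(a: str, b: str) -> int:
    """Number of differing columns; '-' counts as an ordinary state."""
    if len(a) != len(b):
        raise ValueError("sequences have unequal lengths; align them first")
    return sum(x != y for x, y in zip(a, b))


def median_vector(a: str, b: str, c: str) -> str:
    """Per-column majority consensus of three aligned sequences.

    Columns where all three states differ break ties to the smallest
    state in the order A < C < G < T < '-'.
    """
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:
            out.append(min((x, y, z), key=STATE_ORDER.index))
    return "".join(out)


def minimum_spanning_network(
    sequences: Mapping[str, str], epsilon: int = 0
) -> nx.Graph:
    """Union of all minimum spanning trees, relaxed by ``epsilon``.

    Distances are processed in ascending order; an edge at distance d
    joins the network iff its endpoints lie in different components of
    the graph built from all edges with distance < d - epsilon (for
    epsilon = 0: strictly smaller distances). All qualifying edges at a
    level enter together, so the result contains every MST.
    """
    labels = list(sequences)
    graph = nx.Graph()
    for label in labels:
        graph.add_node(label, sequence=sequences[label])
    if len(labels) < 2:
        return graph
    edges: dict[int, list[tuple[str, str]]] = {}
    for u, v in itertools.combinations(labels, 2):
        d = hamming(sequences[u], sequences[v])
        edges.setdefault(d, []).append((u, v))
    components = nx.utils.UnionFind(labels)
    pending: list[tuple[int, str, str]] = []
    for d in sorted(edges):
        # connectivity frozen at the start of the tolerance window
        for dp, u, v in list(pending):
            if dp < d - epsilon:
                components.union(u, v)
                pending.remove((dp, u, v))
        added = []
        for u, v in edges[d]:
            if components[u] != components[v]:
                graph.add_edge(u, v, weight=d)
                added.append((d, u, v))
        pending.extend(added)
    return graph


def _connected_triples(graph: nx.Graph) -> list[tuple[str, str, str]]:
    """Triples {u, v, w} carrying at least two of the three possible links."""
    triples = []
    for v in sorted(graph.nodes):
        neighbours = sorted(graph.neighbors(v))
        for u, w in itertools.combinations(neighbours, 2):
            triples.append((u, v, w))
    return triples


def build_mjn(
    sequences: Mapping[str, str] | Sequence[tuple[str, str]],
    epsilon: int = 0,
    max_iterations: int = 20,
) -> nx.Graph:
    """Median-joining network over labelled, aligned sequences.

    Nodes carry ``sequence`` and ``observed`` attributes; inferred
    medians are labelled ``median-1``, ``median-2``, ... in creation
    order. Deterministic for a given input: ties break lexicographically
    on sequence. Raises :class:`ConvergenceError` if the
    median-generation fixpoint is not reached within ``max_iterations``.
    """
    items = list(sequences.items()) if isinstance(sequences, Mapping) else list(sequences)
    if not items:
        raise ValueError("no sequences given")
    lengths = {len(s) for _, s in items}
    if len(lengths) != 1:
        raise ValueError("sequences have unequal lengths; align them first")
    seq_to_label: dict[str, str] = {}
    for label, seq in items:
        seq = seq.upper()
        if seq not in seq_to_label:
            seq_to_label[seq] = label
    observed = {label: seq for seq, label in seq_to_label.items()}
    nodes = dict(observed)
    median_index = 0
    converged = False
    # medians only accumulate here (monotone growth guarantees a
    # fixpoint); obsolete ones are pruned in the cleanup phase below
    for _ in range(max_iterations):
        graph = minimum_spanning_network(nodes, epsilon)
        known = set(nodes.values())
        candidates: dict[str, int] = {}
        for u, v, w in _connected_triples(graph):
            m = median_vector(nodes[u], nodes[v], nodes[w])
            if m in known:
                continue
            cost = hamming(m, nodes[u]) + hamming(m, nodes[v]) + hamming(m, nodes[w])
            if m not in candidates or cost < candidates[m]:
                candidates[m] = cost
        if not candidates:
            converged = True
            break
        threshold = min(candidates.values()) + epsilon
        for m in sorted(
            (m for m, cost in candidates.items() if cost <= threshold)
        ):
            median_index += 1
            nodes[f"median-{median_index}"] = m
    if not converged:
        raise ConvergenceError(
            f"median generation did not converge in {max_iterations} iterations"
        )
    # final pruning of obsolete medians, re-deriving the MSN each pass
    while True:
        graph = minimum_spanning_network(nodes, epsilon)
        obsolete = [n for n in nodes if n not in observed and graph.degree(n) <= 2]
        if not obsolete:
            break
        for n in obsolete:
            del nodes[n]
    for node in graph.nodes:
        graph.nodes[node]["observed"] = node in observed
    return graph


def annotate_counts(
    network: nx.Graph, genotypes: pd.DataFrame, methods: Sequence[str] | None = None
) -> nx.Graph:
    """Attach per-method gene-copy observation counts to observed nodes.

    Counts follow the frequency-table convention (homozygotes count
    twice). Median nodes get zero; alleles in the table but absent from
    the network trigger a warning.
    """
    if methods is None:
        methods = sorted(genotypes["method"].unique())
    labels = set(network.nodes)
    for method in methods:
        counts: dict[str, int] = {}
        subset = genotypes[genotypes["method"] == method]
        for row in subset.itertuples(index=False):
            alleles = list(row.alleles)
            if len(alleles) == 1:
                alleles = alleles * 2
            for allele in alleles:
                counts[allele] = counts.get(allele, 0) + 1
        for allele in sorted(set(counts) - labels):
            warnings.warn(f"allele {allele!r} not present in network; count dropped")
        for node in network.nodes:
            observed = network.nodes[node].get("observed", True)
            network.nodes[node][f"count_{method}"] = (
                counts.get(node, 0) if observed else 0
            )
    return network


def write_graphml(network: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(network, str(path))


def write_edge_list(network: nx.Graph, path: str | Path) -> None:
    """Plain-text edge list: node1 <TAB> node2 <TAB> mutations."""
    with open(path, "w") as handle:
        handle.write("# node1\tnode2\tmutations\n")
        for u, v, data in sorted(network.edges(data=True)):
            handle.write(f"{u}\t{v}\t{data['weight']}\n")
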