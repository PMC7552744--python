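"""Independent reference implementations used only to check the package.

These are deliberately naive (quadratic DP, exhaustive enumeration,
dictionary counting) and share no code with the library paths they
verify.
"""

from __future__ import annotations

import itertools
from collections import Counter


def edit_distance_dp(a: str, b: str) -> int:
    """Textbook Levenshtein DP, unit costs."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(
                    prev[j] + 1,  # delete from a
                    cur[j - 1] + 1,  # insert into a
                    prev[j - 1] + (ca != cb),  # match/substitute
                )
            )
        prev = cur
    return prev[-1]


def edit_summary_dp(a: str, b: str) -> tuple[int, int, int]:
    """(substitutions, insertions, deletions) via full-traceback DP.

    Among cost-equal alignments prefers the diagonal (maximising
    substitutions over indel pairs), which is also cost-minimal because
    one substitution never costs more than an insertion plus a deletion.
    """
    n, m = len(a), len(b)
    cost = [[0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        cost[i][0] = i
    for j in range(1, m + 1):
        cost[0][j] = j
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            cost[i][j] = min(
                cost[i - 1][j - 1] + (a[i - 1] != b[j - 1]),
                cost[i - 1][j] + 1,
                cost[i][j - 1] + 1,
            )
    subs = ins = dels = 0
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and cost[i][j] == cost[i - 1][j - 1] + (a[i - 1] != b[j - 1]):
            subs += a[i - 1] != b[j - 1]
            i, j = i - 1, j - 1
        elif i > 0 and cost[i][j] == cost[i - 1][j] + 1:
            dels += 1
            i -= 1
        else:
            ins += 1
            j -= 1
    return subs, ins, dels


def count_variants(sequences: list[str]) -> list[tuple[str, int]]:
    """Dictionary counting, deepest first then lexicographic."""
    counts = Counter(sequences)
    return sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


def pairwise_matrix(seqs: list[str]) -> list[list[int]]:
    """Double-loop pairwise difference counts."""
    n = len(seqs)
    out = [[0] * n for _ in range(n)]
    for i in range(n):
        for j in range(n):
            out[i][j] = sum(x != y for x, y in zip(seqs[i], seqs[j]))
    return out


def minimum_spanning_network_bruteforce(
    labels: list[str], seqs: dict[str, str]
) -> set[frozenset[str]]:
    """Union of the edges of ALL minimum spanning trees, by enumeration."""
    n = len(labels)
    if n < 2:
        return set()
    edges = [
        (hamming(seqs[u], seqs[v]), u, v)
        for u, v in itertools.combinations(labels, 2)
    ]

    def is_spanning_tree(subset) -> bool:
        if len(subset) != n - 1:
            return False
        parent = {x: x for x in labels}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for _, u, v in subset:
            ru, rv = find(u), find(v)
            if ru == rv:
                return False
            parent[ru] = rv
        return True

    best = None
    best_edges: set[frozenset[str]] = set()
    for subset in itertools.combinations(edges, n - 1):
        if not is_spanning_tree(subset):
            continue
        weight = sum(w for w, _, _ in subset)
        if best is None or weight < best:
            best = weight
            best_edges = {frozenset((u, v)) for _, u, v in subset}
        elif weight == best:
            best_edges |= {frozenset((u, v)) for _, u, v in subset}
    return best_edges


def msn_edges_cut_property(labels: list[str], seqs: dict[str, str]) -> set[frozenset[str]]:
    """Union-of-all-MSTs via the cut property, polynomial time.

    An edge of weight w belongs to some minimum spanning tree iff its
    endpoints are disconnected in the subgraph of strictly lighter
    edges. Connectivity is delegated to networkx, independently of the
    incremental union-find construction under test.
    """
    import networkx as nx

    out: set[frozenset[str]] = set()
    for u, v in itertools.combinations(labels, 2):
        w = hamming(seqs[u], seqs[v])
        lighter = nx.Graph()
        lighter.add_nodes_from(labels)
        for x, y in itertools.combinations(labels, 2):
            if hamming(seqs[x], seqs[y]) < w:
                lighter.add_edge(x, y)
        if not nx.has_path(lighter, u, v):
            out.add(frozenset((u, v)))
    return out


def prefix_distance_assign(
    read: str, prefixes: dict[str, str], tolerance: int
) -> str | None:
    """Brute-force demultiplex: unique sample whose prefix fits within tolerance."""
    hits = []
    for sample, prefix in prefixes.items():
        if len(read) < len(prefix):
            continue
        mism = sum(x != y for x, y in zip(read[: len(prefix)], prefix))
        if mism <= tolerance:
            hits.append(sample)
    return hits[0] if len(hits) == 1 else None
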