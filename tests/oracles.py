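"""Independent brute-force oracles used to validate the implementation.

These deliberately share no code with the package: closeness comes from a
hand-rolled breadth-first search, hypergeometric tails from exhaustive
enumeration of all draws, and the BH adjustment from a direct transcription
of the step-up formula.
"""

from __future__ import annotations

from collections import deque
from fractions import Fraction
from itertools import combinations


def bfs_distances(adj: dict, start) -> dict:
    """Shortest-path distances from start via breadth-first search."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        u = queue.popleft()
        for v in adj[u]:
            if v not in dist:
                dist[v] = dist[u] + 1
                queue.append(v)
    return dist


def closeness_by_bfs(graph, variant: str = "wf_scaled") -> dict:
    """All-pairs-BFS closeness for a networkx graph (both normalizations)."""
    nodes = list(graph.nodes())
    n = len(nodes)
    adj = {u: set(graph.neighbors(u)) for u in nodes}
    out = {}
    for v in nodes:
        dist = bfs_distances(adj, v)
        reach = len(dist) - 1  # exclude v itself
        total = sum(dist.values())
        if reach == 0 or total == 0:
            out[str(v)] = 0.0
            continue
        c = reach / total
        if variant == "wf_scaled":
            c *= reach / (n - 1)
        out[str(v)] = c
    return out


def hypergeom_tail_by_enumeration(k: int, K: int, n: int, N: int) -> Fraction:
    """P(X >= k) by enumerating every size-n draw from an N-element urn
    whose first K elements are 'successes'.  Exact (Fraction); feasible
    for N <= ~14."""
    successes = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(successes.intersection(draw)) >= k:
            hits += 1
    return Fraction(hits, total) if total else Fraction(1)


def bh_stepup(pvalues) -> list:
    """Direct transcription of the BH step-up: q_(i) = min_{j>=i} p_(j)*m/j,
    capped at 1, returned in input order."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, pvalues[i] * m / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    out = [0.0] * m
    for rank, i in enumerate(order):
        out[i] = q_sorted[rank]
    return out
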