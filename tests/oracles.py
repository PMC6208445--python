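"""Independent brute-force oracles used to validate the fast implementations.

These deliberately take the slow, obviously-correct route: exhaustive
enumeration over all triples/pairs, direct tail summation for the
hypergeometric, full U-statistic enumeration for Mann-Whitney, and
per-step reachability counting for attack curves.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

import networkx as nx
import numpy as np

# ---------------------------------------------------------------------------
# triad classification by canonical code

# representatives of the 13 connected triad classes on nodes (0, 1, 2)
_TRIAD_REPRESENTATIVES = {
    "021D": [(0, 1), (0, 2)],                     # one sender, two receivers
    "021U": [(1, 0), (2, 0)],                     # two senders, one receiver
    "021C": [(0, 1), (1, 2)],                     # directed path
    "111D": [(0, 1), (1, 0), (2, 1)],
    "111U": [(0, 1), (1, 0), (1, 2)],
    "030T": [(0, 1), (0, 2), (1, 2)],             # transitive triangle (FFL)
    "030C": [(0, 1), (1, 2), (2, 0)],             # cyclic triangle
    "201": [(0, 1), (1, 0), (0, 2), (2, 0)],
    "120D": [(0, 1), (1, 0), (2, 0), (2, 1)],
    "120U": [(0, 1), (1, 0), (0, 2), (1, 2)],
    "120C": [(0, 1), (1, 0), (1, 2), (2, 0)],
    "210": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2)],
    "300": [(0, 1), (1, 0), (1, 2), (2, 1), (0, 2), (2, 0)],
}


def _canonical_code(edges: set[tuple[int, int]]) -> int:
    """Smallest 6-bit adjacency code over all relabelings of 3 nodes."""
    best = None
    pairs = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]
    for perm in itertools.permutations(range(3)):
        code = 0
        for bit, (i, j) in enumerate(pairs):
            if (perm[i], perm[j]) in edges:
                code |= 1 << bit
        if best is None or code < best:
            best = code
    return best


_CODE_TO_CLASS = {
    _canonical_code(set(e)): name for name, e in _TRIAD_REPRESENTATIVES.items()
}
assert len(_CODE_TO_CLASS) == 13


def triad_census_bruteforce(digraph: nx.DiGraph) -> dict[str, int]:
    """O(n^3) census of connected 3-node induced subgraphs (self-loops ignored)."""
    nodes = sorted(digraph.nodes())
    counts = {c: 0 for c in _TRIAD_REPRESENTATIVES}
    for a, b, c in itertools.combinations(nodes, 3):
        local = {a: 0, b: 1, c: 2}
        edges = set()
        for u, v in itertools.permutations((a, b, c), 2):
            if digraph.has_edge(u, v):
                edges.add((local[u], local[v]))
        if not edges:
            continue
        und = nx.Graph((u, v) for u, v in edges)
        und.add_nodes_from(range(3))
        if not nx.is_connected(und):
            continue
        counts[_CODE_TO_CLASS[_canonical_code(edges)]] += 1
    return counts


# ---------------------------------------------------------------------------
# exhaustive FFL scan


def find_ffls_bruteforce(network) -> list[tuple[str, str, str]]:
    """All (regulator, miRNA, target) triples by direct triple iteration."""
    regs = sorted(network.nodes_with_role("regulator"))
    mirnas = sorted(network.nodes_with_role("miRNA"))
    tf_genes = sorted(
        network.nodes_with_role("tf_target") | network.nodes_with_role("regulator")
    )
    out = []
    for r in regs:
        for m in mirnas:
            for t in tf_genes:
                if t == r:
                    continue
                if (
                    network.has_edge(r, m, "binds")
                    and network.has_edge(r, t, "binds")
                    and network.has_edge(m, t, "silences")
                ):
                    out.append((r, m, t))
    return sorted(out)


# ---------------------------------------------------------------------------
# exact statistics


def hypergeom_sf_oracle(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) by direct rational tail summation of the pmf."""
    total = Fraction(0)
    denom = math.comb(N, n)
    for x in range(max(k, max(0, n + K - N)), min(K, n) + 1):
        total += Fraction(math.comb(K, x) * math.comb(N - K, n - x), denom)
    return float(total)


def mannwhitney_exact_oracle(x, y) -> float:
    """Two-sided exact Mann-Whitney p by full enumeration of group labels.

    Feasible for n + m <= ~14; handles ties by enumerating all
    C(n+m, n) assignments of the pooled values.
    """
    x, y = list(x), list(y)
    pooled = x + y
    n, m = len(x), len(y)

    def u_stat(xs, ys):
        u = 0.0
        for xi in xs:
            for yi in ys:
                if xi > yi:
                    u += 1
                elif xi == yi:
                    u += 0.5
        return u

    u_obs = u_stat(x, y)
    mean_u = n * m / 2
    dev_obs = abs(u_obs - mean_u)
    hits = 0
    total = 0
    idx = range(n + m)
    for comb in itertools.combinations(idx, n):
        comb = set(comb)
        xs = [pooled[i] for i in comb]
        ys = [pooled[i] for i in idx if i not in comb]
        total += 1
        if abs(u_stat(xs, ys) - mean_u) >= dev_obs - 1e-12:
            hits += 1
    return hits / total


# ---------------------------------------------------------------------------
# attack-curve pair counting


def connectivity_loss_oracle(
    undirected: nx.Graph, removal_order: list[str]
) -> list[float]:
    """Loss after each removal, by direct all-pairs reachability checks."""
    g = undirected.copy()
    nodes0 = sorted(g.nodes())
    r0 = sum(
        1
        for u, v in itertools.combinations(nodes0, 2)
        if nx.has_path(g, u, v)
    )
    losses = []
    for victim in removal_order:
        g.remove_node(victim)
        r = sum(
            1
            for u, v in itertools.combinations(sorted(g.nodes()), 2)
            if nx.has_path(g, u, v)
        )
        losses.append(1 - r / r0)
    return losses
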