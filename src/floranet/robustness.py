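"""Targeted-attack robustness of the meta-network.

Robustness is read from connectivity-loss curves under iterative node
removal.  At each step the node with the highest betweenness centrality
on the current undirected view is removed (a "cascading" attack:
betweenness is recomputed after every removal) and connectivity loss is
1 - R/R0, where R counts unordered node pairs still connected and R0 is
the connected-pair count of the intact network; removed nodes count as
disconnected endpoints.  Dropping the miRNA-mediated (silences) edges
before the attack yields the comparator network without miRNA regulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy import stats

from .network import MetaNetwork

STRATEGIES = ("betweenness_cascading", "betweenness_initial", "degree", "random")


@dataclass
class AttackCurve:
    """Connectivity loss as a function of the fraction of nodes removed."""

    points: list[tuple[float, float]]
    strategy: str
    removed: list[str] = field(default_factory=list)

    @property
    def fractions(self) -> np.ndarray:
        return np.array([p[0] for p in self.points])

    @property
    def losses(self) -> np.ndarray:
        return np.array([p[1] for p in self.points])

    def auc(self) -> float:
        """Area under the loss curve (trapezoid); higher = more fragile."""
        return float(np.trapezoid(self.losses, self.fractions))


def _connected_pairs(graph: nx.Graph) -> int:
    return sum(
        len(c) * (len(c) - 1) // 2 for c in nx.connected_components(graph)
    )


def attack_curve(
    network: MetaNetwork,
    strategy: str = "betweenness_cascading",
    seed: int | None = None,
    max_fraction: float = 1.0,
) -> AttackCurve:
    """Remove nodes by the given strategy and trace connectivity loss.

    Ties on the removal criterion break to the lexicographically smallest
    node id.  ``max_fraction`` truncates the cascade early (the curve then
    ends before loss reaches 1).
    """
    if strategy not in STRATEGIES:
        raise ValueError(f"unknown strategy {strategy!r}; choose from {STRATEGIES}")
    g = nx.Graph(network.graph)  # undirected simple view
    g.remove_edges_from(nx.selfloop_edges(g))
    n0 = g.number_of_nodes()
    if n0 < 2:
        raise ValueError("need at least 2 nodes for an attack curve")
    r0 = _connected_pairs(g)
    if r0 == 0:
        raise ValueError("network has no connected pairs")
    rng = np.random.default_rng(seed)

    if strategy == "betweenness_initial":
        order = sorted(
            g.nodes(), key=lambda n: (-nx.betweenness_centrality(g)[n], n)
        )
    elif strategy == "degree":
        order = sorted(g.nodes(), key=lambda n: (-g.degree(n), n))
    elif strategy == "random":
        order = list(g.nodes())
        rng.shuffle(order)
    else:
        order = None  # chosen adaptively

    points = [(0.0, 0.0)]
    removed: list[str] = []
    n_steps = int(np.floor(max_fraction * n0))
    prev_loss = 0.0
    for k in range(1, n_steps + 1):
        if strategy == "betweenness_cascading":
            bc = nx.betweenness_centrality(g)
            victim = min(bc, key=lambda n: (-bc[n], n))
        else:
            victim = order[k - 1]
        g.remove_node(victim)
        removed.append(victim)
        loss = 1.0 - _connected_pairs(g) / r0
        assert loss >= prev_loss - 1e-12, "connectivity loss must be monotone"
        prev_loss = loss
        points.append((k / n0, loss))
    return AttackCurve(points=points, strategy=strategy, removed=removed)


@dataclass(frozen=True)
class CurveComparison:
    ks_statistic: float
    p_value: float
    auc_a: float
    auc_b: float

    @property
    def auc_difference(self) -> float:
        return self.auc_a - self.auc_b


def compare_curves(curve_a: AttackCurve, curve_b: AttackCurve) -> CurveComparison:
    """Two-sample two-sided Kolmogorov-Smirnov test on the loss values.

    The two curves' loss trajectories are compared as samples; the
    area-under-loss difference is reported as an effect size (positive
    when curve_a is the more fragile network).
    """
    if len(curve_a.points) < 2 or len(curve_b.points) < 2:
        raise ValueError("curves need at least 2 points to compare")
    res = stats.ks_2samp(curve_a.losses, curve_b.losses, method="asymp")
    return CurveComparison(
        ks_statistic=float(res.statistic),
        p_value=float(res.pvalue),
        auc_a=curve_a.auc(),
        auc_b=curve_b.auc(),
    )
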