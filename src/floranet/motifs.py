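"""Network motif census and enrichment against degree-preserving nulls.

One-node motifs are autoregulatory self-edges, two-node motifs are mutual
(feedback) pairs, and three-node motifs are the 13 connected directed
triad isomorphism classes in standard MAN notation (021D ... 300).  The
census ignores edge types (direction only, self-edges excluded); the null
model rewires by double-edge swaps restricted within each edge type
(TF->miRNA binding, TF->TF binding, miRNA silencing), which preserves
every node's per-type in- and out-degree and the network's bipartite-like
layering.  The feed-forward-loop topology is the transitive triad 030T.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import igraph as ig
import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .network import MetaNetwork

# igraph triad_census order (Holland-Leinhardt); first three are the
# disconnected classes and are excluded from the motif universe.
_IGRAPH_ORDER = (
    "003", "012", "102", "021D", "021U", "021C", "111D", "111U",
    "030T", "030C", "201", "120D", "120U", "120C", "210", "300",
)
TRIAD_CLASSES: tuple[str, ...] = _IGRAPH_ORDER[3:]
FFL_CLASS = "030T"


@dataclass(frozen=True)
class MotifEnrichment:
    class_id: str
    observed: int
    null_mean: float
    null_sd: float
    z: float  # nan when null_sd == 0
    empirical_p: float
    adjusted_p: float


@dataclass(frozen=True)
class SIMInstance:
    """A single-input module: one regulator binding a pair of TF genes."""

    regulator: str
    target_pair: frozenset


def count_autoregulation(network: MetaNetwork) -> set[str]:
    """Regulators carrying a binds self-edge."""
    return {
        r
        for r in network.nodes_with_role("regulator")
        if network.has_edge(r, r, "binds")
    }


def count_feedback_loops(network: MetaNetwork) -> set[frozenset]:
    """Unordered node pairs {u, v} with edges in both directions (any types)."""
    loops = set()
    for u, v in network.graph.edges():
        if u != v and network.graph.has_edge(v, u):
            loops.add(frozenset((u, v)))
    return loops


def _to_igraph(network: MetaNetwork) -> ig.Graph:
    nodes = sorted(network.graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    edges = [
        (index[u], index[v]) for u, v in network.graph.edges() if u != v
    ]
    return ig.Graph(n=len(nodes), edges=edges, directed=True)


def triad_census(network: MetaNetwork) -> dict[str, int]:
    """Counts of connected induced 3-node subgraphs by isomorphism class.

    Edge types are ignored (direction kept) and self-edges excluded.
    """
    if network.n_nodes < 3:
        return {c: 0 for c in TRIAD_CLASSES}
    g = _to_igraph(network)
    census = g.triad_census()
    return {c: int(census[i]) for i, c in enumerate(_IGRAPH_ORDER) if c in TRIAD_CLASSES}


_SWAP_CLASSES = ("binds_mirna", "binds_tf", "silences")


def _edge_class(network: MetaNetwork, u: str, v: str) -> str:
    etype = network.graph[u][v]["etype"]
    if etype == "silences":
        return "silences"
    return "binds_mirna" if "miRNA" in network.roles(v) else "binds_tf"


def _indexed_edges(network: MetaNetwork):
    """Node list plus integer-encoded edges split by swap class."""
    nodes = sorted(network.graph.nodes())
    index = {n: i for i, n in enumerate(nodes)}
    by_class: dict[str, list[tuple[int, int]]] = {c: [] for c in _SWAP_CLASSES}
    self_edges: list[int] = []
    for u, v in sorted(network.graph.edges()):
        if u == v:
            self_edges.append(index[u])
        else:
            by_class[_edge_class(network, u, v)].append((index[u], index[v]))
    return nodes, by_class, self_edges


def _swap_core(
    by_class: dict[str, list[tuple[int, int]]],
    n_nodes: int,
    n_swaps_factor: float,
    rng: np.random.Generator,
    occupied: set[int],
) -> dict[str, list[tuple[int, int]]]:
    """In-place-style double-edge swaps on integer edge lists.

    ``occupied`` holds every ordered pair of the whole graph encoded as
    u * n_nodes + v (including self-edges and other classes) and is
    updated as swaps are accepted, so no duplicate pair can arise.
    """
    out: dict[str, list[tuple[int, int]]] = {}
    for cname in _SWAP_CLASSES:
        edges = list(by_class[cname])
        out[cname] = edges
        if len(edges) < 2:
            continue
        n_attempts = math.ceil(n_swaps_factor * len(edges))
        draws = rng.integers(0, len(edges), size=(n_attempts, 2))
        for i, j in draws:
            if i == j:
                continue
            a, b = edges[i]
            c, d = edges[j]
            if a == d or c == b:
                continue
            ad = a * n_nodes + d
            cb = c * n_nodes + b
            if ad in occupied or cb in occupied:
                continue
            occupied.discard(a * n_nodes + b)
            occupied.discard(c * n_nodes + d)
            occupied.add(ad)
            occupied.add(cb)
            edges[i] = (a, d)
            edges[j] = (c, b)
    return out


def randomize_network(
    network: MetaNetwork,
    n_swaps_factor: float = 10.0,
    seed: int | np.random.Generator | None = None,
) -> MetaNetwork:
    """Degree-preserving rewiring by double-edge swaps within edge types.

    For each swap class (binds-to-miRNA, binds-to-TF, silences) about
    ``n_swaps_factor`` x class size swaps are attempted; a swap replaces
    (a->b, c->d) with (a->d, c->b) and is skipped when it would create a
    self-edge or a duplicate ordered pair.  Self-edges (autoregulation)
    are excluded from the pool and therefore preserved exactly, as are all
    per-type in/out degree sequences and role constraints.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes, by_class, self_edges = _indexed_edges(network)
    n = len(nodes)
    occupied = {u * n + u for u in self_edges}
    for edges in by_class.values():
        occupied.update(a * n + b for a, b in edges)
    swapped = _swap_core(by_class, n, n_swaps_factor, rng, occupied)

    out = MetaNetwork()
    for node_id, data in network.graph.nodes(data=True):
        out.add_node(node_id, data["roles"])
    etype_of = {"binds_mirna": "binds", "binds_tf": "binds", "silences": "silences"}
    for u in self_edges:
        out.add_edge(nodes[u], nodes[u], network.graph[nodes[u]][nodes[u]]["etype"])
    for cname, edges in swapped.items():
        for a, b in edges:
            out.add_edge(nodes[a], nodes[b], etype_of[cname])
    return out


def motif_enrichment(
    network: MetaNetwork,
    n_rand: int = 1000,
    seed: int | None = None,
    n_swaps_factor: float = 10.0,
) -> list[MotifEnrichment]:
    """Triad-class enrichment against an ensemble of rewired networks.

    empirical_p = (1 + #{null >= observed}) / (n_rand + 1); z-scores are
    flagged nan when the null is degenerate; Benjamini-Hochberg adjustment
    across the 13 classes.
    """
    if n_rand < 20:
        raise ValueError("n_rand must be >= 20 for a usable null")
    rng = np.random.default_rng(seed)
    observed = triad_census(network)
    nodes, by_class, self_edges = _indexed_edges(network)
    n = len(nodes)
    base_occupied = {u * n + u for u in self_edges}
    for edges in by_class.values():
        base_occupied.update(a * n + b for a, b in edges)
    conn_idx = [i for i, c in enumerate(_IGRAPH_ORDER) if c in TRIAD_CLASSES]
    null = np.zeros((n_rand, len(TRIAD_CLASSES)))
    for r in range(n_rand):
        swapped = _swap_core(
            by_class, n, n_swaps_factor, rng, set(base_occupied)
        )
        g = ig.Graph(
            n=n,
            edges=[e for edges in swapped.values() for e in edges],
            directed=True,
        )
        census = g.triad_census()
        null[r] = [census[i] for i in conn_idx]

    obs = np.array([observed[k] for k in TRIAD_CLASSES], dtype=float)
    mean = null.mean(axis=0)
    sd = null.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / sd, np.nan)
    emp_p = (1 + (null >= obs).sum(axis=0)) / (n_rand + 1)
    adj_p = multipletests(emp_p, method="fdr_bh")[1]
    return [
        MotifEnrichment(
            class_id=k,
            observed=int(obs[i]),
            null_mean=float(mean[i]),
            null_sd=float(sd[i]),
            z=float(z[i]),
            empirical_p=float(emp_p[i]),
            adjusted_p=float(adj_p[i]),
        )
        for i, k in enumerate(TRIAD_CLASSES)
    ]


def find_sims(network: MetaNetwork) -> list[SIMInstance]:
    """All single-input modules: a regulator with a pair of bound TF genes."""
    sims = []
    for r in sorted(network.nodes_with_role("regulator")):
        targets = sorted(
            t
            for t in network.successors(r, "binds")
            if t != r and network.roles(t) & {"tf_target", "regulator"}
        )
        for a, b in itertools.combinations(targets, 2):
            sims.append(SIMInstance(regulator=r, target_pair=frozenset((a, b))))
    return sims


@dataclass
class SimPpiResult:
    regulators: list[str]
    observed_pct: np.ndarray
    control_pct: np.ndarray  # per-regulator mean over iterations
    t_statistic: float
    p_value: float
    skipped: bool = False


def _pair_pct(targets: Sequence[str], ppi: set[frozenset]) -> float:
    n = len(targets)
    if n < 2:
        return 0.0
    hits = sum(
        1
        for a, b in itertools.combinations(targets, 2)
        if frozenset((a, b)) in ppi
    )
    return 100.0 * hits / (n * (n - 1) // 2)


def sim_ppi_enrichment(
    network: MetaNetwork,
    ppi: Iterable[frozenset],
    n_iter: int = 1000,
    seed: int | None = None,
    paired: bool = False,
) -> SimPpiResult:
    """Do regulators preferentially target physically interacting TF pairs?

    For each regulator, the observed value is the percentage of its SIM
    target pairs present in the PPI set; the control redraws same-size
    target samples from the union of all regulators' targets and averages
    the percentage over ``n_iter`` draws.  The two per-regulator vectors
    are compared with a two-tailed Student's t-test (two-sample by
    default; ``paired`` switches to a paired test).
    """
    ppi = set(ppi)
    rng = np.random.default_rng(seed)
    targets_by_reg = {
        r: sorted(
            t
            for t in network.successors(r, "binds")
            if t != r and network.roles(t) & {"tf_target", "regulator"}
        )
        for r in sorted(network.nodes_with_role("regulator"))
    }
    targets_by_reg = {r: t for r, t in targets_by_reg.items() if len(t) >= 2}
    if len(targets_by_reg) < 2:
        raise ValueError("need >= 2 regulators with >= 2 TF targets each")
    regs = list(targets_by_reg)
    pool = sorted(set().union(*targets_by_reg.values()))

    observed = np.array([_pair_pct(targets_by_reg[r], ppi) for r in regs])
    if not ppi:
        return SimPpiResult(
            regulators=regs,
            observed_pct=observed,
            control_pct=np.zeros_like(observed),
            t_statistic=float("nan"),
            p_value=float("nan"),
            skipped=True,
        )
    control = np.zeros(len(regs))
    pool_arr = np.array(pool)
    for i, r in enumerate(regs):
        k = len(targets_by_reg[r])
        acc = 0.0
        for _ in range(n_iter):
            sample = pool_arr[rng.choice(len(pool_arr), size=k, replace=False)]
            acc += _pair_pct(list(sample), ppi)
        control[i] = acc / n_iter
    if paired:
        t, p = stats.ttest_rel(observed, control)
    else:
        t, p = stats.ttest_ind(observed, control)
    return SimPpiResult(
        regulators=regs,
        observed_pct=observed,
        control_pct=control,
        t_statistic=float(t),
        p_value=float(p),
    )
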