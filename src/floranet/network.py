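"""The typed, directed meta-network of regulators, miRNA genes, and TF targets.

Nodes carry role flags from {regulator, miRNA, tf_target}; a master
regulator that is itself a differentially expressed TF target is a single
node holding both flags.  Edges are typed: ``binds`` (TF occupancy at a
target locus, from ChIP target assignments) or ``silences`` (miRNA-mediated
post-transcriptional repression, from a miRNA-target table).
"""

from __future__ import annotations

import warnings
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .targets import TargetAssignment

ROLES = ("regulator", "miRNA", "tf_target")
ETYPES = ("binds", "silences")


class MetaNetwork:
    """Directed typed graph wrapper around :class:`networkx.DiGraph`.

    At most one edge per (source, target, etype); since a node cannot be
    both a regulator and a miRNA, each ordered pair carries at most one
    edge and a plain DiGraph suffices.
    """

    def __init__(self) -> None:
        self.graph = nx.DiGraph()

    # -- construction ------------------------------------------------------

    def add_node(self, node_id: str, roles: Iterable[str]) -> None:
        roles = frozenset(roles)
        if not roles <= set(ROLES):
            raise ValueError(f"unknown roles {roles - set(ROLES)}")
        if "miRNA" in roles and len(roles) > 1:
            raise ValueError(f"{node_id}: miRNA role is exclusive")
        if node_id in self.graph:
            roles = roles | self.graph.nodes[node_id]["roles"]
        self.graph.add_node(node_id, roles=roles)

    def add_edge(
        self,
        source: str,
        target: str,
        etype: str,
        provenance: Mapping | None = None,
    ) -> None:
        if etype not in ETYPES:
            raise ValueError(f"unknown edge type {etype!r}")
        src_roles = self.roles(source)
        tgt_roles = self.roles(target)
        if etype == "binds" and "regulator" not in src_roles:
            raise ValueError(f"binds edge from non-regulator {source!r}")
        if etype == "silences":
            if "miRNA" not in src_roles:
                raise ValueError(f"silences edge from non-miRNA {source!r}")
            if not tgt_roles & {"tf_target", "regulator"}:
                raise ValueError(
                    f"silences edge must land on a TF gene, got {target!r}"
                )
        if self.graph.has_edge(source, target):
            data = self.graph[source][target]
            if data["etype"] != etype:
                raise ValueError(
                    f"conflicting edge types for {source}->{target}"
                )
            if provenance:
                data["provenance"].append(dict(provenance))
            return
        self.graph.add_edge(
            source,
            target,
            etype=etype,
            provenance=[dict(provenance)] if provenance else [],
        )

    # -- queries -----------------------------------------------------------

    def roles(self, node_id: str) -> frozenset:
        if node_id not in self.graph:
            raise KeyError(f"unknown node {node_id!r}")
        return self.graph.nodes[node_id]["roles"]

    def nodes_with_role(self, role: str) -> set[str]:
        return {n for n, d in self.graph.nodes(data=True) if role in d["roles"]}

    def edges_of_type(self, etype: str) -> list[tuple[str, str]]:
        return [
            (u, v)
            for u, v, d in self.graph.edges(data=True)
            if d["etype"] == etype
        ]

    def has_edge(self, source: str, target: str, etype: str | None = None) -> bool:
        if not self.graph.has_edge(source, target):
            return False
        return etype is None or self.graph[source][target]["etype"] == etype

    def successors(self, node_id: str, etype: str | None = None) -> set[str]:
        return {
            v
            for v in self.graph.successors(node_id)
            if etype is None or self.graph[node_id][v]["etype"] == etype
        }

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "MetaNetwork":
        out = MetaNetwork()
        out.graph = self.graph.copy()
        return out

    def without_etype(self, etype: str, drop_isolates: bool = False) -> "MetaNetwork":
        """A copy with all edges of the given type removed."""
        out = self.copy()
        out.graph.remove_edges_from(out.edges_of_type(etype))
        if drop_isolates:
            out.graph.remove_nodes_from(list(nx.isolates(out.graph)))
        return out

    def validate(self) -> None:
        """Assert all role/edge-type invariants; raises on violation."""
        for u, v, d in self.graph.edges(data=True):
            etype = d["etype"]
            if etype == "binds" and "regulator" not in self.roles(u):
                raise AssertionError(f"binds edge from non-regulator {u}")
            if etype == "silences":
                if "miRNA" not in self.roles(u):
                    raise AssertionError(f"silences edge from non-miRNA {u}")
                if not self.roles(v) & {"tf_target", "regulator"}:
                    raise AssertionError(f"silences edge to non-TF {v}")

    # -- serialization -----------------------------------------------------

    def to_edge_frame(self) -> pd.DataFrame:
        rows = []
        for u, v, d in sorted(self.graph.edges(data=True)):
            prov = d.get("provenance") or [{}]
            first = prov[0]
            rows.append(
                {
                    "source": u,
                    "target": v,
                    "etype": d["etype"],
                    "source_roles": ",".join(sorted(self.roles(u))),
                    "target_roles": ",".join(sorted(self.roles(v))),
                    "stage": first.get("stage", ""),
                    "score": first.get("score", ""),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "source", "target", "etype", "source_roles", "target_roles",
                "stage", "score",
            ],
        )

    @classmethod
    def from_edge_frame(cls, df: pd.DataFrame) -> "MetaNetwork":
        net = cls()
        for row in df.itertuples(index=False):
            net.add_node(row.source, row.source_roles.split(","))
            net.add_node(row.target, row.target_roles.split(","))
            prov = {}
            if getattr(row, "stage", ""):
                prov["stage"] = row.stage
            net.add_edge(row.source, row.target, row.etype, prov or None)
        return net


def build_meta_network(
    assignments: Iterable[TargetAssignment],
    mirna_targets: pd.DataFrame,
    regulators: set[str],
    expressed_mirnas: set[str],
    de_tf_genes: set[str],
    stage: str | None = None,
    keep_isolates: bool = False,
    strict: bool = False,
) -> MetaNetwork:
    """Assemble the meta-network from binding assignments and a miRNA table.

    ``binds`` edges are regulator -> {miRNA, DE TF gene, regulator}
    assignments restricted to the provided node sets; ``silences`` edges are
    miRNA -> TF-gene rows of ``mirna_targets`` (columns source, target)
    restricted likewise.  Edges with endpoints outside all role sets are
    dropped with a warning (or raise when ``strict``).  Nodes left without
    incident edges are dropped unless ``keep_isolates``.
    """
    if not (regulators and expressed_mirnas and de_tf_genes):
        raise ValueError("all three role sets must be non-empty")
    net = MetaNetwork()
    for r in sorted(regulators):
        net.add_node(r, {"regulator"})
        if r in de_tf_genes:
            net.add_node(r, {"tf_target"})
    for m in sorted(expressed_mirnas):
        net.add_node(m, {"miRNA"})
    for g in sorted(de_tf_genes - regulators):
        net.add_node(g, {"tf_target"})

    known = regulators | expressed_mirnas | de_tf_genes
    dropped = 0
    for a in assignments:
        if stage is not None and a.stage != stage:
            continue
        if a.tf not in regulators or a.gene_id not in known:
            dropped += 1
            if strict:
                raise ValueError(
                    f"assignment endpoint outside role sets: {a.tf}->{a.gene_id}"
                )
            continue
        net.add_edge(
            a.tf, a.gene_id, "binds", {"stage": a.stage, "score": a.score}
        )
    for row in mirna_targets.itertuples(index=False):
        src, tgt = row.source, row.target
        if src not in expressed_mirnas or tgt not in (de_tf_genes | regulators):
            dropped += 1
            if strict:
                raise ValueError(
                    f"miRNA-target endpoint outside role sets: {src}->{tgt}"
                )
            continue
        prov = {"source": getattr(row, "evidence", "predicted")}
        net.add_edge(src, tgt, "silences", prov)
    if dropped:
        warnings.warn(f"dropped {dropped} edges with unknown endpoints", stacklevel=2)
    if not keep_isolates:
        net.graph.remove_nodes_from(list(nx.isolates(net.graph)))
    net.validate()
    return net


def cross_regulation_matrix(
    network: MetaNetwork, regulators: Iterable[str]
) -> tuple[pd.DataFrame, pd.Series]:
    """Regulator x regulator binding matrix and the autoregulation diagonal.

    Entry (i, j) is True when a binds edge i -> j exists; the diagonal
    marks self-binding (autoregulation).
    """
    regulators = sorted(regulators)
    missing = [r for r in regulators if r not in network.graph]
    if missing:
        raise KeyError(f"regulators absent from network: {missing}")
    mat = pd.DataFrame(False, index=regulators, columns=regulators)
    for i in regulators:
        for j in regulators:
            if network.has_edge(i, j, "binds"):
                mat.loc[i, j] = True
    auto = pd.Series(np.diag(mat.values), index=regulators, name="autoregulation")
    return mat, auto
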