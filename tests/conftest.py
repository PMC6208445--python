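import networkx as nx
import numpy as np
import pytest

from floranet.network import MetaNetwork
from floranet.simulate import GeneratorConfig, generate_all


def wrap_digraph(g: nx.DiGraph) -> MetaNetwork:
    """Embed an arbitrary digraph as an all-regulator meta-network."""
    net = MetaNetwork()
    for n in g.nodes():
        net.add_node(f"n{n:03d}", {"regulator"})
    for u, v in g.edges():
        net.add_edge(f"n{u:03d}", f"n{v:03d}", "binds")
    return net


SMALL_SCALE = dict(
    n_regulators=15,
    n_mirnas=40,
    n_de_tfs=120,
    n_other_genes=300,
    edges_tf_mirna=110,
    edges_mirna_tf=70,
    edges_tf_tf=300,
    n_extra_binding=300,
    n_planted_ffls=15,
    autoregulation_count=11,
    # background in-degree is ~2.5 here, so a planted hub must sit well
    # beyond the binomial tail to be a hub at all
    n_hub_genes=4,
    hub_in_degree=9,
    domain_counts={
        "AP1_specific": 40,
        "AP3_specific": 25,
        "AG_specific": 40,
        "AP1_AP3_common": 30,
        "AP3_AG_common": 25,
    },
    n_null_domain_genes=100,
    regression_n_genes=200,
)


def small_config(seed: int = 0, **overrides) -> GeneratorConfig:
    params = {**SMALL_SCALE, **overrides}
    return GeneratorConfig(seed=seed, **params)


@pytest.fixture(scope="session")
def paper_scale_bundle():
    """One full synthetic study at the published network scale."""
    return generate_all(GeneratorConfig(seed=11))


@pytest.fixture(scope="session")
def small_bundle():
    """A proportionally scaled-down synthetic study for fast tests."""
    return generate_all(small_config(seed=2))


@pytest.fixture()
def sep3_network() -> MetaNetwork:
    """Hand-encoded SEP3 / MIR319a / TCP4 / TCP10 mini-circuit."""
    net = MetaNetwork()
    net.add_node("SEP3", {"regulator"})
    net.add_node("MIR319a", {"miRNA"})
    net.add_node("TCP4", {"tf_target"})
    net.add_node("TCP10", {"tf_target"})
    net.add_edge("SEP3", "MIR319a", "binds")
    net.add_edge("SEP3", "TCP4", "binds")
    net.add_edge("SEP3", "TCP10", "binds")
    net.add_edge("MIR319a", "TCP4", "silences")
    net.add_edge("MIR319a", "TCP10", "silences")
    return net
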