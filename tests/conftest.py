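import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mlcascade.netmodel import (
    InterdependencyMap,
    Layer,
    MultilayerNetwork,
    SupportMap,
)
from mlcascade.synth import ERBenchmarkSpec, generate_er_multilayer, toy_fixture

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def t1() -> MultilayerNetwork:
    return toy_fixture("T1")


@pytest.fixture
def t2() -> MultilayerNetwork:
    return toy_fixture("T2")


@pytest.fixture(scope="session")
def small_er() -> MultilayerNetwork:
    """A modest ER network for property checks (fast to cascade on)."""
    return generate_er_multilayer(
        ERBenchmarkSpec(n_g=200, n_p=200, n_m=50, c_g=2, c_p=6, c_m=4, c_s=3), seed=9
    )


def make_net(grn_edges, ppi_edges, met_edges, gp_pairs, pm_links,
             genes=(), prots=(), mets=()) -> MultilayerNetwork:
    """Assemble a small multilayer network from raw edge lists."""
    return MultilayerNetwork(
        grn=Layer.from_edges("grn", grn_edges, directed=True, nodes=genes),
        ppi=Layer.from_edges("ppi", ppi_edges, nodes=prots),
        met=Layer.from_edges("met", met_edges, nodes=mets),
        gp=InterdependencyMap(set(gp_pairs)),
        pm=SupportMap(set(pm_links)),
    )


def induced_subnetwork(net: MultilayerNetwork, genes, prots, mets) -> MultilayerNetwork:
    """The multilayer network induced on the given functional node sets."""
    genes, prots, mets = set(genes), set(prots), set(mets)
    return MultilayerNetwork(
        grn=Layer("grn", True, net.grn.graph.subgraph(genes).copy()),
        ppi=Layer("ppi", False, net.ppi.graph.subgraph(prots).copy()),
        met=Layer("met", False, net.met.graph.subgraph(mets).copy()),
        gp=InterdependencyMap({(g, p) for g, p in net.gp.pairs if g in genes and p in prots}),
        pm=SupportMap({(p, m) for p, m in net.pm.links if p in prots and m in mets}),
    )
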