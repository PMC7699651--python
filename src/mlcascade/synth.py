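"""Synthetic multilayer networks: ER benchmarks and hand-traceable fixtures.

``generate_er_multilayer`` builds the three-layer Erdos-Renyi benchmark used
to validate the analytical theory: a directed ER regulatory layer (in- and
out-degrees independently Poisson, matching the independence assumption of
the thinning step in :mod:`mlcascade.theory`), undirected ER protein and
metabolic layers, a random partial one-to-one gene<->protein matching with
coverage fractions ``q_G``/``q_P``, and Poisson-distributed many-to-many
protein->metabolite supports.

``toy_fixture`` returns two tiny fixed networks whose cascades can be traced
by hand; they anchor the exactness tests of the simulator.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from ._rng import rng_for
from .netmodel import InterdependencyMap, Layer, MultilayerNetwork, SupportMap

__all__ = [
    "ERBenchmarkSpec",
    "generate_er_multilayer",
    "toy_fixture",
    "generate_planted_positives",
    "generate_planted_disease_set",
]


@dataclass(frozen=True)
class ERBenchmarkSpec:
    """Parameters of the three-layer ER benchmark.

    Defaults are the canonical acceptance configuration: 5000 genes and
    proteins, 1000 metabolites, mean degrees c_G=2 (regulatory, in = out),
    c_P=8 (protein), c_M=4 (metabolic), coupling fractions q_G=q_P=0.8 and
    mean support degree c_s=3.
    """

    n_g: int = 5000
    n_p: int = 5000
    n_m: int = 1000
    c_g: float = 2.0
    c_p: float = 8.0
    c_m: float = 4.0
    q_g: float = 0.8
    q_p: float = 0.8
    c_s: float = 3.0

    def __post_init__(self):
        if min(self.n_g, self.n_p, self.n_m) < 1:
            raise ValueError("layer sizes must be >= 1")
        for name in ("q_g", "q_p"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if min(self.c_g, self.c_p, self.c_m, self.c_s) < 0:
            raise ValueError("mean degrees must be non-negative")


def generate_er_multilayer(spec: ERBenchmarkSpec | None = None, seed: int = 0) -> MultilayerNetwork:
    """Generate a three-layer ER benchmark network (reproducible per seed)."""
    spec = spec or ERBenchmarkSpec()
    rng = rng_for(seed, "synth.er")

    def int_seed(name: str) -> int:
        return int(rng_for(seed, name).integers(0, 2**31 - 1))

    grn_g = nx.fast_gnp_random_graph(
        spec.n_g, min(1.0, spec.c_g / spec.n_g), seed=int_seed("synth.grn"), directed=True
    )
    ppi_g = nx.fast_gnp_random_graph(
        spec.n_p, min(1.0, spec.c_p / spec.n_p), seed=int_seed("synth.ppi")
    )
    met_g = nx.fast_gnp_random_graph(
        spec.n_m, min(1.0, spec.c_m / spec.n_m), seed=int_seed("synth.met")
    )

    genes = [f"g{i}" for i in range(spec.n_g)]
    prots = [f"p{i}" for i in range(spec.n_p)]
    mets = [f"m{i}" for i in range(spec.n_m)]

    grn = Layer.from_edges(
        "grn", [(genes[u], genes[v]) for u, v in grn_g.edges], directed=True, nodes=genes
    )
    ppi = Layer.from_edges("ppi", [(prots[u], prots[v]) for u, v in ppi_g.edges], nodes=prots)
    met = Layer.from_edges("met", [(mets[u], mets[v]) for u, v in met_g.edges], nodes=mets)

    n_pairs = min(int(round(spec.q_g * spec.n_g)), int(round(spec.q_p * spec.n_p)))
    g_sel = rng.choice(spec.n_g, size=n_pairs, replace=False)
    p_sel = rng.choice(spec.n_p, size=n_pairs, replace=False)
    gp = InterdependencyMap({(genes[g], prots[p]) for g, p in zip(g_sel, p_sel)})

    links = set()
    k_s = rng.poisson(spec.c_s, size=spec.n_m)
    for m, k in enumerate(k_s):
        k = int(min(k, spec.n_p))
        if k:
            for p in rng.choice(spec.n_p, size=k, replace=False):
                links.add((prots[p], mets[m]))
    pm = SupportMap(links)

    return MultilayerNetwork(grn=grn, ppi=ppi, met=met, gp=gp, pm=pm)


def toy_fixture(name: str) -> MultilayerNetwork:
    """Tiny fixed fixtures.

    ``T1``
        4 genes, 5 proteins, 3 metabolites; every cascade on it can be traced
        by hand.
    ``T2``
        T1 plus a fifth gene paired to the previously unpaired protein and
        regulating g2, creating a genuine second-round failure chain
        (protein disconnection -> gene failure -> new regulatory failure).
    """
    if name not in ("T1", "T2"):
        raise ValueError(f"unknown fixture {name!r}")
    grn_edges = [("g1", "g2"), ("g1", "g3"), ("g4", "g3")]
    gene_nodes = ["g1", "g2", "g3", "g4"]
    gp_pairs = {("g1", "p1"), ("g2", "p2"), ("g3", "p3"), ("g4", "p4")}
    if name == "T2":
        grn_edges.append(("g5", "g2"))
        gene_nodes.append("g5")
        gp_pairs.add(("g5", "p5"))
    grn = Layer.from_edges("grn", grn_edges, directed=True, nodes=gene_nodes)
    ppi = Layer.from_edges(
        "ppi",
        [("p1", "p2"), ("p2", "p3"), ("p3", "p4"), ("p4", "p5"), ("p2", "p4")],
        nodes=[f"p{i}" for i in range(1, 6)],
    )
    met = Layer.from_edges("met", [("m1", "m2"), ("m2", "m3")], nodes=["m1", "m2", "m3"])
    pm = SupportMap({("p2", "m1"), ("p4", "m1"), ("p3", "m2"), ("p5", "m3")})
    return MultilayerNetwork(grn=grn, ppi=ppi, met=met, gp=InterdependencyMap(gp_pairs), pm=pm)


def generate_planted_positives(
    net: MultilayerNetwork, k: int, placement: str = "high_coupling", seed: int = 0
) -> set[str]:
    """A stand-in "important gene" set for prioritization tests.

    ``high_coupling`` plants the positives at the k eligible genes maximizing
    out-degree x paired-protein degree (the positions where the coupled
    process concentrates damage); ``random`` samples uniformly.
    """
    eligible = sorted(net.eligible_genes)
    if k > len(eligible):
        raise ValueError(f"k={k} exceeds the {len(eligible)} eligible genes")
    if placement == "random":
        rng = rng_for(seed, "synth.positives")
        return set(rng.choice(eligible, size=k, replace=False).tolist())
    if placement != "high_coupling":
        raise ValueError(f"unknown placement {placement!r}")
    g2p = net.gp.gene_to_protein()
    pdeg = net.ppi.degree()
    out_deg = dict(net.grn.graph.out_degree())
    score = {g: out_deg.get(g, 0) * pdeg.get(g2p[g], 0) for g in eligible}
    ranked = sorted(eligible, key=lambda g: (-score[g], g))
    return set(ranked[:k])


def generate_planted_disease_set(
    net: MultilayerNetwork, target_metabolites: set[str], seed: int = 0
) -> set[str]:
    """Genes whose paired proteins support the target metabolites -- a
    stand-in disease gene set whose perturbation is wired to damage a known
    part of the metabolic layer."""
    targets = set(target_metabolites)
    if not targets:
        return set()
    unknown = targets - net.met.nodes
    if unknown:
        raise ValueError(f"unknown metabolite(s): {sorted(unknown)[:5]}")
    p2g = net.gp.protein_to_gene()
    sup = net.pm.supports_of()
    genes = {p2g[p] for m in targets for p in sup.get(m, ()) if p in p2g}
    genes &= net.grn.nodes
    if not genes:
        raise ValueError("no paired genes support the target metabolites")
    return genes
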