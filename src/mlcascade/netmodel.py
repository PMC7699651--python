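"""Multilayer molecular-network data model, validation, degree statistics and I/O.

Layers
------
``grn``
    Directed transcription-factor -> target-gene regulation.
``ppi``
    Undirected physical protein-protein interactions.
``met``
    Undirected metabolite-metabolite associations.

Interlayer structure
--------------------
``gp``
    Partial one-to-one matching between protein-coding genes and their
    protein products.  These links are bidirectional interdependencies:
    failure of either endpoint fails the other.
``pm``
    Many-to-many protein -> metabolite support links.  A metabolite's
    support degree ``k_s`` counts the proteins sustaining its function.

File formats are deliberately plain: two-column whitespace/tab-separated
edge lists with ``#`` comments, optional one-column node lists for isolated
nodes, and a small YAML bundle naming the five files.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import yaml

log = logging.getLogger(__name__)

#: Prefixes applied per layer when raw node-id namespaces collide.
LAYER_PREFIX = {"grn": "G:", "ppi": "P:", "met": "M:"}


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class Layer:
    """One intra-layer graph.

    Undirected edges are stored canonically (unordered pairs); self-loops
    are dropped at construction and duplicate / reverse-duplicate edges
    collapse silently, both with logged counts.
    """

    name: str
    directed: bool
    graph: nx.Graph
    dropped_self_loops: int = 0
    collapsed_duplicates: int = 0

    @classmethod
    def from_edges(
        cls,
        name: str,
        edges: Iterable[tuple[str, str]],
        *,
        directed: bool = False,
        nodes: Iterable[str] = (),
    ) -> "Layer":
        g = nx.DiGraph() if directed else nx.Graph()
        g.add_nodes_from(str(n) for n in nodes)
        loops = dups = 0
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                loops += 1
                continue
            if g.has_edge(u, v):
                dups += 1
                continue
            g.add_edge(u, v)
        if loops:
            log.warning("%s: dropped %d self-loop(s)", name, loops)
        if dups:
            log.warning("%s: collapsed %d duplicate edge(s)", name, dups)
        return cls(name, directed, g, loops, dups)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[str, str]]:
        if self.directed:
            return [tuple(e) for e in self.graph.edges]
        return [tuple(sorted(e)) for e in self.graph.edges]

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def degree(self) -> dict[str, int]:
        """Total degree per node (in+out for the directed layer)."""
        return dict(self.graph.degree())

    def relabel(self, mapping: Mapping[str, str]) -> "Layer":
        return Layer(
            self.name,
            self.directed,
            nx.relabel_nodes(self.graph, dict(mapping), copy=True),
            self.dropped_self_loops,
            self.collapsed_duplicates,
        )

    def __len__(self) -> int:
        return self.graph.number_of_nodes()


@dataclass
class InterdependencyMap:
    """Bidirectional gene <-> protein interdependency links.

    A well-formed map is a partial one-to-one matching: each gene and each
    protein appears in at most one pair (checked by :func:`validate`).
    """

    pairs: set[tuple[str, str]] = field(default_factory=set)

    @property
    def genes(self) -> set[str]:
        return {g for g, _ in self.pairs}

    @property
    def proteins(self) -> set[str]:
        return {p for _, p in self.pairs}

    def gene_to_protein(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g, p in self.pairs:
            if g in out:
                raise ValueError(f"gene {g!r} appears in more than one interdependency pair")
            out[g] = p
        return out

    def protein_to_gene(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for g, p in self.pairs:
            if p in out:
                raise ValueError(f"protein {p!r} appears in more than one interdependency pair")
            out[p] = g
        return out

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class SupportMap:
    """Directed protein -> metabolite support links (many-to-many)."""

    links: set[tuple[str, str]] = field(default_factory=set)

    @property
    def proteins(self) -> set[str]:
        return {p for p, _ in self.links}

    @property
    def metabolites(self) -> set[str]:
        return {m for _, m in self.links}

    def supports_of(self) -> dict[str, set[str]]:
        """Metabolite -> set of supporting proteins."""
        out: dict[str, set[str]] = {}
        for p, m in self.links:
            out.setdefault(m, set()).add(p)
        return out

    def support_degree(self, metabolites: Iterable[str]) -> dict[str, int]:
        """k_s per metabolite, zero for metabolites with no supports."""
        sup = self.supports_of()
        return {m: len(sup.get(m, ())) for m in metabolites}

    def __len__(self) -> int:
        return len(self.links)


@dataclass
class MultilayerNetwork:
    """The three intra-layer graphs plus the two interlayer link maps.

    This is the single source of truth consumed by the simulator, the
    analytics and the analytical theory.
    """

    grn: Layer
    ppi: Layer
    met: Layer
    gp: InterdependencyMap
    pm: SupportMap

    @property
    def eligible_genes(self) -> set[str]:
        """Genes with a paired protein product (the perturbable set)."""
        return self.gp.genes & self.grn.nodes

    def validate(self) -> list[str]:
        return validate(self)


@dataclass
class DegreeDistributions:
    """Empirical degree pmfs: the inputs to every generating function.

    ``support`` includes metabolites with ``k_s = 0`` so that the fraction
    of uncoupled metabolites (``1 - q_Meta``) is recoverable from it.
    """

    grn_joint: dict[tuple[int, int], float]
    ppi: dict[int, float]
    met: dict[int, float]
    support: dict[int, float]

    def check(self, tol: float = 1e-12) -> None:
        for name, pmf in [
            ("grn_joint", self.grn_joint),
            ("ppi", self.ppi),
            ("met", self.met),
            ("support", self.support),
        ]:
            total = sum(pmf.values())
            if abs(total - 1.0) > tol:
                raise ValueError(f"{name} pmf sums to {total!r}, not 1")
            for k in pmf:
                ks = k if isinstance(k, tuple) else (k,)
                if any((not isinstance(x, (int,)) and not float(x).is_integer()) or x < 0 for x in ks):
                    raise ValueError(f"{name} pmf has non-integer or negative key {k!r}")


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------


def load_layer(
    path: str | Path,
    directed: bool,
    *,
    name: str | None = None,
    nodes_path: str | Path | None = None,
) -> Layer:
    """Read a 2+ column whitespace-separated edge list (``#`` comments allowed).

    Self-loops are dropped and duplicates collapsed, with logged counts.
    Raises ``FileNotFoundError`` for a missing file and ``ValueError`` with
    the offending line number for a malformed line.
    """
    path = Path(path)
    edges = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(parts)}")
            edges.append((parts[0], parts[1]))
    nodes: list[str] = []
    if nodes_path is not None:
        nodes = _read_node_list(nodes_path)
    return Layer.from_edges(name or path.stem, edges, directed=directed, nodes=nodes)


def _read_node_list(path: str | Path) -> list[str]:
    out = []
    with open(path) as fh:
        for raw in fh:
            line = raw.split("#", 1)[0].strip()
            if line:
                out.append(line.split()[0])
    return out


def _read_pairs(path: str | Path) -> list[tuple[str, str]]:
    out = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected >=2 columns, got {len(parts)}")
            out.append((parts[0], parts[1]))
    return out


def largest_component(layer: Layer, subset: set[str] | None = None) -> set[str]:
    """Union of all maximum-size connected components of the induced subgraph.

    When several components tie for the maximum size, the nodes of *all* of
    them are returned (inclusive tie rule: the functionality criterion never
    depends on arbitrary node ordering).  An empty subset yields an empty set.
    """
    if layer.directed:
        raise ValueError("largest_component is defined for undirected layers only")
    if subset is None:
        subset = layer.nodes
    else:
        extra = set(subset) - layer.nodes
        if extra:
            raise ValueError(f"subset contains nodes outside the layer: {sorted(extra)[:5]}")
    if not subset:
        return set()
    sub = layer.graph.subgraph(subset)
    comps = [set(c) for c in nx.connected_components(sub)]
    biggest = max(len(c) for c in comps)
    out: set[str] = set()
    for c in comps:
        if len(c) == biggest:
            out |= c
    return out


def degree_distributions(net: MultilayerNetwork) -> DegreeDistributions:
    """Empirical pmfs of the joint GRN (k_in, k_out), PPI/metabolic degree
    and metabolite support degree (including k_s = 0)."""
    for layer in (net.grn, net.ppi, net.met):
        if len(layer) == 0:
            raise ValueError(f"layer {layer.name!r} is empty")
    g = net.grn.graph
    joint = Counter((g.in_degree(n), g.out_degree(n)) for n in g.nodes)
    n_g = len(net.grn)
    ppi_c = Counter(d for _, d in net.ppi.graph.degree())
    met_c = Counter(d for _, d in net.met.graph.degree())
    sup_c = Counter(net.pm.support_degree(net.met.nodes).values())
    dd = DegreeDistributions(
        grn_joint={k: v / n_g for k, v in sorted(joint.items())},
        ppi={k: v / len(net.ppi) for k, v in sorted(ppi_c.items())},
        met={k: v / len(net.met) for k, v in sorted(met_c.items())},
        support={k: v / len(net.met) for k, v in sorted(sup_c.items())},
    )
    dd.check(tol=1e-9)
    return dd


def validate(net: MultilayerNetwork) -> list[str]:
    """Structural validation; an empty report means every invariant holds."""
    problems: list[str] = []
    for layer in (net.grn, net.ppi, net.met):
        loops = list(nx.selfloop_edges(layer.graph))
        if loops:
            problems.append(f"{layer.name}: {len(loops)} self-loop(s)")
    # namespace disjointness
    for a, b in [(net.grn, net.ppi), (net.grn, net.met), (net.ppi, net.met)]:
        shared = a.nodes & b.nodes
        if shared:
            problems.append(
                f"namespace collision between {a.name} and {b.name}: "
                f"{len(shared)} shared id(s), e.g. {sorted(shared)[0]!r}"
            )
    # gp: dangling endpoints + injectivity
    gene_seen: Counter = Counter(g for g, _ in net.gp.pairs)
    prot_seen: Counter = Counter(p for _, p in net.gp.pairs)
    for g, p in sorted(net.gp.pairs):
        if g not in net.grn.nodes:
            problems.append(f"gp: dangling endpoint {g!r} not in grn")
        if p not in net.ppi.nodes:
            problems.append(f"gp: dangling endpoint {p!r} not in ppi")
    for g, n in sorted(gene_seen.items()):
        if n > 1:
            problems.append(f"gp: non-injective matching, gene {g!r} in {n} pairs")
    for p, n in sorted(prot_seen.items()):
        if n > 1:
            problems.append(f"gp: non-injective matching, protein {p!r} in {n} pairs")
    # pm: dangling endpoints
    for p, m in sorted(net.pm.links):
        if p not in net.ppi.nodes:
            problems.append(f"pm: dangling endpoint {p!r} not in ppi")
        if m not in net.met.nodes:
            problems.append(f"pm: dangling endpoint {m!r} not in met")
    return problems


# ---------------------------------------------------------------------------
# bundle I/O
# ---------------------------------------------------------------------------


def load_network(
    bundle_path: str | Path,
    *,
    restrict_lcc: Sequence[str] = (),
) -> MultilayerNetwork:
    """Load a multilayer network from a YAML bundle.

    The bundle names the five files (layer edge lists, optional node lists,
    interdependency and support link lists)::

        grn: {edges: grn.tsv, nodes: grn_nodes.tsv}   # nodes optional
        ppi: ppi.tsv
        met: met.tsv
        gp: gp.tsv
        pm: pm.tsv
        prefix: auto          # auto | true | false

    Relative paths are resolved against the bundle's directory.  With
    ``prefix: auto`` (the default) layer-specific prefixes (``G:``, ``P:``,
    ``M:``) are applied only if the raw id namespaces collide.

    ``restrict_lcc`` optionally restricts the named *undirected* layers to
    their largest connected component before any analysis; the directed
    regulatory layer is never restricted.
    """
    bundle_path = Path(bundle_path)
    with open(bundle_path) as fh:
        cfg = yaml.safe_load(fh)
    base = bundle_path.parent

    def spec_of(key: str) -> tuple[Path, Path | None]:
        entry = cfg[key]
        if isinstance(entry, str):
            return base / entry, None
        nodes = entry.get("nodes")
        return base / entry["edges"], (base / nodes if nodes else None)

    directedness = {"grn": True, "ppi": False, "met": False}
    layers = {}
    for name in ("grn", "ppi", "met"):
        edges_path, nodes_path = spec_of(name)
        layers[name] = load_layer(
            edges_path, directedness[name], name=name, nodes_path=nodes_path
        )
    gp_pairs = _read_pairs(base / cfg["gp"])
    pm_links = _read_pairs(base / cfg["pm"])

    prefix = cfg.get("prefix", "auto")
    collide = (
        (layers["grn"].nodes & layers["ppi"].nodes)
        or (layers["grn"].nodes & layers["met"].nodes)
        or (layers["ppi"].nodes & layers["met"].nodes)
    )
    if prefix is True or (prefix == "auto" and collide):
        layers = {
            name: lay.relabel({n: LAYER_PREFIX[name] + n for n in lay.nodes})
            for name, lay in layers.items()
        }
        gp_pairs = [("G:" + g, "P:" + p) for g, p in gp_pairs]
        pm_links = [("P:" + p, "M:" + m) for p, m in pm_links]

    for name in restrict_lcc:
        if name not in ("ppi", "met"):
            raise ValueError(f"restrict_lcc applies to undirected layers only, got {name!r}")
        keep = largest_component(layers[name])
        layers[name] = Layer(
            name,
            False,
            layers[name].graph.subgraph(keep).copy(),
            layers[name].dropped_self_loops,
            layers[name].collapsed_duplicates,
        )
        gp_pairs = [(g, p) for g, p in gp_pairs if name != "ppi" or p in keep]
        pm_links = [
            (p, m)
            for p, m in pm_links
            if (name != "ppi" or p in keep) and (name != "met" or m in keep)
        ]

    net = MultilayerNetwork(
        grn=layers["grn"],
        ppi=layers["ppi"],
        met=layers["met"],
        gp=InterdependencyMap(set(gp_pairs)),
        pm=SupportMap(set(pm_links)),
    )
    return net


def write_network(net: MultilayerNetwork, outdir: str | Path, bundle_name: str = "bundle.yaml") -> Path:
    """Write the five TSV files plus node lists and a YAML bundle; returns
    the bundle path.  ``write_network`` then :func:`load_network` round-trips
    node and edge sets exactly."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for layer in (net.grn, net.ppi, net.met):
        with open(outdir / f"{layer.name}.tsv", "w") as fh:
            for u, v in sorted(layer.edges):
                fh.write(f"{u}\t{v}\n")
        with open(outdir / f"{layer.name}_nodes.tsv", "w") as fh:
            for n in sorted(layer.nodes):
                fh.write(f"{n}\n")
    with open(outdir / "gp.tsv", "w") as fh:
        for g, p in sorted(net.gp.pairs):
            fh.write(f"{g}\t{p}\n")
    with open(outdir / "pm.tsv", "w") as fh:
        for p, m in sorted(net.pm.links):
            fh.write(f"{p}\t{m}\n")
    bundle = {
        "grn": {"edges": "grn.tsv", "nodes": "grn_nodes.tsv"},
        "ppi": {"edges": "ppi.tsv", "nodes": "ppi_nodes.tsv"},
        "met": {"edges": "met.tsv", "nodes": "met_nodes.tsv"},
        "gp": "gp.tsv",
        "pm": "pm.tsv",
        "prefix": "auto",
    }
    bundle_path = outdir / bundle_name
    with open(bundle_path, "w") as fh:
        yaml.safe_dump(bundle, fh, sort_keys=False)
    return bundle_path
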