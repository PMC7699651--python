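"""The coupled cascading-failure simulator and its controls.

A perturbation removes a set of target genes (or a random ``1 - p``
fraction) from the regulatory layer.  One cascade round then consists of:

(i)   **GRN step** -- the targets regulated by the newly failed genes become
      dysfunctional (all of them, or an independent Bernoulli(``f``) subset
      per failing gene when ``f < 1``); genes left with zero remaining
      in+out degree fail as regulatory isolates (see ``isolate_rule``);
(ii)  proteins paired to the newly failed genes fail;
(iii) **PPI step** -- proteins disconnected from the largest connected
      component(s) of the surviving interactome fail;
(iv)  genes paired to the newly failed proteins fail, and seed the next
      round.

Rounds repeat until no new failure occurs.  Metabolites are then updated
once (they exert no feedback): a metabolite with ``k_s > 0`` supports fails
when its failed supports reach ``ceil(f_P2M * k_s)``, and surviving
metabolites outside the largest component(s) of the metabolic layer fail.

Two isolate policies are available.  ``"initial"`` (default) applies the
regulatory-isolation rule only in the first round, reading isolation as a
consequence of the initial loss of regulatory context; ``"per_round"``
re-applies it after every round, which is the process the analytical
recursion of :mod:`mlcascade.theory` describes.  Both policies agree
whenever the cascade terminates in one round.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from ._rng import rng_for
from .netmodel import Layer, MultilayerNetwork, largest_component

__all__ = [
    "PerturbationConfig",
    "CascadeResult",
    "RobustnessCurve",
    "CascadeSimulator",
    "run_cascade",
    "run_uncoupled",
    "run_merged",
    "robustness_curve",
]


# ---------------------------------------------------------------------------
# configuration and results
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PerturbationConfig:
    """Full parameterization of one perturbation experiment.

    Exactly one of ``seeds`` (explicit gene ids) and ``remove_fraction``
    (the random ``1 - p`` removal fraction) must be given.
    """

    seeds: frozenset | None = None
    remove_fraction: float | None = None
    f_p2m: float = 1.0
    mode: str = "coupled"  # coupled | uncoupled | merged
    grn_propagation: str = "one_hop"  # one_hop | recursive
    isolate_rule: str = "initial"  # initial | per_round
    target_failure_fraction: float = 1.0
    coupling_retention: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if (self.seeds is None) == (self.remove_fraction is None):
            raise ValueError("give exactly one of seeds / remove_fraction")
        if self.remove_fraction is not None and not 0.0 <= self.remove_fraction <= 1.0:
            raise ValueError("remove_fraction must lie in [0, 1]")
        if not 0.0 <= self.f_p2m <= 1.0:
            raise ValueError("f_p2m must lie in [0, 1]")
        if not 0.0 < self.target_failure_fraction <= 1.0:
            raise ValueError("target_failure_fraction must lie in (0, 1]")
        if not 0.0 <= self.coupling_retention <= 1.0:
            raise ValueError("coupling_retention must lie in [0, 1]")
        if self.mode not in ("coupled", "uncoupled", "merged"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.grn_propagation not in ("one_hop", "recursive"):
            raise ValueError(f"unknown grn_propagation {self.grn_propagation!r}")
        if self.isolate_rule not in ("initial", "per_round"):
            raise ValueError(f"unknown isolate_rule {self.isolate_rule!r}")
        if self.seeds is not None:
            object.__setattr__(self, "seeds", frozenset(self.seeds))


@dataclass
class CascadeResult:
    """Per-round newly failed node sets and final functional fractions."""

    rounds: list[dict[str, list[str]]]
    functional_genes: frozenset
    functional_proteins: frozenset
    functional_metabolites: frozenset
    f_s_gene: float
    f_s_ppi: float
    f_s_met: float

    @property
    def n_rounds(self) -> int:
        return max(1, len(self.rounds))

    def failed_in_round(self, t: int) -> dict[str, list[str]]:
        """Failures of round ``t`` (1-based); empty sets beyond the last round."""
        if 1 <= t <= len(self.rounds):
            return self.rounds[t - 1]
        return {"genes": [], "proteins": [], "metabolites": []}

    def second_round_size(self) -> int:
        r = self.failed_in_round(2)
        return len(r["genes"]) + len(r["proteins"])

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "f_s_gene": self.f_s_gene,
            "f_s_ppi": self.f_s_ppi,
            "f_s_met": self.f_s_met,
            "n_rounds": self.n_rounds,
        }


@dataclass
class RobustnessCurve:
    """Mean functional fractions per layer over a grid of surviving
    fractions ``p``, with Monte-Carlo standard errors and the robustness
    integral ``R = int_0^1 f_S dp`` per layer (trapezoidal on the grid)."""

    p: np.ndarray
    mean: dict[str, np.ndarray]
    se: dict[str, np.ndarray]
    replicates: int
    r_integral: dict[str, float]

    LAYERS = ("gene", "ppi", "met")

    def to_frame(self):
        import pandas as pd

        data = {"p": self.p}
        for lay in self.LAYERS:
            data[f"f_s_{lay}"] = self.mean[lay]
            data[f"se_{lay}"] = self.se[lay]
        return pd.DataFrame(data)


# ---------------------------------------------------------------------------
# simulator
# ---------------------------------------------------------------------------


def _symmetric_csr(n: int, rows: np.ndarray, cols: np.ndarray) -> csr_matrix:
    r = np.concatenate([rows, cols])
    c = np.concatenate([cols, rows])
    m = csr_matrix((np.ones(r.size, dtype=np.int8), (r, c)), shape=(n, n))
    m.data[:] = 1  # collapse duplicate entries summed by the constructor
    return m


class CascadeSimulator:
    """Reusable index structures for repeated cascades on one network.

    Building the simulator once and calling :meth:`run` per perturbation is
    the fast path used by influence scoring and robustness curves.
    """

    def __init__(self, net: MultilayerNetwork):
        self.net = net
        self.genes = sorted(net.grn.nodes)
        self.prots = sorted(net.ppi.nodes)
        self.mets = sorted(net.met.nodes)
        self._gidx = {g: i for i, g in enumerate(self.genes)}
        self._pidx = {p: i for i, p in enumerate(self.prots)}
        self._midx = {m: i for i, m in enumerate(self.mets)}
        nG, nP, nM = len(self.genes), len(self.prots), len(self.mets)

        ge = np.array(
            [(self._gidx[u], self._gidx[v]) for u, v in net.grn.graph.edges], dtype=np.int64
        ).reshape(-1, 2)
        self.grn_out = csr_matrix(
            (np.ones(ge.shape[0], dtype=np.int8), (ge[:, 0], ge[:, 1])), shape=(nG, nG)
        )
        self.grn_und = _symmetric_csr(nG, ge[:, 0], ge[:, 1])

        pe = np.array(
            [(self._pidx[u], self._pidx[v]) for u, v in net.ppi.graph.edges], dtype=np.int64
        ).reshape(-1, 2)
        self.ppi_adj = _symmetric_csr(nP, pe[:, 0], pe[:, 1])

        me = np.array(
            [(self._midx[u], self._midx[v]) for u, v in net.met.graph.edges], dtype=np.int64
        ).reshape(-1, 2)
        self.met_adj = _symmetric_csr(nM, me[:, 0], me[:, 1])

        self.pair_p_of_g = np.full(nG, -1, dtype=np.int64)
        self.pair_g_of_p = np.full(nP, -1, dtype=np.int64)
        for g, p in net.gp.gene_to_protein().items():
            if g in self._gidx and p in self._pidx:
                self.pair_p_of_g[self._gidx[g]] = self._pidx[p]
                self.pair_g_of_p[self._pidx[p]] = self._gidx[g]

        se = np.array(
            [(self._midx[m], self._pidx[p]) for p, m in net.pm.links
             if m in self._midx and p in self._pidx],
            dtype=np.int64,
        ).reshape(-1, 2)
        self.support = csr_matrix(
            (np.ones(se.shape[0], dtype=np.int8), (se[:, 0], se[:, 1])), shape=(nM, nP)
        )
        self.k_s = np.asarray(self.support.sum(axis=1)).ravel()

    # -- helpers ----------------------------------------------------------

    def _out_edges(self, rows: np.ndarray) -> np.ndarray:
        """Target indices of all out-edges of ``rows`` (with multiplicity)."""
        return self.grn_out[rows].indices

    def _isolated(self, alive: np.ndarray) -> np.ndarray:
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            return idx
        sub = self.grn_und[idx][:, idx]
        return idx[np.diff(sub.indptr) == 0]

    @staticmethod
    def _non_lcc(adj: csr_matrix, alive: np.ndarray) -> np.ndarray:
        """Indices of alive nodes outside the maximum-size component(s)."""
        idx = np.flatnonzero(alive)
        if idx.size == 0:
            return idx
        sub = adj[idx][:, idx]
        _, labels = connected_components(sub, directed=False)
        sizes = np.bincount(labels)
        return idx[sizes[labels] < sizes.max()]

    def _resolve_seeds(self, cfg: PerturbationConfig, rng) -> np.ndarray:
        nG = len(self.genes)
        if cfg.seeds is not None:
            unknown = [s for s in cfg.seeds if s not in self._gidx]
            if unknown:
                raise KeyError(f"unknown seed gene(s): {sorted(unknown)[:5]}")
            return np.array(sorted(self._gidx[s] for s in cfg.seeds), dtype=np.int64)
        k = int(round(cfg.remove_fraction * nG))
        return np.sort(rng.choice(nG, size=k, replace=False))

    # -- main entry -------------------------------------------------------

    def run(self, cfg: PerturbationConfig) -> CascadeResult:
        if cfg.mode == "uncoupled":
            return self._run_uncoupled_mode(cfg)
        if cfg.mode == "merged":
            return self._run_merged_mode(cfg)
        return self._run_coupled(cfg)

    def _run_coupled(self, cfg: PerturbationConfig) -> CascadeResult:
        rng = rng_for(cfg.seed, "cascade")
        nG, nP, nM = len(self.genes), len(self.prots), len(self.mets)
        g_alive = np.ones(nG, dtype=bool)
        p_alive = np.ones(nP, dtype=bool)
        m_alive = np.ones(nM, dtype=bool)

        seed_idx = self._resolve_seeds(cfg, rng)

        # interdependency dilution: a 1-r fraction of pairs is severed before
        # the run; the perturbed genes always transmit to their own protein.
        blocked_g = np.zeros(nG, dtype=bool)
        if cfg.coupling_retention < 1.0:
            paired = np.flatnonzero(self.pair_p_of_g >= 0)
            n_sever = int(round((1.0 - cfg.coupling_retention) * paired.size))
            if n_sever:
                blocked_g[rng.choice(paired, size=n_sever, replace=False)] = True

        rounds: list[dict[str, list[str]]] = []
        propagators = np.empty(0, dtype=np.int64)
        t = 0
        while True:
            t += 1
            new_genes: list[np.ndarray] = []
            transmitting: list[np.ndarray] = []
            if t == 1:
                s = seed_idx[g_alive[seed_idx]]
                g_alive[s] = False
                new_genes.append(s)
                transmitting.append(s)  # seeds always transmit to their protein
                frontier = s
            else:
                frontier = propagators

            # (i) regulatory one-hop (or recursive) target failure
            while frontier.size:
                tg = self._out_edges(frontier)
                if cfg.target_failure_fraction < 1.0 and tg.size:
                    tg = tg[rng.random(tg.size) < cfg.target_failure_fraction]
                tg = np.unique(tg)
                tg = tg[g_alive[tg]]
                g_alive[tg] = False
                new_genes.append(tg)
                frontier = tg if cfg.grn_propagation == "recursive" else np.empty(0, dtype=np.int64)

            if cfg.isolate_rule == "per_round" or t == 1:
                iso = self._isolated(g_alive)
                g_alive[iso] = False
                new_genes.append(iso)

            gene_new = np.concatenate(new_genes) if new_genes else np.empty(0, dtype=np.int64)
            non_seed = gene_new if t > 1 else np.setdiff1d(gene_new, seed_idx, assume_unique=False)
            transmitting.append(non_seed[~blocked_g[non_seed]])
            trans = np.concatenate(transmitting)

            # (ii) interdependent protein loss
            pnew = self.pair_p_of_g[trans]
            pnew = pnew[pnew >= 0]
            pnew = pnew[p_alive[pnew]]
            p_alive[pnew] = False

            # (iii) PPI largest-component rule
            lcc_fail = np.empty(0, dtype=np.int64)
            if pnew.size or t == 1:
                lcc_fail = self._non_lcc(self.ppi_adj, p_alive)
                p_alive[lcc_fail] = False
            prot_new = np.concatenate([pnew, lcc_fail])

            # (iv) feedback to the regulatory layer
            fb = self.pair_g_of_p[prot_new]
            fb = fb[fb >= 0]
            fb = fb[g_alive[fb] & ~blocked_g[fb]]
            g_alive[fb] = False
            gene_round = np.concatenate([gene_new, fb])

            n_new = gene_round.size + prot_new.size
            if n_new or t == 1:
                rounds.append(
                    {
                        "genes": [self.genes[i] for i in np.sort(gene_round)],
                        "proteins": [self.prots[i] for i in np.sort(prot_new)],
                        "metabolites": [],
                    }
                )
            propagators = fb
            if n_new == 0:
                break

        # metabolic update (no feedback: applied once after convergence)
        if nM:
            failed_support = self.support.dot((~p_alive).astype(np.float64))
            thresh = np.ceil(cfg.f_p2m * self.k_s)
            sup_fail = (self.k_s > 0) & (failed_support >= thresh) & m_alive
            m_alive[sup_fail] = False
            mlcc = self._non_lcc(self.met_adj, m_alive)
            m_alive[mlcc] = False
            met_failed = np.sort(np.concatenate([np.flatnonzero(sup_fail), mlcc]))
            rounds[-1]["metabolites"] = [self.mets[i] for i in met_failed]

        return self._result(rounds, g_alive, p_alive, m_alive)

    def _result(self, rounds, g_alive, p_alive, m_alive) -> CascadeResult:
        # trim trailing all-empty rounds (keep at least one)
        while len(rounds) > 1 and not any(rounds[-1].values()):
            rounds.pop()
        fg = frozenset(self.genes[i] for i in np.flatnonzero(g_alive))
        fp = frozenset(self.prots[i] for i in np.flatnonzero(p_alive))
        fm = frozenset(self.mets[i] for i in np.flatnonzero(m_alive))
        return CascadeResult(
            rounds=rounds,
            functional_genes=fg,
            functional_proteins=fp,
            functional_metabolites=fm,
            f_s_gene=len(fg) / max(1, len(self.genes)),
            f_s_ppi=len(fp) / max(1, len(self.prots)),
            f_s_met=len(fm) / max(1, len(self.mets)) if self.mets else 1.0,
        )

    # -- control processes -------------------------------------------------

    def _run_uncoupled_mode(self, cfg: PerturbationConfig) -> CascadeResult:
        """Remove the perturbed genes' proteins from the isolated PPI directly."""
        rng = rng_for(cfg.seed, "cascade")
        nG, nP, nM = len(self.genes), len(self.prots), len(self.mets)
        seed_idx = self._resolve_seeds(cfg, rng)
        g_alive = np.ones(nG, dtype=bool)
        g_alive[seed_idx] = False
        p_alive = np.ones(nP, dtype=bool)
        removed = self.pair_p_of_g[seed_idx]
        removed = removed[removed >= 0]
        p_alive[removed] = False
        lcc_fail = self._non_lcc(self.ppi_adj, p_alive)
        p_alive[lcc_fail] = False
        m_alive = np.ones(nM, dtype=bool)
        rounds = [
            {
                "genes": [self.genes[i] for i in seed_idx],
                "proteins": [self.prots[i] for i in np.sort(np.concatenate([removed, lcc_fail]))],
                "metabolites": [],
            }
        ]
        if nM:
            failed_support = self.support.dot((~p_alive).astype(np.float64))
            thresh = np.ceil(cfg.f_p2m * self.k_s)
            sup_fail = (self.k_s > 0) & (failed_support >= thresh)
            m_alive[sup_fail] = False
            mlcc = self._non_lcc(self.met_adj, m_alive)
            m_alive[mlcc] = False
            rounds[-1]["metabolites"] = [
                self.mets[i] for i in np.sort(np.concatenate([np.flatnonzero(sup_fail), mlcc]))
            ]
        return self._result(rounds, g_alive, p_alive, m_alive)

    def _run_merged_mode(self, cfg: PerturbationConfig) -> CascadeResult:
        rng = rng_for(cfg.seed, "cascade")
        seed_idx = self._resolve_seeds(cfg, rng)
        seeds = {self.genes[i] for i in seed_idx}
        frac = run_merged(self.net, seeds)
        nG = len(self.genes)
        g_alive = np.ones(nG, dtype=bool)
        g_alive[seed_idx] = False
        rounds = [{"genes": sorted(seeds), "proteins": [], "metabolites": []}]
        res = self._result(rounds, g_alive, np.ones(len(self.prots), bool), np.ones(len(self.mets), bool))
        res.f_s_ppi = frac  # merged functional fraction is reported on the PPI slot
        return res


# ---------------------------------------------------------------------------
# module-level operations
# ---------------------------------------------------------------------------


def run_cascade(net: MultilayerNetwork, cfg: PerturbationConfig) -> CascadeResult:
    """Run one perturbation experiment on ``net`` (see module docstring)."""
    return CascadeSimulator(net).run(cfg)


def run_uncoupled(ppi: Layer, removed_proteins: Iterable[str]) -> float:
    """Functional PPI fraction after deleting ``removed_proteins`` from the
    isolated interactome (largest-component rule, inclusive ties)."""
    removed = set(removed_proteins)
    unknown = removed - ppi.nodes
    if unknown:
        raise KeyError(f"unknown protein(s): {sorted(unknown)[:5]}")
    surviving = ppi.nodes - removed
    if not surviving:
        return 0.0
    keep = largest_component(ppi, surviving)
    return len(keep) / len(ppi.nodes)


def merged_graph(net: MultilayerNetwork) -> nx.Graph:
    """Undirected union of GRN and PPI edges with each gene-protein pair
    contracted into a single node (labelled by the gene id)."""
    alias: dict[str, str] = {}
    for g, p in net.gp.pairs:
        alias[p] = g
    m = nx.Graph()
    m.add_nodes_from(net.grn.nodes)
    m.add_nodes_from(alias.get(p, p) for p in net.ppi.nodes)
    for u, v in net.grn.graph.edges:
        if u != v:
            m.add_edge(u, v)
    for u, v in net.ppi.graph.edges:
        cu, cv = alias.get(u, u), alias.get(v, v)
        if cu != cv:
            m.add_edge(cu, cv)
    return m


def run_merged(net: MultilayerNetwork, seeds: Iterable[str]) -> float:
    """Largest-component fraction of the merged GRN+PPI graph after deleting
    the seed nodes (the merged-network control of the coupled process)."""
    m = merged_graph(net)
    seeds = set(seeds)
    unknown = seeds - set(m.nodes)
    if unknown:
        raise KeyError(f"unknown seed(s): {sorted(unknown)[:5]}")
    surviving = set(m.nodes) - seeds
    if not surviving:
        return 0.0
    layer = Layer("merged", False, m)
    keep = largest_component(layer, surviving)
    return len(keep) / m.number_of_nodes()


def robustness_curve(
    net: MultilayerNetwork,
    p_grid: Sequence[float],
    replicates: int = 30,
    f_p2m: float = 1.0,
    seed: int | None = None,
    *,
    isolate_rule: str = "initial",
    simulator: CascadeSimulator | None = None,
) -> RobustnessCurve:
    """Mean functional fractions per layer after random removal of a
    ``1 - p`` gene fraction, averaged over independent replicates."""
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    p_grid = np.asarray(sorted(p_grid), dtype=float)
    if p_grid.min() < 0 or p_grid.max() > 1:
        raise ValueError("p grid must lie within [0, 1]")
    sim = simulator or CascadeSimulator(net)
    acc = {lay: np.zeros((p_grid.size, replicates)) for lay in RobustnessCurve.LAYERS}
    for i, p in enumerate(p_grid):
        for r in range(replicates):
            cfg = PerturbationConfig(
                remove_fraction=1.0 - float(p),
                f_p2m=f_p2m,
                isolate_rule=isolate_rule,
                seed=None if seed is None else (seed * 100_003 + i * 1_009 + r) % (2**31 - 1),
            )
            res = sim.run(cfg)
            acc["gene"][i, r] = res.f_s_gene
            acc["ppi"][i, r] = res.f_s_ppi
            acc["met"][i, r] = res.f_s_met
    mean = {lay: acc[lay].mean(axis=1) for lay in acc}
    se = {
        lay: acc[lay].std(axis=1, ddof=1) / np.sqrt(replicates) if replicates > 1
        else np.zeros(p_grid.size)
        for lay in acc
    }
    r_int = {lay: float(np.trapezoid(mean[lay], p_grid)) for lay in acc}
    return RobustnessCurve(p=p_grid, mean=mean, se=se, replicates=replicates, r_integral=r_int)
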