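"""Analytical percolation framework for the multilayer cascade.

The theory predicts the final functional fraction of each layer from degree
distributions alone, using configuration-model generating functions:

* a joint in/out-degree calculation for the regulatory layer -- a gene
  survives the initial perturbation only if neither it nor any of its
  regulators is removed (survival probability ``p**(k_in+1)``), after which
  regulatory isolates are non-functional;
* site percolation with generating functions ``G(x)`` / ``H(x)`` for the
  largest-component rule in the PPI and metabolic layers;
* a fixed-point recursion over the mutual gene<->protein dependency with
  equivalent coupling strengths ``q_G`` (genes depending on proteins) and
  ``q_P`` (proteins depending on genes);
* a binomial support-failure stage for metabolites with threshold
  ``ceil(f_P2M * k_s)`` and coupling strength ``q_Meta`` (fraction of
  metabolites with at least one support).

All quantities are fractions in [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .netmodel import DegreeDistributions, MultilayerNetwork, degree_distributions

__all__ = [
    "GeneratingFunction",
    "CouplingStrengths",
    "TheoryResult",
    "r_s",
    "remaining_joint",
    "f_s_gene",
    "h_gene",
    "giant_fraction",
    "cascade_theory",
    "metabolic_theory",
    "coupling_strengths",
    "theory_curve",
    "theory_vs_sim",
]


# ---------------------------------------------------------------------------
# generating functions
# ---------------------------------------------------------------------------


class GeneratingFunction:
    """Probability generating function of a degree pmf.

    ``G(x) = sum_k p_k x^k`` and the excess-degree (branching) function
    ``H(x) = G'(x) / G'(1)``.  Keys must be non-negative integers and the
    pmf must sum to 1 within 1e-12 (tiny float slack is renormalized).
    """

    def __init__(self, pmf: Mapping[int, float]):
        if not pmf:
            raise ValueError("empty pmf")
        kmax = 0
        for k, v in pmf.items():
            if k < 0 or int(k) != k:
                raise ValueError(f"degree keys must be non-negative integers, got {k!r}")
            if v < 0:
                raise ValueError("negative probability")
            kmax = max(kmax, int(k))
        self.p = np.zeros(kmax + 1)
        for k, v in pmf.items():
            self.p[int(k)] += v
        total = self.p.sum()
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"pmf sums to {total!r}, not 1")
        self.p /= total
        self._dcoef = self.p[1:] * np.arange(1, self.p.size) if self.p.size > 1 else np.zeros(0)

    @property
    def mean(self) -> float:
        return float(self._dcoef.sum())

    def __call__(self, x):
        return np.polynomial.polynomial.polyval(x, self.p)

    def deriv(self, x):
        if self._dcoef.size == 0:
            return np.zeros_like(np.asarray(x, dtype=float))
        return np.polynomial.polynomial.polyval(x, self._dcoef)

    def branching(self, x):
        """H(x) = G'(x)/G'(1); undefined (raises) for a zero-mean pmf."""
        m = self.mean
        if m == 0:
            raise ZeroDivisionError("branching function undefined: mean degree is 0")
        return self.deriv(x) / m

    @classmethod
    def from_degrees(cls, degrees: Sequence[int]) -> "GeneratingFunction":
        ks, counts = np.unique(np.asarray(degrees, dtype=int), return_counts=True)
        return cls(dict(zip(ks.tolist(), (counts / counts.sum()).tolist())))


def giant_fraction(gf: GeneratingFunction, p: float, tol: float = 1e-12, max_iter: int = 100_000) -> float:
    """Probability that an occupied node is in the giant component under
    site percolation with occupation probability ``p``:
    ``h(p) = 1 - G(p*x_c + 1 - p)`` with ``x_c = H(p*x_c + 1 - p)``.

    The fixed point is iterated from 0, which converges monotonically to the
    smallest root (``x = 1`` is always a root and corresponds to no giant
    component); a bisection polish guards slow convergence near criticality.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must lie in [0, 1]")
    if p == 0.0 or gf.mean == 0.0:
        return 0.0
    # no giant component unless the expected branching factor p*H'(1) exceeds 1
    second = float((gf._dcoef[1:] * np.arange(1, gf._dcoef.size)).sum()) if gf._dcoef.size > 1 else 0.0
    if p * second / gf.mean <= 1.0:
        return 0.0
    x = 0.0
    for _ in range(max_iter):
        x_new = float(gf.branching(p * x + 1.0 - p))
        if abs(x_new - x) < tol:
            x = x_new
            break
        x = x_new
    else:
        # Slow (near-critical) convergence: bisect f(x) = x - H(px + 1 - p),
        # which is <= 0 below the smallest root and > 0 between that root and
        # 1 in the supercritical regime.
        def f(y: float) -> float:
            return y - float(gf.branching(p * y + 1.0 - p))

        hi = 1.0 - 1e-9
        if f(hi) > 0:
            x = float(optimize.brentq(f, x, hi, xtol=tol))
        else:  # subcritical or critical: the only root is x = 1, giant part 0
            x = 1.0
    residual = abs(x - float(gf.branching(p * x + 1.0 - p)))
    if residual > 1e-9:
        raise RuntimeError(f"giant-component fixed point did not converge (residual {residual:.2e})")
    return float(1.0 - gf(p * x + 1.0 - p))


# ---------------------------------------------------------------------------
# regulatory layer (joint in/out degrees)
# ---------------------------------------------------------------------------


def _joint_array(joint: Mapping[tuple[int, int], float] | np.ndarray) -> np.ndarray:
    if isinstance(joint, np.ndarray):
        arr = joint
    else:
        ki = max(k for k, _ in joint) if joint else 0
        ko = max(k for _, k in joint) if joint else 0
        arr = np.zeros((ki + 1, ko + 1))
        for (i, j), v in joint.items():
            arr[i, j] = v
    total = arr.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"joint pmf sums to {total!r}, not 1")
    return arr / total


def r_s(p: float, grn_joint) -> float:
    """Remaining gene fraction after removing a random ``1-p`` fraction and
    the targets they regulate: ``sum_{kin,kout} P(kin,kout) p^(kin+1)``."""
    arr = _joint_array(grn_joint)
    p_in = arr.sum(axis=1)
    return float(p * np.polynomial.polynomial.polyval(p, p_in))


def remaining_joint(grn_joint, r: float) -> dict[tuple[int, int], float]:
    """Joint degree pmf of the remaining regulatory network: independent
    binomial thinning of both margins at retention rate ``r``."""
    if not 0.0 <= r <= 1.0:
        raise ValueError("retention rate must lie in [0, 1]")
    arr = _joint_array(grn_joint)
    ni, nj = arr.shape
    b_in = np.array([[stats.binom.pmf(k, i, r) for i in range(ni)] for k in range(ni)])
    b_out = np.array([[stats.binom.pmf(k, j, r) for j in range(nj)] for k in range(nj)])
    thinned = b_in @ arr @ b_out.T
    out = {}
    for i in range(ni):
        for j in range(nj):
            if thinned[i, j] > 0:
                out[(i, j)] = float(thinned[i, j])
    return out


def _p00(arr: np.ndarray, r: float) -> float:
    """Probability that a gene of the thinned network has k_in=k_out=0:
    ``sum P(i,j) (1-r)^(i+j)``."""
    a = 1.0 - r
    ui = a ** np.arange(arr.shape[0])
    uj = a ** np.arange(arr.shape[1])
    return float(ui @ arr @ uj)


def f_s_gene(p: float, grn_joint) -> float:
    """Functional regulatory fraction after initial perturbation at ``p``:
    the remaining genes minus the regulatory isolates."""
    arr = _joint_array(grn_joint)
    r = r_s(p, arr)
    return float(r * (1.0 - _p00(arr, r)))


def h_gene(p: float, grn_joint) -> float:
    """Conditional functional probability of the regulatory layer,
    ``h_Gene(p) = r_S/p * [1 - P^(r_S)(0,0)]``; requires ``p > 0``."""
    if p == 0:
        raise ValueError("h_gene requires p > 0")
    arr = _joint_array(grn_joint)
    r = r_s(p, arr)
    return float(r / p * (1.0 - _p00(arr, r)))


# ---------------------------------------------------------------------------
# coupled recursion
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CouplingStrengths:
    """Equivalent random-coupling strengths between the layers."""

    q_g: float
    q_p: float
    q_meta: float

    def __post_init__(self):
        for name in ("q_g", "q_p", "q_meta"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v!r}")


@dataclass
class TheoryResult:
    """Stage-by-stage remaining (primed) and functional layer sizes of the
    analytical cascade, with the converged predictions."""

    psi_prime: list[float]
    psi: list[float]
    phi_prime: list[float]
    phi: list[float]
    f_s_gene: float
    f_s_ppi: float
    f_s_met: float | None = None
    omega: float | None = None
    r_meta: float | None = None

    @property
    def stages(self) -> int:
        return len(self.psi_prime)


def cascade_theory(
    p: float,
    q_g: float,
    q_p: float,
    grn_joint,
    ppi_gf: GeneratingFunction,
    tol: float = 1e-9,
    max_iter: int = 10_000,
) -> TheoryResult:
    """Iterate the mutual-dependency recursion to its fixed point.

    psi'_n = p * (1 - q_G*(1 - h_PPI(phi'_{n-1})))
    phi'_n = 1 - q_P*(1 - h_Gene(psi'_n) * p)

    Convergence is declared on ``|psi'_n - psi'_{n+1}| < tol``; the final
    functional fractions are ``f_S^G = psi'_m h_Gene(psi'_m)`` and
    ``f_S^P = phi'_m h_PPI(phi'_m)``.
    """
    arr = _joint_array(grn_joint)

    def hg(x: float) -> float:
        return 0.0 if x <= 0 else h_gene(x, arr)

    def hp(x: float) -> float:
        return 0.0 if x <= 0 else giant_fraction(ppi_gf, x)

    psi_p: list[float] = []
    psi: list[float] = []
    phi_p: list[float] = []
    phi: list[float] = []

    cur = float(p)
    for n in range(max_iter):
        psi_p.append(cur)
        psi.append(cur * hg(cur))
        fp = 1.0 - q_p * (1.0 - hg(cur) * p)
        phi_p.append(fp)
        phi.append(fp * hp(fp))
        nxt = p * (1.0 - q_g * (1.0 - hp(fp)))
        if abs(nxt - cur) < tol:
            cur = nxt
            break
        cur = nxt
    else:
        raise RuntimeError(f"coupled recursion did not converge within {max_iter} stages")

    return TheoryResult(
        psi_prime=psi_p,
        psi=psi,
        phi_prime=phi_p,
        phi=phi,
        f_s_gene=psi[-1],
        f_s_ppi=phi[-1],
    )


def metabolic_theory(
    phi_m: float,
    support_pmf: Mapping[int, float],
    met_gf: GeneratingFunction,
    q_meta: float | None = None,
    f_p2m: float = 1.0,
) -> tuple[float, float, float]:
    """Support-failure probability ``omega``, remaining metabolite fraction
    ``r_Meta = 1 - omega`` and final functional metabolic fraction.

    ``omega = q_Meta * sum_{k_s>=1} P_D(k_s | k_s>=1)
              * sum_{l=ceil(f_P2M k_s)}^{k_s} C(k_s,l) (1-phi_m)^l phi_m^(k_s-l)``

    Metabolites without supports (``k_s = 0``) never fail through support
    loss -- hence the ``q_Meta`` prefactor over the conditional support
    distribution; they remain subject to the largest-component rule, which
    enters through the giant-component factor of the metabolic layer.
    """
    if not 0.0 <= phi_m <= 1.0:
        raise ValueError("phi_m must lie in [0, 1]")
    total = sum(support_pmf.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("support pmf must sum to 1")
    p0 = support_pmf.get(0, 0.0) / total
    if q_meta is None:
        q_meta = 1.0 - p0
    pos = {k: v / total for k, v in support_pmf.items() if k >= 1}
    pos_total = sum(pos.values())
    omega = 0.0
    if pos_total > 0 and q_meta > 0:
        for k, w in pos.items():
            lmin = int(np.ceil(f_p2m * k))
            tail = float(stats.binom.sf(lmin - 1, k, 1.0 - phi_m))
            omega += (w / pos_total) * tail
        omega *= q_meta
    r_meta = 1.0 - omega
    fsm = r_meta * giant_fraction(met_gf, r_meta) if r_meta > 0 else 0.0
    return float(omega), float(r_meta), float(fsm)


# ---------------------------------------------------------------------------
# coupling strengths
# ---------------------------------------------------------------------------


def coupling_strengths(
    net: MultilayerNetwork,
    method: str = "naive",
    *,
    sim_fsp: Sequence[float] | None = None,
    sim_fsg: Sequence[float] | None = None,
    p_grid: Sequence[float] | None = None,
) -> CouplingStrengths:
    """Equivalent coupling strengths between the layers.

    ``naive``
        q_G = fraction of genes with a paired protein, q_P = fraction of
        proteins with a paired gene, q_Meta = fraction of metabolites with
        at least one support.
    ``calibrated``
        (q_G, q_P) minimizing the squared deviation between the analytical
        curves and supplied simulated curves over ``p_grid`` (coarse grid
        search followed by local refinement); q_Meta stays the naive
        fraction, which the metabolic stage uses directly.  ``sim_fsp`` is
        required; supplying ``sim_fsg`` as well is recommended -- the
        protein curve alone under-identifies q_G, whose footprint on the
        protein layer is easily traded against small model bias, while the
        gene-layer curve pins it down.
    """
    n_g, n_p, n_m = len(net.grn.nodes), len(net.ppi.nodes), len(net.met.nodes)
    supported = {m for _, m in net.pm.links} & net.met.nodes
    naive = CouplingStrengths(
        q_g=len(net.gp.genes & net.grn.nodes) / n_g,
        q_p=len(net.gp.proteins & net.ppi.nodes) / n_p,
        q_meta=len(supported) / n_m,
    )
    if method == "naive":
        return naive
    if method != "calibrated":
        raise ValueError(f"unknown method {method!r}")
    if sim_fsp is None or p_grid is None:
        raise ValueError("calibration requires sim_fsp and p_grid")

    dd = degree_distributions(net)
    ppi_gf = GeneratingFunction(dd.ppi)
    sim_fsp = np.asarray(sim_fsp, dtype=float)
    sim_fsg = None if sim_fsg is None else np.asarray(sim_fsg, dtype=float)
    p_grid = np.asarray(p_grid, dtype=float)

    def loss(q: np.ndarray) -> float:
        qg, qp = np.clip(q, 0.0, 1.0)
        res = [cascade_theory(p, qg, qp, dd.grn_joint, ppi_gf) for p in p_grid]
        sse = float(np.sum((np.array([r.f_s_ppi for r in res]) - sim_fsp) ** 2))
        if sim_fsg is not None:
            sse += float(np.sum((np.array([r.f_s_gene for r in res]) - sim_fsg) ** 2))
        return sse

    grid = np.linspace(0.0, 1.0, 11)
    best, best_val = None, np.inf
    for qg in grid:
        for qp in grid:
            v = loss(np.array([qg, qp]))
            if v < best_val:
                best, best_val = (qg, qp), v
    res = optimize.minimize(
        loss, x0=np.array(best), method="Nelder-Mead",
        options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 400},
    )
    qg, qp = np.clip(res.x, 0.0, 1.0)
    return CouplingStrengths(q_g=float(qg), q_p=float(qp), q_meta=naive.q_meta)


# ---------------------------------------------------------------------------
# curves
# ---------------------------------------------------------------------------


def theory_curve(
    source: MultilayerNetwork | DegreeDistributions,
    p_grid: Sequence[float],
    f_p2m: float = 1.0,
    couplings: CouplingStrengths | None = None,
) -> pd.DataFrame:
    """Predicted functional fractions per layer on a grid of ``p`` values.

    ``source`` may be a network (degree distributions and naive couplings
    are derived from it) or precomputed :class:`DegreeDistributions`, in
    which case ``couplings`` must be given.
    """
    if isinstance(source, MultilayerNetwork):
        dd = degree_distributions(source)
        if couplings is None:
            couplings = coupling_strengths(source, "naive")
    else:
        dd = source
        if couplings is None:
            raise ValueError("couplings are required when passing raw distributions")
    ppi_gf = GeneratingFunction(dd.ppi)
    met_gf = GeneratingFunction(dd.met)
    rows = []
    for p in sorted(p_grid):
        res = cascade_theory(p, couplings.q_g, couplings.q_p, dd.grn_joint, ppi_gf)
        _, _, fs_m = metabolic_theory(res.f_s_ppi, dd.support, met_gf, couplings.q_meta, f_p2m)
        rows.append(
            {"p": float(p), "f_s_gene": res.f_s_gene, "f_s_ppi": res.f_s_ppi, "f_s_met": fs_m}
        )
    return pd.DataFrame(rows)


def theory_vs_sim(curve_a: pd.DataFrame, curve_b: pd.DataFrame) -> float:
    """Pearson correlation between two curve tables over the concatenated
    per-layer, per-p functional fractions (grids must match)."""
    cols = ["f_s_gene", "f_s_ppi", "f_s_met"]
    a = curve_a.sort_values("p")
    b = curve_b.sort_values("p")
    if len(a) != len(b) or not np.allclose(a["p"].to_numpy(), b["p"].to_numpy()):
        raise ValueError("p grids do not match")
    if len(a) < 3:
        raise ValueError("need at least 3 grid points")
    va = np.concatenate([a[c].to_numpy() for c in cols])
    vb = np.concatenate([b[c].to_numpy() for c in cols])
    return float(stats.pearsonr(va, vb).statistic)
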