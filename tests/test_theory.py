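"""Generating-function percolation theory: closed forms, fixed points,
internal cross-checks and coupling-strength estimation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import optimize, stats

from mlcascade.cascade import robustness_curve
from mlcascade.netmodel import degree_distributions
from mlcascade.synth import ERBenchmarkSpec, generate_er_multilayer
from mlcascade.theory import (
    CouplingStrengths,
    GeneratingFunction,
    cascade_theory,
    coupling_strengths,
    f_s_gene,
    giant_fraction,
    h_gene,
    metabolic_theory,
    r_s,
    remaining_joint,
    theory_curve,
    theory_vs_sim,
)


def poisson_pmf(mean: float, kmax: int = 80) -> dict[int, float]:
    pmf = {k: stats.poisson.pmf(k, mean) for k in range(kmax)}
    pmf[0] += 1.0 - sum(pmf.values())  # fold the tail into k=0 for exact norm.
    return pmf


def poisson_joint(mean: float, kmax: int = 60) -> dict[tuple[int, int], float]:
    pin = poisson_pmf(mean, kmax)
    pout = poisson_pmf(mean, kmax)
    return {(i, j): pin[i] * pout[j] for i in pin for j in pout if pin[i] * pout[j] > 0}


# ------------------------------------------------------- generating functions


class TestGeneratingFunction:
    def test_normalization_and_branching(self):
        gf = GeneratingFunction({1: 0.5, 3: 0.5})
        assert gf(1.0) == pytest.approx(1.0, abs=1e-12)
        assert gf.branching(1.0) == pytest.approx(1.0, abs=1e-12)
        assert gf.mean == pytest.approx(2.0)

    @given(st.integers(0, 10_000))
    def test_monotone_on_unit_interval(self, seed):
        rng = np.random.default_rng(seed)
        ks = rng.choice(20, size=rng.integers(1, 6), replace=False)
        ws = rng.random(ks.size)
        pmf = dict(zip(ks.tolist(), (ws / ws.sum()).tolist()))
        gf = GeneratingFunction(pmf)
        xs = np.linspace(0, 1, 20)
        vals = gf(xs)
        assert np.all(np.diff(vals) >= -1e-12)
        if gf.mean > 0:
            hv = gf.branching(xs)
            assert np.all(np.diff(hv) >= -1e-12)

    def test_invalid_pmfs_rejected(self):
        with pytest.raises(ValueError):
            GeneratingFunction({-1: 1.0})
        with pytest.raises(ValueError):
            GeneratingFunction({0: 0.7})
        with pytest.raises(ValueError):
            GeneratingFunction({})


class TestGiantFraction:
    def test_poisson4_supercritical_vs_bisection(self):
        gf = GeneratingFunction(poisson_pmf(4.0))
        h = giant_fraction(gf, 1.0)
        u = optimize.brentq(lambda x: x - np.exp(4 * (x - 1)), 0, 1 - 1e-10)
        assert h == pytest.approx(1 - np.exp(4 * (u - 1)), abs=1e-9)
        assert h == pytest.approx(0.98017, abs=1e-5)

    def test_subcritical_is_exactly_zero(self):
        gf = GeneratingFunction(poisson_pmf(4.0))
        assert giant_fraction(gf, 0.2) == 0.0

    def test_degenerate_pmf(self):
        gf = GeneratingFunction({0: 1.0})
        for p in (0.0, 0.5, 1.0):
            assert giant_fraction(gf, p) == 0.0

    @pytest.mark.parametrize("dist", ["poisson", "geometric"])
    def test_solver_matches_bisection_oracle(self, dist):
        """Fixed-point iteration vs an independent bracketing root-finder on
        100 random pmfs."""
        rng = np.random.default_rng(17)
        for _ in range(50):
            if dist == "poisson":
                mean = rng.uniform(0.5, 8.0)
                gf = GeneratingFunction(poisson_pmf(mean))
            else:
                q = rng.uniform(0.15, 0.7)
                pmf = {k: (1 - q) ** k * q for k in range(200)}
                pmf[0] += 1.0 - sum(pmf.values())
                gf = GeneratingFunction(pmf)
            p = rng.uniform(0.05, 1.0)
            h = giant_fraction(gf, p)

            def f(x):
                return x - gf.branching(p * x + 1 - p)

            # oracle: scan for the smallest sign change, then bisect
            xs = np.linspace(0, 1, 2001)
            fx = np.array([f(x) for x in xs])
            idx = np.where((fx[:-1] <= 0) & (fx[1:] > 0))[0]
            if idx.size == 0:
                expected = 0.0
            else:
                root = optimize.brentq(f, xs[idx[0]], xs[idx[0] + 1], xtol=1e-13)
                expected = 1 - gf(p * root + 1 - p)
            assert h == pytest.approx(expected, abs=1e-9)


# ------------------------------------------------------- regulatory formulas


class TestRegulatoryLayer:
    def test_rs_limits(self):
        joint = poisson_joint(2.0)
        assert r_s(1.0, joint) == pytest.approx(1.0, abs=1e-9)
        assert r_s(0.0, joint) == 0.0

    def test_rs_poisson_closed_form(self):
        joint = poisson_joint(2.0)
        assert r_s(0.5, joint) == pytest.approx(0.5 * np.exp(-1.0), abs=1e-9)

    def test_remaining_joint_identity_and_degenerate(self):
        joint = {(1, 2): 0.5, (0, 1): 0.5}
        assert remaining_joint(joint, 1.0) == pytest.approx(joint)
        collapsed = remaining_joint(joint, 0.0)
        assert collapsed[(0, 0)] == pytest.approx(1.0)

    def test_remaining_joint_binomial_product(self):
        thinned = remaining_joint({(1, 1): 1.0}, 0.5)
        assert thinned == pytest.approx(
            {(0, 0): 0.25, (0, 1): 0.25, (1, 0): 0.25, (1, 1): 0.25}
        )

    def test_no_isolates_at_p1(self):
        joint = {(1, 1): 0.5, (2, 1): 0.5}  # no (0,0) mass
        assert f_s_gene(1.0, joint) == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    def test_direct_sum_equals_thinned_form(self, seed):
        """The double-sum expression and the thinned-pmf expression for the
        functional regulatory fraction agree to 1e-10 on random joints."""
        rng = np.random.default_rng(seed)
        a = rng.random((rng.integers(2, 6), rng.integers(2, 6)))
        a /= a.sum()
        joint = {(i, j): a[i, j] for i in range(a.shape[0]) for j in range(a.shape[1])}
        p = rng.uniform(0.05, 1.0)
        r = r_s(p, joint)
        thinned = remaining_joint(joint, r)
        assert f_s_gene(p, joint) == pytest.approx(
            r * (1 - thinned.get((0, 0), 0.0)), abs=1e-10
        )

    def test_h_gene_requires_positive_p(self):
        with pytest.raises(ValueError):
            h_gene(0.0, {(1, 1): 1.0})


# ------------------------------------------------------------------ coupling


class TestCascadeTheory:
    def test_decoupled_limit_reduces_to_single_layers(self):
        joint = poisson_joint(2.0)
        ppi_gf = GeneratingFunction(poisson_pmf(6.0))
        for p in (0.3, 0.6, 0.9):
            res = cascade_theory(p, 0.0, 0.0, joint, ppi_gf)
            assert res.f_s_gene == pytest.approx(f_s_gene(p, joint), abs=1e-12)
            assert res.f_s_ppi == pytest.approx(giant_fraction(ppi_gf, 1.0), abs=1e-12)
            assert all(abs(x - p) < 1e-12 for x in res.psi_prime)
            assert all(abs(x - 1.0) < 1e-12 for x in res.phi_prime)

    def test_remaining_sequence_non_increasing(self):
        joint = poisson_joint(2.0)
        ppi_gf = GeneratingFunction(poisson_pmf(8.0))
        res = cascade_theory(0.6, 0.8, 0.8, joint, ppi_gf)
        psi = np.array(res.psi_prime)
        assert np.all(np.diff(psi) <= 1e-12)
        for seq in (res.psi_prime, res.psi, res.phi_prime, res.phi):
            assert all(0.0 <= x <= 1.0 for x in seq)

    def test_p1_baseline(self):
        # no isolated genes and a degree-regular PPI (its giant component is
        # everything), so nothing fails at p = 1 for any coupling strengths
        joint = {(1, 1): 0.5, (2, 2): 0.5}
        ppi_gf = GeneratingFunction({4: 1.0})
        res = cascade_theory(1.0, 0.5, 0.5, joint, ppi_gf)
        assert res.f_s_gene == pytest.approx(1.0, abs=1e-9)
        assert res.f_s_ppi == pytest.approx(1.0, abs=1e-9)


class TestMetabolicTheory:
    def test_no_protein_failure_keeps_all_supported(self):
        met_gf = GeneratingFunction(poisson_pmf(4.0))
        omega, r_meta, _ = metabolic_theory(1.0, {0: 0.25, 2: 0.75}, met_gf, f_p2m=0.7)
        assert omega == 0.0
        assert r_meta == 1.0

    def test_binomial_tail_hand_value(self):
        met_gf = GeneratingFunction(poisson_pmf(4.0))
        omega, _, _ = metabolic_theory(0.9, {2: 1.0}, met_gf, q_meta=1.0, f_p2m=0.5)
        assert omega == pytest.approx(2 * 0.1 * 0.9 + 0.1**2)

    def test_all_supports_must_fail_closed_form(self):
        met_gf = GeneratingFunction(poisson_pmf(4.0))
        pmf = {1: 0.3, 2: 0.4, 3: 0.3}
        phi = 0.65
        omega, _, _ = metabolic_theory(phi, pmf, met_gf, q_meta=1.0, f_p2m=1.0)
        expected = sum(w * (1 - phi) ** k for k, w in pmf.items())
        assert omega == pytest.approx(expected, abs=1e-12)

    def test_zero_threshold_fails_all_supported(self):
        met_gf = GeneratingFunction(poisson_pmf(4.0))
        omega, _, _ = metabolic_theory(1.0, {0: 0.2, 3: 0.8}, met_gf, f_p2m=0.0)
        assert omega == pytest.approx(0.8)


class TestCouplingStrengths:
    def test_naive_on_t1(self, t1):
        cs = coupling_strengths(t1)
        assert cs.q_g == pytest.approx(1.0)
        assert cs.q_p == pytest.approx(4 / 5)
        assert cs.q_meta == pytest.approx(1.0)

    def test_naive_fully_matched(self):
        net = generate_er_multilayer(
            ERBenchmarkSpec(n_g=100, n_p=100, n_m=30, q_g=1.0, q_p=1.0), seed=0
        )
        cs = coupling_strengths(net)
        assert cs.q_g == 1.0
        assert cs.q_p == 1.0

    def test_calibration_requires_curve(self, t1):
        with pytest.raises(ValueError):
            coupling_strengths(t1, "calibrated")

    def test_calibrated_on_decoupled_simulation_near_zero(self):
        """Simulated curves from a network without interlayer links calibrate
        to vanishing coupling strengths."""
        net = generate_er_multilayer(
            ERBenchmarkSpec(n_g=800, n_p=800, n_m=100, q_g=0.0, q_p=0.0), seed=6
        )
        grid = np.round(np.arange(2, 11) * 0.1, 10)
        curve = robustness_curve(net, grid, replicates=4, seed=2, isolate_rule="per_round")
        cs = coupling_strengths(
            net, "calibrated",
            sim_fsp=curve.mean["ppi"], sim_fsg=curve.mean["gene"], p_grid=grid,
        )
        assert cs.q_p == pytest.approx(0.0, abs=0.05)

    def test_calibration_self_consistency(self):
        """Calibrating against the model's own curves recovers the generating
        couplings essentially exactly (estimator consistency)."""
        net = generate_er_multilayer(
            ERBenchmarkSpec(n_g=600, n_p=600, n_m=100), seed=3
        )
        grid = np.round(np.arange(1, 21) * 0.05, 10)
        truth = CouplingStrengths(0.8, 0.8, 1.0)
        th = theory_curve(net, grid, couplings=truth)
        cs = coupling_strengths(
            net, "calibrated",
            sim_fsp=th["f_s_ppi"], sim_fsg=th["f_s_gene"], p_grid=grid,
        )
        assert cs.q_g == pytest.approx(0.8, abs=0.01)
        assert cs.q_p == pytest.approx(0.8, abs=0.01)


# -------------------------------------------------------------------- curves


class TestCurves:
    def test_identical_and_antimonotone(self):
        import pandas as pd

        a = pd.DataFrame(
            {"p": [0.1, 0.5, 1.0], "f_s_gene": [0.1, 0.5, 0.9],
             "f_s_ppi": [0.2, 0.5, 0.8], "f_s_met": [0.1, 0.4, 0.9]}
        )
        assert theory_vs_sim(a, a) == pytest.approx(1.0)
        b = a.copy()
        for c in ("f_s_gene", "f_s_ppi", "f_s_met"):
            b[c] = 1.0 - 0.9 * a[c]
        assert theory_vs_sim(a, b) == pytest.approx(-1.0)
        with pytest.raises(ValueError):
            theory_vs_sim(a.iloc[:2], a.iloc[:2])

    def test_curves_bounded_and_monotone(self, small_er):
        grid = np.round(np.linspace(0.05, 1.0, 20), 10)
        df = theory_curve(small_er, grid)
        for c in ("f_s_gene", "f_s_ppi", "f_s_met"):
            assert ((0 <= df[c]) & (df[c] <= 1)).all()
            assert np.all(np.diff(df[c].to_numpy()) >= -1e-9)
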