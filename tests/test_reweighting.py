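"""Histogramming, WHAM self-consistency, Gibbs free energy, projections."""

import math

import numpy as np
import pytest

from aquamono.model import StatePoint
from aquamono.observables import ObservableSeries
from aquamono.reweighting import (
    Histogram2D,
    build_histogram,
    common_edges,
    gibbs_along_isotherm,
    project_order_parameter,
    reweight,
    reweighted_moments,
    solve_wham,
)
from aquamono.workbench import synthetic_series


def _series(u, rho, T=1.0, P=0.2, n_mol=100):
    n = len(u)
    return ObservableSeries(point=StatePoint(T=T, P=P),
                            u=np.asarray(u, dtype=float),
                            rho=np.asarray(rho, dtype=float),
                            n_hb=np.zeros(n, dtype=int),
                            n_coop=np.zeros(n, dtype=int),
                            V=n_mol / np.asarray(rho, dtype=float),
                            meta={"n_molecules": n_mol})


class TestBuildHistogram:
    def test_constant_series_single_bin(self):
        s = _series(np.full(50, -1.0), np.full(50, 0.5))
        h = build_histogram(s, bins=(10, 10))
        assert h.counts.sum() == 50
        assert (h.counts > 0).sum() == 1

    def test_counts_conserved_for_two_values(self):
        u = np.array([-1.0] * 30 + [-0.5] * 20)
        rho = np.array([0.4] * 30 + [0.6] * 20)
        h = build_histogram(_series(u, rho), bins=(8, 8))
        assert h.counts.sum() == 50
        assert sorted(h.counts[h.counts > 0].tolist()) == [20, 30]

    def test_rebuild_is_bit_identical(self):
        s = synthetic_series("gaussian", seed=4, n=500)
        ue, re_ = common_edges([s], bins=(50, 50))
        a = build_histogram(s, ue, re_)
        b = build_histogram(s, ue, re_)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_empty_series_rejected(self):
        s = _series(np.array([]), np.array([]))
        with pytest.raises(ValueError):
            build_histogram(s)

    def test_hdf5_container_roundtrip(self, tmp_path):
        from aquamono.reweighting import load_histograms, save_histograms
        s = synthetic_series("gaussian", seed=4, n=500)
        h = build_histogram(s, bins=(20, 20))
        path = tmp_path / "runs.h5"
        save_histograms(path, [h, h])
        back = load_histograms(path)
        assert len(back) == 2
        np.testing.assert_array_equal(back[0].counts, h.counts)
        assert back[0].T == h.T and back[0].n_molecules == h.n_molecules


class TestWham:
    def test_single_run_gauge(self):
        s = synthetic_series("gaussian", seed=1, n=2000)
        sol = solve_wham([build_histogram(s, bins=(40, 40))])
        assert sol.C[0] == 0.0
        assert sol.converged

    def test_identical_runs_equal_constants(self):
        a = synthetic_series("gaussian", seed=1, n=2000)
        b = synthetic_series("gaussian", seed=2, n=2000)
        ue, re_ = common_edges([a, b], bins=(40, 40))
        sol = solve_wham([build_histogram(a, ue, re_),
                          build_histogram(b, ue, re_)])
        assert sol.C[1] == pytest.approx(0.0, abs=0.05)

    def test_mismatched_edges_rejected(self):
        a = synthetic_series("gaussian", seed=1, n=200)
        with pytest.raises(ValueError):
            solve_wham([build_histogram(a, bins=(10, 10)),
                        build_histogram(a, bins=(12, 12))])

    def test_decoupled_edge_free_energy(self, rng):
        # independent-edge toy: N_match ~ Binomial(E, p(beta)); the exact
        # log partition function is a binomial sum, so C_2 - C_1 is known
        q, E, j, V, P, n = 6, 512, 0.3, 300.0, 0.2, 40000
        betas = (1.0 / 1.2, 1.0 / 0.9)
        series = []
        for b in betas:
            pm = math.exp(b * j) / (math.exp(b * j) + q - 1)
            nm = rng.binomial(E, pm, size=n)
            series.append(_series(-j * nm / 256.0, np.full(n, 256.0 / V),
                                  T=1.0 / b, P=P, n_mol=256))
        ue, re_ = common_edges(series, bins=(400, 2))
        sol = solve_wham([build_histogram(s, ue, re_) for s in series])
        from scipy.special import gammaln
        k = np.arange(E + 1)

        def log_Z(b):
            lg = (gammaln(E + 1) - gammaln(k + 1) - gammaln(E - k + 1)
                  + k * b * j + (E - k) * math.log(q - 1) - E * math.log(q))
            m = lg.max()
            return m + math.log(np.exp(lg - m).sum()) - b * P * V

        analytic = -(log_Z(betas[1]) - log_Z(betas[0]))
        assert sol.C[1] - sol.C[0] == pytest.approx(analytic, abs=0.05)

    def test_convergence_tolerance_honoured(self):
        s = [synthetic_series("gaussian", seed=i, n=2000, mean_u=-1.0 + 0.1 * i)
             for i in range(3)]
        ue, re_ = common_edges(s, bins=(40, 40))
        sol = solve_wham([build_histogram(x, ue, re_) for x in s],
                         tolerance=1e-3)
        assert sol.max_change < 1e-3
        # fixed-point change decreases monotonically after the first step
        assert all(np.diff(sol.trace[1:]) <= 1e-12)


class TestReweight:
    def test_identity_reweighting(self):
        s = synthetic_series("gaussian", seed=3, n=5000)
        h = build_histogram(s, bins=(60, 60))
        sol = solve_wham([h])
        back = reweight(sol, s.point.T, s.point.P)
        np.testing.assert_allclose(back.counts, h.counts / h.counts.sum(),
                                   atol=1e-12)

    def test_mass_conservation(self):
        s = synthetic_series("gaussian", seed=3, n=5000)
        sol = solve_wham([build_histogram(s, bins=(60, 60))])
        h = reweight(sol, s.point.T * 1.02, s.point.P * 0.98)
        assert h.counts.sum() == pytest.approx(1.0, abs=1e-12)

    def test_gauge_invariance(self):
        s = synthetic_series("gaussian", seed=3, n=5000)
        sol = solve_wham([build_histogram(s, bins=(60, 60))])
        m1 = reweighted_moments(sol, 1.02, 0.19)
        sol.C = sol.C + 3.7  # common shift must not change observables
        sol.log_omega = sol.log_omega  # density of states untouched
        m2 = reweighted_moments(sol, 1.02, 0.19)
        assert m1["u"] == pytest.approx(m2["u"], rel=1e-12)
        assert m1["K_T"] == pytest.approx(m2["K_T"], rel=1e-12)

    def test_interpolated_mean_matches_enumeration(self, rng):
        # two-level toy with exact enumeration at an intermediate beta
        q, E, j, V, P, n = 6, 512, 0.3, 300.0, 0.2, 60000
        T1, T2, T_mid = 1.2, 0.9, 1.05
        series = []
        for T in (T1, T2):
            pm = math.exp(j / T) / (math.exp(j / T) + q - 1)
            nm = rng.binomial(E, pm, size=n)
            series.append(_series(-j * nm / 256.0, np.full(n, 256.0 / V),
                                  T=T, P=P, n_mol=256))
        ue, re_ = common_edges(series, bins=(400, 2))
        sol = solve_wham([build_histogram(s, ue, re_) for s in series])
        m = reweighted_moments(sol, T_mid, P)
        pm = math.exp(j / T_mid) / (math.exp(j / T_mid) + q - 1)
        exact_u = -j * E * pm / 256.0
        assert m["u"] == pytest.approx(exact_u, abs=3 * j * math.sqrt(E) / 256 / math.sqrt(n) * 50)


class TestGibbs:
    def test_dG_dP_equals_mean_volume(self):
        s = synthetic_series("gaussian", seed=6, n=20000, mean_rho=0.5,
                             cov=[[0.01, 0.0], [0.0, 0.001]])
        sol = solve_wham([build_histogram(s, bins=(80, 80))])
        T = s.point.T
        P_vals = np.linspace(s.point.P * 0.95, s.point.P * 1.05, 11)
        g = gibbs_along_isotherm(sol, T, P_vals)
        interior = slice(1, -1)
        np.testing.assert_allclose(g["dG_dP"].to_numpy()[interior],
                                   g["mean_V"].to_numpy()[interior], rtol=0.02)
        assert g["G"].iloc[0] == 0.0

    def test_ideal_volume_toy_matches_quadrature(self, rng):
        # bare-measure ideal system: V - N v0 ~ Exp(T/P0); G(P) has the
        # closed integral -T ln int exp(-P V / T) dV over the support
        T, P0, n_mol, n = 1.0, 0.3, 100, 120000
        V = n_mol + rng.exponential(T / P0, size=n)
        s = _series(np.zeros(n), n_mol / V, T=T, P=P0, n_mol=n_mol)
        sol = solve_wham([build_histogram(s, bins=(2, 400))])
        P_vals = np.linspace(0.25, 0.35, 5)
        g = gibbs_along_isotherm(sol, T, P_vals)
        # analytic: G(P) - G(P_lo) = n_mol (P - P_lo) + T ln(P / P_lo)
        expect = n_mol * (P_vals - P_vals[0]) + T * np.log(P_vals / P_vals[0])
        np.testing.assert_allclose(g["G"].to_numpy(), expect, atol=0.05)


class TestProjection:
    def test_zero_mixing_recovers_density_marginal(self):
        s = synthetic_series("gaussian", seed=8, n=30000)
        h = build_histogram(s, bins=(60, 60))
        M, Q = project_order_parameter(h, s=0.0)
        marg = h.counts.sum(axis=0)
        marg = marg / (marg.sum() * (h.rho_edges[1] - h.rho_edges[0]))
        centers = h.rho_centers
        # same mean and variance as the rho marginal
        mM = np.sum(M * Q) / Q.sum()
        mR = np.sum(centers * marg) / marg.sum()
        assert mM == pytest.approx(mR, abs=1e-3)

    def test_isotropic_gaussian_projection_variance(self):
        sig2 = 0.01
        s = synthetic_series("gaussian", seed=9, n=200000,
                             cov=[[sig2, 0.0], [0.0, sig2]])
        h = build_histogram(s, bins=(120, 120))
        for mix in (0.5, 1.0):
            M, Q = project_order_parameter(h, s=mix)
            w = Q / Q.sum()
            mean = np.sum(w * M)
            var = np.sum(w * (M - mean) ** 2)
            assert var == pytest.approx((1 + mix ** 2) * sig2, rel=0.05)

    def test_matches_sample_level_projection(self):
        s = synthetic_series("double_gaussian", seed=10, n=50000,
                             separation=0.2, width=0.03,
                             direction=[0.6, 0.8])
        h = build_histogram(s, bins=(150, 150))
        mix = 0.3
        M, Q = project_order_parameter(h, s=mix)
        w = Q / Q.sum()
        direct = s.rho + mix * s.u
        assert np.sum(w * M) == pytest.approx(direct.mean(), abs=2e-3)
        var_hist = np.sum(w * (M - np.sum(w * M)) ** 2)
        assert var_hist == pytest.approx(direct.var(), rel=0.05)

    def test_unit_mass(self):
        s = synthetic_series("gaussian", seed=11, n=5000)
        h = build_histogram(s, bins=(60, 60))
        M, Q = project_order_parameter(h, s=0.4)
        dx = M[1] - M[0]
        assert np.sum(Q) * dx == pytest.approx(1.0, abs=1e-12)
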