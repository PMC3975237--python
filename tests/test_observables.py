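"""Response functions, correlation lengths, loci and thermodynamic identities."""

import math

import numpy as np
import pandas as pd
import pytest

from aquamono.model import StatePoint
from aquamono.observables import (
    CorrelationData,
    ObservableSeries,
    correlation_function,
    density_extrema,
    extrema_loci,
    fit_correlation_length,
    is_bimodal,
    lg_spinodal,
    ll_spinodal_from_isochores,
    loci_coincide,
    response_functions,
    thermo_fields,
    verify_thermo_identities,
    widom_line,
)


def _series(T, P, V, u=None, n_mol=100):
    n = len(V)
    u = np.zeros(n) if u is None else u
    return ObservableSeries(point=StatePoint(T=T, P=P), u=u,
                            rho=n_mol / np.asarray(V, dtype=float),
                            n_hb=np.zeros(n, dtype=int),
                            n_coop=np.zeros(n, dtype=int),
                            V=np.asarray(V, dtype=float),
                            meta={"n_molecules": n_mol})


class TestResponseFunctions:
    def test_ideal_volume_law(self, rng):
        # V = N v0 + Exp(T/P): K_T = T/(P^2 <V>), alpha_P = 1/(P <V>),
        # C_P = 1 (H = P V exactly, var H = P^2 var V = T^2)
        T, n_mol = 1.0, 100
        n = 60000
        series = []
        for P in (0.2, 0.25, 0.3):
            V = n_mol + rng.exponential(T / P, size=n)
            series.append(_series(T, P, V, n_mol=n_mol))
        for Tv in (0.9, 1.1):
            P = 0.25
            V = n_mol + rng.exponential(Tv / P, size=n)
            series.append(_series(Tv, P, V, n_mol=n_mol))
        grid = response_functions(series)
        mid = grid[(grid["T"] == 1.0) & (grid["P"] == 0.25)].iloc[0]
        meanV = n_mol + T / 0.25
        assert mid["K_T"] == pytest.approx(T / (0.25 ** 2 * meanV), rel=0.05)
        assert mid["alpha_P"] == pytest.approx(1 / (0.25 * meanV), rel=0.05)
        # derivative routes agree with fluctuation routes
        assert mid["K_T_deriv"] == pytest.approx(mid["K_T"], rel=0.1)
        assert mid["alpha_P_deriv"] == pytest.approx(mid["alpha_P"], rel=0.15)

    def test_constant_series_has_zero_response(self):
        V = np.full(500, 120.0)
        grid = response_functions([_series(1.0, 0.3, V)])
        row = grid.iloc[0]
        assert row["K_T"] == 0.0 and row["C_P"] == 0.0
        assert not row["coexistence"]

    def test_bimodal_point_flagged_and_suppressed(self, rng):
        V = np.concatenate([rng.normal(100, 1, 2000), rng.normal(140, 1, 2000)])
        grid = response_functions([_series(1.0, 0.3, V)])
        row = grid.iloc[0]
        assert row["coexistence"]
        assert np.isnan(row["K_T"])


class TestBimodalDetector:
    def test_unimodal(self, rng):
        assert not is_bimodal(rng.normal(size=4000))

    def test_bimodal(self, rng):
        x = np.concatenate([rng.normal(-3, 1, 2000), rng.normal(3, 1, 2000)])
        assert is_bimodal(x)


def _make_corr(r, G, err=None, side=32):
    return CorrelationData(r=np.asarray(r, dtype=float),
                           G=np.asarray(G, dtype=float),
                           G_err=None if err is None else np.asarray(err),
                           side=side)


class TestCorrelationLength:
    def test_pure_exponential(self):
        r = np.arange(0, 9, dtype=float)
        corr = _make_corr(r, np.exp(-r / 2.0))
        fit = fit_correlation_length(corr, mode="exp")
        assert fit.xi == pytest.approx(2.0, abs=1e-10)

    def test_ornstein_zernike(self):
        r = np.arange(1, 9, dtype=float)
        corr = _make_corr(np.concatenate([[0.0], r]),
                          np.concatenate([[1.0], np.exp(-r / 3.0) / r ** 0.25]))
        fit = fit_correlation_length(corr, d=2, mode="oz", eta=0.25)
        assert fit.xi == pytest.approx(3.0, abs=1e-10)

    def test_noisy_recovery_within_two_sigma(self, rng):
        r = np.arange(0, 9, dtype=float)
        G = np.exp(-r / 2.0) * np.exp(rng.normal(scale=0.05, size=len(r)))
        fit = fit_correlation_length(_make_corr(r, G), mode="exp")
        assert abs(fit.xi - 2.0) < 2 * max(fit.xi_err, 0.05)

    def test_rescaling_invariance(self):
        r = np.arange(0, 9, dtype=float)
        a = fit_correlation_length(_make_corr(r, np.exp(-r / 2.0)))
        b = fit_correlation_length(_make_corr(r, 7.3 * np.exp(-r / 2.0)))
        assert a.xi == pytest.approx(b.xi, rel=1e-12)

    def test_too_few_bins(self):
        with pytest.raises(ValueError):
            fit_correlation_length(_make_corr([0.0, 1.0], [1.0, -0.1]))

    def test_degenerate_flag_passthrough(self):
        corr = CorrelationData(r=np.arange(4.0), G=np.full(4, np.nan),
                               degenerate=True, side=8)
        fit = fit_correlation_length(corr)
        assert fit.degenerate and not fit.reliable


class TestCorrelationFunction:
    def test_ordered_configuration_is_degenerate(self):
        sig = np.full((64, 4), 3, dtype=np.int64)
        corr = correlation_function([sig] * 10, side=8, q=6)
        assert corr.degenerate

    def test_uniform_random_is_uncorrelated(self, rng):
        configs = [rng.integers(0, 6, size=(256, 4)) for _ in range(200)]
        corr = correlation_function(configs, side=16, q=6)
        assert corr.G[0] == pytest.approx(1.0)
        assert np.all(np.abs(corr.G[1:]) < 0.02)

    def test_matches_enumeration_on_tiny_system(self):
        # 2x2, q = 2 at finite beta: G(1) from MC configurations vs a direct
        # exhaustive average over all 2^16 sigma states
        import itertools

        from aquamono.mc import MCConfig, make_rng_state, run_state_point
        from aquamono.model import LatticeState, ModelParams
        from aquamono.observables import _overlap_fields

        params = ModelParams(q=2)
        pt = StatePoint(T=0.8, P=0.4)
        V0 = 5.0  # pinned, occupied
        # exact enumeration of the overlap-kernel correlation at r = 1
        from aquamono.model import count_cooperative, count_matching_edges
        num0 = num1 = norm = 0.0
        mean_f = np.zeros(2)
        beta = pt.beta
        for arms in itertools.product(range(2), repeat=16):
            sig = np.asarray(arms, dtype=np.int64).reshape(4, 4)
            nm = count_matching_edges(sig, 2)
            nc = count_cooperative(sig)
            E = -params.j * nm - params.j_sigma * nc
            w = math.exp(-beta * (E + pt.P * (V0 + nm * params.v_hb)))
            psi = _overlap_fields(sig, 2, 2).reshape(2, 4)
            c0 = np.sum(psi ** 2) / 4
            # r = 1 pairs on the 2x2 torus: each site with 2 distinct nbrs
            c1 = (psi[:, 0] @ psi[:, 1] + psi[:, 2] @ psi[:, 3]
                  + psi[:, 0] @ psi[:, 2] + psi[:, 1] @ psi[:, 3]) / 4
            num0 += w * c0
            num1 += w * c1
            mean_f += w * psi.mean(axis=1)
            norm += w
        c0, c1 = num0 / norm, num1 / norm
        sbar2 = float(np.sum((mean_f / norm) ** 2))
        G1_exact = (c1 - sbar2) / (c0 - sbar2)
        # MC estimate
        st = LatticeState.random(2, params, np.random.default_rng(0), V0=V0)
        cfg = MCConfig(schedule=[pt], seed=5, n_equil=300, n_sample=4000,
                       decorrelation_stride=2, volume_moves_per_sweep=0,
                       collect_configs=True)
        s = run_state_point(st, pt, params, cfg, make_rng_state(5))
        corr = correlation_function(s.configs, side=2, q=2)
        G1_mc = corr.G[np.isclose(corr.r, 1.0)][0]
        err = corr.G_err[np.isclose(corr.r, 1.0)][0]
        assert abs(G1_mc - G1_exact) < 4 * err + 0.01


class TestDensityExtrema:
    def test_parabolic_maximum(self):
        T = np.linspace(1.0, 3.0, 21)
        rho = 1.0 - (T - 2.0) ** 2
        ext = density_extrema(T, rho)
        tmds = [e for e in ext if e.kind == "TMD"]
        assert len(tmds) == 1
        assert tmds[0].T == pytest.approx(2.0, abs=1e-8)

    def test_monotone_has_no_extremum(self):
        T = np.linspace(1.0, 3.0, 21)
        ext = density_extrema(T, 0.5 + 0.1 * T)
        assert not [e for e in ext if not e.at_edge]

    def test_min_then_max_ordering(self):
        T = np.linspace(0.0, 3.0, 31)
        rho = -0.1 * (T - 1.0) ** 3 + 0.15 * (T - 1.0) ** 2 + 0.5
        ext = [e for e in density_extrema(T, rho) if not e.at_edge]
        kinds = {e.kind: e.T for e in ext}
        assert "TMD" in kinds and "TminD" in kinds
        assert kinds["TMD"] > kinds["TminD"]

    def test_needs_enough_points(self):
        with pytest.raises(ValueError):
            density_extrema(np.arange(3.0), np.arange(3.0))


class TestSpinodals:
    def test_step_isobar(self):
        T = np.linspace(1.0, 2.0, 11)
        rho = np.where(T < 1.55, 0.7, 0.01)
        assert lg_spinodal(T, rho) == pytest.approx(1.55, abs=0.05)

    def test_no_jump_returns_none(self):
        T = np.linspace(1.0, 2.0, 11)
        assert lg_spinodal(T, np.full(11, 0.7)) is None

    def test_isochore_fan_envelope(self):
        T0, P0 = 1.2, 0.4
        T = np.linspace(0.8, 1.6, 100)
        isochores = [(rho, T, P0 + slope * (T - T0))
                     for rho, slope in ((0.5, 0.3), (0.55, 0.6), (0.6, 0.9))]
        env = ll_spinodal_from_isochores(isochores)
        assert len(env) == 2
        assert np.allclose(env["T"], T0, atol=0.02)
        assert np.allclose(env["P"], P0, atol=0.02)


class TestExtremaLoci:
    @staticmethod
    def _grid_with_bumps():
        rows = []
        T = np.linspace(0.0, 10.0, 101)
        for P in (0.1, 0.2):
            K = (10.0 * np.exp(-((T - 3.0) ** 2) / 0.5)
                 + 2.0 * np.exp(-((T - 7.0) ** 2) / 0.5) + 0.1)
            for t, k in zip(T, K):
                rows.append({"T": t, "P": P, "K_T": k})
        return pd.DataFrame(rows)

    def test_strong_weak_classification(self):
        loci = extrema_loci(self._grid_with_bumps(), quantities=("K_T",))
        strong = loci["K_T_strong_max_T"]
        weak = loci["K_T_weak_max_T"]
        assert np.allclose(strong["T"], 3.0, atol=0.05)
        assert np.allclose(weak["T"], 7.0, atol=0.05)

    def test_symmetric_surface_loci_coincide(self):
        rows = []
        x = np.linspace(0.0, 2.0, 41)
        for P in x:
            for T in x:
                rows.append({"T": T, "P": P,
                             "K_T": np.exp(-((T - 1) ** 2 + (P - 1) ** 2))})
        loci = extrema_loci(pd.DataFrame(rows), quantities=("K_T",))
        along_T = loci["K_T_strong_max_T"]
        along_P = loci["K_T_strong_max_P"]
        # both scans put the ridge at the symmetric centre
        assert np.allclose(along_T["T"], 1.0, atol=0.03)
        assert np.allclose(along_P["P"], 1.0, atol=0.03)


class TestWidomLine:
    def test_ridge_recovery(self):
        rows = []
        for P in np.linspace(0.2, 0.8, 4):
            for T in np.linspace(0.1, 1.1, 21):
                rows.append({"T": T, "P": P,
                             "xi": 5.0 * np.exp(-((T - P) ** 2) / 0.02)})
        wl = widom_line(pd.DataFrame(rows))
        assert len(wl) == 4
        assert np.allclose(wl["T"], wl["P"], atol=0.03)

    def test_no_interior_maximum_excluded(self):
        rows = [{"T": t, "P": 0.3, "xi": t} for t in np.linspace(0, 1, 11)]
        wl = widom_line(pd.DataFrame(rows))
        assert len(wl) == 0

    def test_loci_coincide_helper(self):
        a = pd.DataFrame({"T": [1.0, 1.1], "P": [0.2, 0.3]})
        b = pd.DataFrame({"T": [1.02, 1.13], "P": [0.2, 0.3]})
        assert loci_coincide(a, b, t_err=0.02)
        assert not loci_coincide(a, b, t_err=0.002)


class TestThermoIdentities:
    @staticmethod
    def _toy(T, P):
        return 2.0 - 0.05 * P + 0.3 * (T - (1.0 + 0.2 * P)) ** 2

    def test_alpha_vanishes_on_tmd_analytically(self):
        # alpha_P = 0 exactly on the extremal line T = T0(P)
        f = thermo_fields(self._toy, 1.0 + 0.2 * 0.5, 0.5)
        assert abs(f["alpha_P"]) < 1e-9

    def test_maxwell_identity_on_grid(self):
        rep = verify_thermo_identities(self._toy, np.linspace(0.8, 1.4, 5),
                                       np.linspace(0.2, 0.8, 5))
        assert rep["identity_rel_residual"] < 1e-6
        assert rep["alpha_max_on_extrema"] < 1e-3
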