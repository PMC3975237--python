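"""Mixed-field scaling: rescaling, cumulants, divergences, finite-size fits."""

import math

import numpy as np
import pytest

from aquamono.criticality import (
    UniversalReference,
    b_scaling_exponent,
    clb_parameter,
    extrapolate_critical,
    fit_critical_point,
    interface_free_energy,
    kl_divergence,
    liu_deviation,
    mixed_field_series,
    piecewise_loglog,
    reference_distribution,
    rescale_distribution,
    wham_qn_provider,
)
from aquamono.model import StatePoint
from aquamono.reweighting import build_histogram, common_edges, solve_wham
from aquamono.workbench import synthetic_critical_runs, synthetic_series


def _gauss_ref(mu=0.0, sigma=1.0, lim=6.0, n=2001):
    x = np.linspace(-lim, lim, n)
    pdf = np.exp(-((x - mu) ** 2) / (2 * sigma ** 2)) / (sigma * math.sqrt(2 * math.pi))
    return UniversalReference(d=2, x=x, pdf=pdf)


class TestMixedFieldSeries:
    def test_zero_mixing_is_density(self):
        s = synthetic_series("gaussian", seed=1, n=100)
        np.testing.assert_array_equal(mixed_field_series(s, 0.0), s.rho)

    def test_linear_combination(self):
        s = synthetic_series("gaussian", seed=1, n=100)
        np.testing.assert_allclose(mixed_field_series(s, 0.3),
                                   s.rho + 0.3 * s.u)


class TestRescaleDistribution:
    def test_standard_gaussian(self):
        ref = _gauss_ref()
        x, Q, B, M_c = rescale_distribution(ref.x, ref.pdf)
        assert B == pytest.approx(1.0, abs=1e-4)
        assert M_c == pytest.approx(0.0, abs=1e-10)

    def test_shifted_scaled_gaussian(self):
        ref = _gauss_ref(mu=5.0, sigma=2.0, lim=20.0)
        x, Q, B, M_c = rescale_distribution(ref.x + 0.0, ref.pdf)
        assert M_c == pytest.approx(5.0, abs=1e-3)
        assert B == pytest.approx(0.5, abs=1e-3)

    def test_output_has_zero_mean_unit_variance(self):
        # bimodal fixture; moments re-verified on the rescaled grid
        x0 = np.linspace(-3, 3, 1201)
        Q0 = np.exp(-((x0 - 1.1) ** 2) / 0.08) + 0.7 * np.exp(-((x0 + 0.9) ** 2) / 0.1)
        x, Q, B, M_c = rescale_distribution(x0, Q0)
        w = Q / Q.sum()
        assert np.sum(w * x) == pytest.approx(0.0, abs=1e-9)
        assert np.sum(w * x ** 2) == pytest.approx(1.0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            rescale_distribution(np.array([1.0, 1.0]), np.array([0.5, 0.5]))


class TestCLBParameter:
    def test_point_mass_is_two_thirds(self):
        u, err = clb_parameter(np.full(100, 3.7))
        assert u == pytest.approx(2.0 / 3.0, abs=1e-14)

    def test_two_deltas(self):
        # equal-weight masses at 1 and 3: 1 - 41/75
        M = np.array([1.0, 3.0])
        u, _ = clb_parameter(M, weights=np.array([0.5, 0.5]))
        assert u == pytest.approx(1.0 - 41.0 / 75.0, abs=1e-14)

    def test_narrow_gaussian_limit(self, rng):
        # exact: 1 - (mu^4 + 6 mu^2 s^2 + 3 s^4) / (3 (mu^2 + s^2)^2)
        mu, sg = 10.0, 0.1
        exact = 1.0 - (mu ** 4 + 6 * mu ** 2 * sg ** 2 + 3 * sg ** 4) \
            / (3 * (mu ** 2 + sg ** 2) ** 2)
        M = rng.normal(mu, sg, size=200000)
        u, _ = clb_parameter(M)
        assert u == pytest.approx(exact, abs=2e-5)
        assert abs(u - 2.0 / 3.0) < 2e-4  # narrow-peak limit

    def test_scale_invariance(self, rng):
        M = rng.normal(1.0, 0.5, size=5000)
        u1, _ = clb_parameter(M)
        u2, _ = clb_parameter(5.0 * M)
        assert u1 == pytest.approx(u2, rel=1e-12)

    def test_bimodal_below_two_thirds(self, rng):
        # two well-separated positive phases (density-like order parameter)
        M = np.concatenate([rng.normal(0.5, 0.02, 5000),
                            rng.normal(1.5, 0.02, 5000)])
        u, _ = clb_parameter(M)
        assert u < 2.0 / 3.0 - 0.15

    def test_zero_samples_rejected(self):
        with pytest.raises(ValueError):
            clb_parameter(np.zeros(10))


class TestKLDivergence:
    def test_self_divergence_zero(self):
        ref = reference_distribution(2)
        assert kl_divergence(ref.x, ref.pdf, ref) == pytest.approx(0.0, abs=1e-9)

    def test_gaussian_closed_form(self):
        # KL(N(0,1) || N(0.5,1)) = mu^2/2 = 0.125
        p = _gauss_ref(0.0, 1.0, lim=10.0, n=6001)
        q = _gauss_ref(0.5, 1.0, lim=10.0, n=6001)
        assert kl_divergence(p.x, p.pdf, q) == pytest.approx(0.125, abs=2e-3)

    def test_nonnegative(self, rng):
        ref = reference_distribution(2)
        noisy = np.maximum(ref.pdf + rng.normal(scale=0.01, size=len(ref.pdf)), 0)
        assert kl_divergence(ref.x, noisy, ref) >= 0.0

    def test_disjoint_support_infinite(self):
        ref = _gauss_ref(0.0, 0.1, lim=1.0)
        x = np.linspace(50.0, 60.0, 100)
        p = np.exp(-((x - 55) ** 2))
        with pytest.warns(UserWarning):
            assert kl_divergence(x, p, ref) == math.inf


class TestLiuDeviation:
    def test_identical_is_zero(self):
        ref = reference_distribution(2)
        assert liu_deviation(ref.x, ref.pdf, ref) == pytest.approx(0.0, abs=1e-12)

    def test_unimodal_gives_one(self):
        ref = reference_distribution(2)
        g = _gauss_ref()
        assert liu_deviation(g.x, g.pdf, ref) == pytest.approx(1.0, abs=1e-6)

    def test_scaled_peak_contrast(self):
        ref = reference_distribution(2)
        scaled = UniversalReference(d=2, x=ref.x, pdf=ref.pdf.copy())
        # perturb so the peak-minus-centre contrast is 1.2x the reference
        delta = ref.delta()
        pdf2 = ref.pdf + 0.2 * delta * (ref.pdf == ref.pdf.max())
        assert liu_deviation(ref.x, pdf2, ref) == pytest.approx(0.2, abs=1e-9)

    def test_flat_reference_rejected(self):
        flat = UniversalReference(d=2, x=np.linspace(-1, 1, 11),
                                  pdf=np.full(11, 0.5))
        with pytest.raises(ValueError):
            liu_deviation(flat.x, flat.pdf, flat)


class TestInterfaceFreeEnergy:
    def test_closed_form_peaks(self):
        x = np.linspace(-2, 2, 401)
        Q = np.full_like(x, 1.0)
        Q += (math.e - 1.0) * (np.exp(-((x - 1) ** 2) / 0.01)
                               + np.exp(-((x + 1) ** 2) / 0.01))
        assert interface_free_energy(x, Q) == pytest.approx(1.0, abs=1e-3)

    def test_symmetric_double_gaussian(self):
        # peaks at +-2 sigma_0 separation 4 sigma: analytic mixture values
        x = np.linspace(-5, 5, 4001)
        Q = np.exp(-((x - 2) ** 2) / 2) + np.exp(-((x + 2) ** 2) / 2)
        q_max = (np.exp(0) + np.exp(-8))          # at x = +-2
        q_min = 2 * np.exp(-2)                    # at x = 0
        expect = math.log(q_max / q_min)
        assert interface_free_energy(x, Q) == pytest.approx(expect, abs=1e-3)

    def test_normalisation_invariance(self):
        x = np.linspace(-5, 5, 2001)
        Q = np.exp(-((x - 2) ** 2) / 2) + np.exp(-((x + 2) ** 2) / 2)
        a = interface_free_energy(x, Q)
        b = interface_free_energy(x, 17.3 * Q)
        assert a == pytest.approx(b, rel=1e-12)

    def test_unimodal_rejected(self):
        g = _gauss_ref()
        with pytest.raises(ValueError):
            interface_free_energy(g.x, g.pdf)


class TestReferenceDistributions:
    @pytest.mark.parametrize("d", [2, 3])
    def test_symmetric_zero_mean_unit_variance(self, d):
        ref = reference_distribution(d)
        w = ref.pdf / ref.pdf.sum()
        assert np.sum(w * ref.x) == pytest.approx(0.0, abs=0.02)
        assert np.sum(w * ref.x ** 2) == pytest.approx(1.0, abs=0.03)
        sym = np.interp(-ref.x, ref.x, ref.pdf)
        assert np.max(np.abs(ref.pdf - sym)) < 0.05 * ref.pdf.max()

    def test_2d_is_double_peaked_near_unit_x(self):
        ref = reference_distribution(2)
        peak_x = abs(ref.x[np.argmax(ref.pdf)])
        assert 0.9 < peak_x < 1.4
        assert ref.delta() > 0.5

    def test_3d_flatter_than_2d_between_peaks(self):
        # the 3D fixed-point distribution has a much shallower trough
        assert reference_distribution(3).delta() < \
            0.5 * reference_distribution(2).delta()

    def test_unsupported_dimension(self):
        with pytest.raises(ValueError):
            reference_distribution(4)


class TestCriticalFit:
    def test_parameter_recovery_single_replicate(self):
        s_true, Tc, Pc = 0.2, 1.5, 0.3
        pts = [StatePoint(T=Tc + dt, P=Pc + dp)
               for dt in (-0.02, 0.0, 0.02) for dp in (-0.002, 0.0, 0.002)]
        runs = synthetic_critical_runs(s_true, Tc, Pc, pts, seed=42)
        ue, re_ = common_edges(runs, bins=(100, 100))
        sol = solve_wham([build_histogram(r, ue, re_) for r in runs])
        provider = wham_qn_provider(sol)
        fit = fit_critical_point(
            provider, 200, (Tc + 0.01, Pc - 0.001, 0.1), n_boot=5,
            boot_seed=42,
            bounds={"T": (Tc - 0.05, Tc + 0.05), "P": (Pc - 0.01, Pc + 0.01),
                    "s": (-0.3, 0.8)})
        assert abs(fit.s - s_true) <= 3 * fit.s_err
        assert abs(fit.T_c - Tc) <= 3 * fit.T_c_err
        assert fit.converged

    def test_symmetric_point_is_local_minimum_in_s(self):
        from aquamono.criticality import _asymmetry
        s_true, Tc, Pc = 0.2, 1.5, 0.3
        pts = [StatePoint(T=Tc + dt, P=Pc) for dt in (-0.02, 0.0, 0.02)]
        runs = synthetic_critical_runs(s_true, Tc, Pc, pts, seed=7,
                                       n_per_run=20000)
        ue, re_ = common_edges(runs, bins=(120, 120))
        sol = solve_wham([build_histogram(r, ue, re_) for r in runs])
        provider = wham_qn_provider(sol)
        a0 = _asymmetry(*provider(Tc, Pc, s_true)[:2])
        for ds in (-0.15, 0.15):
            assert _asymmetry(*provider(Tc, Pc, s_true + ds)[:2]) > a0


class TestScalingFits:
    def test_tc_extrapolation_exact(self):
        N = np.array([2500.0, 1e4, 4e4])
        intercept, slope = extrapolate_critical(N, 1.5 + 2.0 * N ** -1.5)
        assert intercept == pytest.approx(1.5, abs=1e-10)
        assert slope == pytest.approx(2.0, rel=1e-10)

    def test_b_slope_planted_exponent(self):
        N = np.geomspace(2500, 4e4, 5)
        slope = b_scaling_exponent(N, 0.31 * N ** (1.0 / 16.0))
        assert slope == pytest.approx(1.0 / 16.0, abs=1e-12)

    def test_piecewise_breakpoint_recovery(self, rng):
        N = np.geomspace(1e3, 1e6, 13)
        y = np.where(N <= 1e4, N ** (2 / 3), 1e4 ** (2 / 3 - 0.5) * N ** 0.5)
        y = y * np.exp(rng.normal(scale=0.02, size=len(N)))
        fit = piecewise_loglog(N, y)
        ratio = max(fit["N_cross"] / 1e4, 1e4 / fit["N_cross"])
        assert ratio < 1.5
        assert fit["slope_small"] == pytest.approx(2 / 3, abs=0.05)
        assert fit["slope_large"] == pytest.approx(0.5, abs=0.05)

    def test_too_few_sizes(self):
        with pytest.raises(ValueError):
            piecewise_loglog(np.array([1e3, 1e4, 1e5]), np.ones(3))
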