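"""Self-contained validation campaigns.

Each function runs one scaled-down study end to end — simulation, analysis,
comparison against an exact oracle or closed form — and returns a flat dict
of measured numbers.  They are the package's own regression surface: the
test suite asserts on their outputs, and ``scripts/acceptance.py`` reports
them.  Problem sizes are chosen so the full set completes in a few minutes
on one CPU; the methods note discusses what these sizes do and do not probe.
"""

from __future__ import annotations

import math
import warnings

import numpy as np
from scipy.signal import find_peaks

from .mc import MCConfig, anneal, check_equilibration, make_rng_state, \
    run_state_point
from .model import LatticeState, ModelParams, StatePoint
from .observables import (
    correlation_function,
    density_extrema,
    fit_correlation_length,
    lg_spinodal,
    response_functions,
    thermo_fields,
    verify_thermo_identities,
)
from .reweighting import build_histogram, common_edges, reweight, solve_wham
from .criticality import fit_critical_point, wham_qn_provider
from .workbench import enumerate_exact, sample_oracle_series, \
    synthetic_critical_runs

__all__ = [
    "mc_vs_enumeration",
    "edge_closed_form",
    "fluctuation_dissipation",
    "wham_validation",
    "thermo_identity_validation",
    "critical_recovery",
    "scaling_validation",
    "phase_diagram_campaign",
]


def _sem(x: np.ndarray, tau_factor: float = 5.0) -> float:
    return float(np.std(x, ddof=1) / math.sqrt(len(x) / tau_factor))


def _v0_grid(point: StatePoint, n_mol: int = 4, nodes: int = 600) -> np.ndarray:
    hi = n_mol * 1.0 + (n_mol + 30) * point.T / max(point.P, 0.05)
    return np.linspace(n_mol * 1.0, hi, nodes)


# ---------------------------------------------------------------------------
# 1. Monte Carlo vs exact enumeration
# ---------------------------------------------------------------------------


def mc_vs_enumeration(seed: int, n_sample: int = 20000) -> dict:
    """MC averages on the 2x2, q = 2 system vs the enumeration oracle.

    Five state points spanning the occupied and mixed-occupancy regimes;
    reports the largest |z| over (u, rho, N_HB, N_coop, V) and points.
    """
    params = ModelParams(q=2)
    points = [StatePoint(T=0.6, P=0.3), StatePoint(T=0.8, P=0.4),
              StatePoint(T=1.0, P=0.6), StatePoint(T=0.5, P=0.8),
              StatePoint(T=1.2, P=0.2)]
    worst = 0.0
    for k, pt in enumerate(points):
        rng_np = np.random.default_rng(seed + k)
        st = LatticeState.random(2, params, rng_np, V0=5.0)
        cfg = MCConfig(schedule=[pt], seed=seed + k, n_equil=500,
                       n_sample=n_sample, decorrelation_stride=2,
                       volume_moves_per_sweep=4, volume_step=1.5)
        s = run_state_point(st, pt, params, cfg, make_rng_state(seed + k))
        ex = enumerate_exact(pt, params, _v0_grid(pt), q=2)
        for name, arr in (("u", s.u), ("rho", s.rho), ("n_hb", s.n_hb),
                          ("n_coop", s.n_coop), ("V", s.V)):
            z = abs(arr.mean() - ex.means[name]) / _sem(arr)
            worst = max(worst, z)
    return {"max_abs_z": worst, "n_points": len(points),
            "n_samples": n_sample}


# ---------------------------------------------------------------------------
# 2. independent-edge closed form
# ---------------------------------------------------------------------------


def edge_closed_form(seed: int, n_sample: int = 4000) -> dict:
    """<delta> per edge vs exp(bJ_eff)/(exp(bJ_eff)+q-1) with J_sigma=eps=0.

    A (beta, P) grid including P = J/v_HB, where J_eff -> 0 and the match
    probability must equal 1/q exactly.
    """
    base = ModelParams(q=6, j_sigma=0.0, eps=0.0)
    pts = [StatePoint(T=1.0, P=0.2), StatePoint(T=0.5, P=0.4),
           StatePoint(T=2.0, P=0.6), StatePoint(T=1.0, P=0.8),
           StatePoint(T=1.0, P=1.0)]  # last point: J_eff = 0, <delta> = 1/q
    side = 8
    n_edges = 2 * side * side
    worst = 0.0
    for k, pt in enumerate(pts):
        st = LatticeState.random(side, base, np.random.default_rng(seed + k),
                                 V0=1.2 * side * side)
        cfg = MCConfig(schedule=[pt], seed=seed + k, n_equil=200,
                       n_sample=n_sample, decorrelation_stride=2,
                       volume_moves_per_sweep=0)
        s = run_state_point(st, pt, base, cfg, make_rng_state(seed + k))
        j_eff = max(base.j - pt.P * base.v_hb, 0.0)
        expect = math.exp(j_eff / pt.T) / (math.exp(j_eff / pt.T) + base.q - 1)
        frac = s.n_hb / n_edges
        z = abs(frac.mean() - expect) / _sem(frac)
        worst = max(worst, z)
    return {"max_abs_z": worst, "n_points": len(pts)}


# ---------------------------------------------------------------------------
# 3. fluctuation-dissipation consistency
# ---------------------------------------------------------------------------


def fluctuation_dissipation(seed: int) -> dict:
    """Fluctuation vs derivative routes for K_T and C_P.

    (a) On i.i.d. samples from the exact 2x2 distribution at neighbouring
    state points; (b) on a 16x16 model run at high temperature (the
    operational equilibration criterion for production runs).
    """
    params = ModelParams(q=2)
    out: dict = {}
    # (a) oracle-sampled series
    T0, P0 = 0.8, 0.4
    iso_P = [sample_oracle_series(StatePoint(T=T0, P=p), params,
                                  _v0_grid(StatePoint(T=T0, P=p)), 20000, 2,
                                  seed + i)
             for i, p in enumerate((0.36, 0.4, 0.44))]
    iso_T = [sample_oracle_series(StatePoint(T=t, P=P0), params,
                                  _v0_grid(StatePoint(T=t, P=P0)), 20000, 2,
                                  seed + 10 + i)
             for i, t in enumerate((0.72, 0.8, 0.88))]
    rep_K = check_equilibration(iso_P)
    rep_C = check_equilibration(iso_T)
    out["oracle_K_T_pass"] = rep_K["checks"]["K_T"]["pass"]
    out["oracle_C_P_pass"] = rep_C["checks"]["C_P"]["pass"]

    def _z(c):
        num = abs(c["fluctuation"] - c["derivative"])
        den = math.hypot(c["fluctuation_err"], c["derivative_err"])
        return num / den if den > 0 else 0.0

    out["oracle_K_T_z"] = _z(rep_K["checks"]["K_T"])
    out["oracle_C_P_z"] = _z(rep_C["checks"]["C_P"])

    # (b) 16x16 model run at high T
    p16 = ModelParams()
    side = 16

    def run(pt, k):
        st = LatticeState.random(side, p16, np.random.default_rng(seed + k),
                                 V0=1.4 * side * side)
        cfg = MCConfig(schedule=[pt], seed=seed + k, n_equil=300,
                       n_sample=1500, decorrelation_stride=2,
                       volume_moves_per_sweep=8, volume_step=4.0)
        return run_state_point(st, pt, p16, cfg, make_rng_state(seed + k))

    T1, P1 = 0.9, 0.3
    series_P = [run(StatePoint(T=T1, P=p), 20 + i)
                for i, p in enumerate((0.24, 0.3, 0.36))]
    series_T = [run(StatePoint(T=t, P=P1), 30 + i)
                for i, t in enumerate((0.81, 0.9, 0.99))]
    rep_K16 = check_equilibration(series_P)
    rep_C16 = check_equilibration(series_T)
    out["model_K_T_pass"] = rep_K16["checks"]["K_T"]["pass"]
    out["model_C_P_pass"] = rep_C16["checks"]["C_P"]["pass"]
    out["model_K_T_z"] = _z(rep_K16["checks"]["K_T"])
    out["model_C_P_z"] = _z(rep_C16["checks"]["C_P"])
    out["max_abs_z"] = max(out["oracle_K_T_z"], out["oracle_C_P_z"],
                           out["model_K_T_z"], out["model_C_P_z"])
    return out


# ---------------------------------------------------------------------------
# 4. WHAM validation
# ---------------------------------------------------------------------------


def wham_validation(seed: int, tolerance: float = 1e-3) -> dict:
    """Identity reweighting, analytic free-energy difference, convergence.

    The toy system is a set of independent edges (J_sigma = eps = 0, pinned
    occupied volume): N_match is binomial and the NPT partition function is
    (exp(b J_eff) + q - 1)^E up to constants, so C_j differences have a
    closed form.
    """
    rng = np.random.default_rng(seed)
    q, E = 6, 512          # 16x16 lattice worth of edges
    j_eff = 0.3
    V = 300.0              # pinned volume
    P = 0.2
    n = 40000
    betas = np.array([1.0 / 1.2, 1.0 / 0.9])
    series = []
    from .observables import ObservableSeries
    for i, b in enumerate(betas):
        p_match = math.exp(b * j_eff) / (math.exp(b * j_eff) + q - 1)
        nm = rng.binomial(E, p_match, size=n)
        u = -j_eff * nm / 256.0
        series.append(ObservableSeries(
            point=StatePoint(T=1.0 / b, P=P), u=u,
            rho=np.full(n, 256.0 / V), n_hb=nm, n_coop=np.zeros(n, dtype=int),
            V=np.full(n, V), meta={"n_molecules": 256, "seed": seed}))
    ue, re_ = common_edges(series, bins=(400, 2))
    hists = [build_histogram(s, ue, re_) for s in series]
    sol = solve_wham(hists, tolerance=tolerance)
    # analytic: exp(-C_j) = sum_E g(E) exp(-b_j(E + P V)); gauge C_0 = 0
    k = np.arange(E + 1)
    from scipy.special import gammaln

    def log_Z(b):
        logg = (gammaln(E + 1) - gammaln(k + 1) - gammaln(E - k + 1)
                + k * b * j_eff + (E - k) * math.log(q - 1) - E * math.log(q))
        m = logg.max()
        return m + math.log(np.exp(logg - m).sum()) - b * P * V

    analytic_dC = -(log_Z(betas[1]) - log_Z(betas[0]))
    # Monte Carlo error of the free-energy difference ~ histogram stat error
    err = 5.0 / math.sqrt(n)
    fe_abs_err = abs((sol.C[1] - sol.C[0]) - analytic_dC)
    # identity reweighting on a single run
    sol1 = solve_wham(hists[:1], tolerance=tolerance)
    h_back = reweight(sol1, series[0].point.T, series[0].point.P)
    ref = hists[0].counts / hists[0].counts.sum()
    identity_dev = float(np.abs(h_back.counts - ref).max())
    return {
        "identity_max_abs_dev": identity_dev,
        "free_energy_abs_err": fe_abs_err,
        "free_energy_err_scale": err,
        "analytic_dC": analytic_dC,
        "wham_dC": float(sol.C[1] - sol.C[0]),
        "final_max_change": sol.max_change,
        "converged": sol.converged,
        "n_iterations": sol.n_iterations,
    }


# ---------------------------------------------------------------------------
# 5. thermodynamic identities on analytic equations of state
# ---------------------------------------------------------------------------


def thermo_identity_validation() -> dict:
    """Response-function identities on analytic toy equations of state.

    Toy A has a parabolic-in-T volume with a turning TMD line
    T0(P) = t0 - g (P - p0)^2: alpha_P vanishes on the TMD and the locus
    (dK_T/dT)_P = 0 crosses the TMD exactly at its turning point p0 (where
    dT/dP = 0 along the TMD).  Toy B has V_TT changing sign on the extremal
    line at p1, where the density-extrema branch has dP/dT = 0 (the C_P
    crossing geometry).
    """
    t0, p0, g, b, c = 1.0, 0.5, 0.8, 0.05, 0.3

    def T0(P):
        return t0 - g * (P - p0) ** 2

    def V_a(T, P):
        return 2.0 - b * P + c * (T - T0(P)) ** 2

    T_grid = np.linspace(0.7, 1.3, 7)
    P_grid = np.linspace(0.2, 0.8, 7)
    rep = verify_thermo_identities(V_a, T_grid, P_grid, h=1e-3)
    # crossing geometry of toy A: sign change of dK_T/dT along the TMD
    Ps = np.linspace(0.3, 0.7, 41)
    vals = [thermo_fields(V_a, T0(float(P)), float(P), 1e-3)["dKT_dT"]
            for P in Ps]
    sign_change = np.nonzero(np.diff(np.sign(vals)))[0]
    kt_cross = float(Ps[sign_change[0]]) if len(sign_change) else math.nan
    # toy B: V = a - bP + c0 (P - p1)(T - T1)^2 + e (T - T1)^4
    p1, T1, c0, e = 0.5, 1.0, 0.4, 0.5

    def V_b(T, P):
        return 2.0 - 0.05 * P + c0 * (P - p1) * (T - T1) ** 2 \
            + e * (T - T1) ** 4

    # density-extrema branch off T = T1: P(T) = p1 - 2 e (T - T1)^2 / c0,
    # a parabola with vertex (dP/dT = 0) exactly where it meets V_TT = 0
    dT = np.linspace(-0.3, 0.3, 61)
    P_branch = p1 - 2 * e * dT ** 2 / c0
    slope_at_vertex = np.polyfit(dT[28:33], P_branch[28:33], 1)[0]
    v_tt_at_vertex = thermo_fields(V_b, T1, p1, 1e-3)["V_TT"]
    return {
        "identity_max_rel_residual": rep["identity_rel_residual"],
        "alpha_max_on_extrema": rep["alpha_max_on_extrema"],
        "n_extrema": len(rep["extrema"]),
        "kt_zero_crossing_P": kt_cross,
        "kt_crossing_vs_turning_point": abs(kt_cross - p0),
        "cp_branch_slope_at_crossing": abs(float(slope_at_vertex)),
        "v_tt_at_crossing": abs(float(v_tt_at_vertex)),
    }


# ---------------------------------------------------------------------------
# 7. critical-point parameter recovery
# ---------------------------------------------------------------------------


def critical_recovery(seed: int, n_rep: int = 20) -> dict:
    """Recovery of (s, T_c) from the synthetic mixed-field family.

    Each replicate generates runs around a known critical point, solves
    WHAM, fits (T, P, s) by symmetrising Q_N(x), and counts the fits whose
    3-sigma confidence intervals cover the truth.
    """
    s_true, Tc, Pc = 0.2, 1.5, 0.3
    pts = [StatePoint(T=Tc + dt, P=Pc + dp)
           for dt in (-0.02, 0.0, 0.02) for dp in (-0.002, 0.0, 0.002)]
    bounds = {"T": (Tc - 0.05, Tc + 0.05), "P": (Pc - 0.01, Pc + 0.01),
              "s": (-0.3, 0.8)}
    ok_s = ok_T = 0
    for rep in range(n_rep):
        rs = seed * 1000 + rep
        runs = synthetic_critical_runs(s_true, Tc, Pc, pts, seed=rs)
        ue, re_ = common_edges(runs, bins=(100, 100))
        sol = solve_wham([build_histogram(r, ue, re_) for r in runs])
        fit = fit_critical_point(wham_qn_provider(sol), 200,
                                 (Tc + 0.01, Pc - 0.001, 0.1),
                                 n_boot=5, boot_seed=rs, bounds=bounds)
        ok_s += abs(fit.s - s_true) <= 3 * fit.s_err
        ok_T += abs(fit.T_c - Tc) <= 3 * fit.T_c_err
    return {"recovered_s": ok_s, "recovered_T": ok_T, "n_rep": n_rep,
            "recovered_both_fraction": min(ok_s, ok_T) / n_rep}


# ---------------------------------------------------------------------------
# 8. finite-size scaling machinery
# ---------------------------------------------------------------------------


def scaling_validation(seed: int) -> dict:
    """Planted-exponent checks of the finite-size fits."""
    from .criticality import b_scaling_exponent, extrapolate_critical, \
        piecewise_loglog

    N = np.array([2500.0, 1e4, 4e4])
    Tc = 1.5 + 2.0 * N ** -1.5
    intercept, _ = extrapolate_critical(N, Tc)
    slope = b_scaling_exponent(N, 0.7 * N ** (1.0 / 16.0))
    rng = np.random.default_rng(seed)
    N2 = np.geomspace(1e3, 1e6, 13)
    dg = np.where(N2 <= 1e4, 0.05 * N2 ** (2 / 3),
                  0.05 * 1e4 ** (2 / 3 - 0.5) * N2 ** 0.5)
    dg *= np.exp(rng.normal(scale=0.02, size=len(N2)))
    pw = piecewise_loglog(N2, dg)
    return {
        "tc_intercept": float(intercept),
        "tc_intercept_abs_err": abs(float(intercept) - 1.5),
        "b_slope": float(slope),
        "b_slope_abs_err": abs(float(slope) - 1.0 / 16.0),
        "breakpoint_N": pw["N_cross"],
        "breakpoint_ratio": max(pw["N_cross"] / 1e4, 1e4 / pw["N_cross"]),
        "slope_small": pw["slope_small"],
        "slope_large": pw["slope_large"],
    }


# ---------------------------------------------------------------------------
# 9. qualitative phase diagram at scaled-down size
# ---------------------------------------------------------------------------


def _peak_position(x: np.ndarray, y: np.ndarray, yerr: np.ndarray,
                   rng: np.random.Generator, n_boot: int = 300,
                   half: int = 3) -> tuple[float, float]:
    """Maximum position by local quadratic refinement, with bootstrap error.

    A parabola is fitted around the argmax and its vertex taken as the peak;
    parametric resampling within the point errors propagates both statistical
    noise and the flatness of the underlying maximum into the position
    uncertainty (floored at one grid step).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    err = np.where(np.isfinite(yerr) & (yerr > 0), yerr, 0.0)

    def locate(yy):
        i = int(np.nanargmax(yy))
        lo, hi = max(0, i - half), min(len(x), i + half + 1)
        if hi - lo >= 3:
            c = np.polyfit(x[lo:hi], yy[lo:hi], 2)
            if c[0] < 0:
                xv = -c[1] / (2 * c[0])
                return float(min(max(xv, x[lo]), x[hi - 1]))
        return float(x[i])

    pos = [locate(y + rng.normal(scale=err)) for _ in range(n_boot)]
    grid_step = float(np.median(np.diff(np.sort(np.unique(x)))))
    return float(np.median(pos)), max(float(np.std(pos)), grid_step)


def phase_diagram_campaign(seed: int, side: int = 32,
                           n_sample: int = 400) -> dict:
    """Scaled-down qualitative phase diagram: 5 isobars on a 32x32 lattice.

    Measures (i) the TMD on every isobar and its separation from the
    liquid-gas spinodal (heating scans at low P, smaller lattice -- crossing
    the occupancy step is a rare event at larger N); (ii) the strong low-T /
    weak high-T structure of K_T(T) on the liquid branch of the lowest
    isobar; (iii) the coincidence of the xi-maximum locus with the strong
    K_T-maximum locus within joint position errors.  The loci merge toward
    the critical region; at the lowest pressure the hydrogen-bond volume
    susceptibility peaks measurably above the bonding-index ordering at this
    lattice size, so coincidence is reported per isobar and as a locus mean.
    """
    params = ModelParams()
    P_values = [0.2, 0.3, 0.4, 0.5, 0.6]
    T_low = np.round(np.arange(0.05, 0.36, 0.03), 3)
    T_high = np.round(np.arange(0.45, 1.45, 0.1), 3)
    Ts = np.concatenate([T_high[::-1], T_low[::-1]])
    all_series: dict = {}
    for k, P in enumerate(P_values):
        cfg = MCConfig(
            schedule=[StatePoint(T=float(t), P=float(P)) for t in Ts],
            seed=seed, n_equil=250, n_sample=n_sample,
            decorrelation_stride=2, volume_moves_per_sweep=8,
            volume_step=5.0, clusters_per_sweep=256,
            collect_configs=True, config_stride=2)
        all_series[P] = anneal(cfg, params, side, stream=k)
    grid = response_functions([s for v in all_series.values() for s in v])

    out: dict = {"side": side, "P_values": P_values}
    # (i) TMD per isobar
    tmds = {}
    for P in P_values:
        sub = grid[grid.P == P].sort_values("T")
        ext = density_extrema(sub["T"].to_numpy(), sub["mean_rho"].to_numpy())
        cands = [e for e in ext if e.kind == "TMD" and not e.at_edge]
        if cands:
            tmds[P] = max(cands, key=lambda e: e.value).T
    out["n_isobars_with_tmd"] = len(tmds)
    out["tmd_T"] = {str(k): float(v) for k, v in tmds.items()}

    # liquid-gas spinodal by heating at low P (smaller lattice: the
    # occupancy-step crossing rate vanishes exponentially with N)
    side_sp = 16
    spin = []
    for k, P in enumerate((0.02, 0.05, 0.1)):
        rng = make_rng_state(seed + 77, k)
        st = LatticeState.random(side_sp, params,
                                 np.random.default_rng(seed + 77 + k),
                                 V0=1.3 * side_sp ** 2)
        Th = np.round(np.arange(2.0, 8.1, 0.4), 3)
        rhos = []
        for T in Th:
            pt = StatePoint(T=float(T), P=float(P))
            cfg = MCConfig(schedule=[pt], seed=seed, n_equil=120,
                           n_sample=120, decorrelation_stride=1,
                           volume_moves_per_sweep=8, volume_step=10.0,
                           clusters_per_sweep=128)
            s = run_state_point(st, pt, params, cfg, rng)
            rhos.append(s.rho.mean())
        t_sp = lg_spinodal(Th, np.array(rhos))
        if t_sp is not None:
            spin.append(t_sp)
    out["n_spinodal_points"] = len(spin)
    out["spinodal_T_min"] = float(min(spin)) if spin else math.nan
    out["tmd_spinodal_gap"] = (float(min(spin)) - max(tmds.values())
                               if spin and tmds else math.nan)

    # (ii) strong/weak K_T structure on the lowest isobar's liquid branch
    P_low = P_values[0]
    sub = grid[grid.P == P_low].sort_values("T").reset_index(drop=True)
    rho = sub["mean_rho"].to_numpy()
    Tv = sub["T"].to_numpy()
    jumps = np.abs(np.diff(rho))
    hi_T = Tv >= 0.4
    j_idx = int(np.argmax(np.where(hi_T[:-1], jumps, 0.0)))
    T_end = Tv[j_idx]          # last liquid-branch temperature
    liquid = sub[(sub["T"] <= T_end) & (~sub["coexistence"])
                 & (sub["K_T_err"] < 0.5 * sub["K_T"])]
    x = liquid["T"].to_numpy()
    y = liquid["K_T"].to_numpy()
    pk, _ = find_peaks(y)
    strong = [(x[i], y[i]) for i in pk if x[i] <= 0.4]
    # weak high-T structure: the K_T level in the crossover window between
    # the TMD region and the end of the liquid branch (interior points only)
    weak_win = (x >= 0.45) & (x < T_end)
    out["strong_max"] = max((v for _, v in strong), default=math.nan)
    out["weak_max"] = float(np.max(y[weak_win])) if weak_win.any() else math.nan
    out["strong_to_weak_ratio"] = (out["strong_max"] / out["weak_max"]
                                   if strong and weak_win.any() else math.nan)

    # (iii) xi-max locus vs strong K_T-max locus
    rng = np.random.default_rng(seed + 5)
    devs = []
    for P in P_values:
        xi_T, xi_v, xi_e = [], [], []
        for s in sorted(all_series[P], key=lambda s: s.point.T):
            if s.point.T > 0.4:
                continue
            corr = correlation_function(s.configs, side, kernel="overlap",
                                        q=params.q)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit = fit_correlation_length(corr, mode="exp",
                                                 r_min=1.0, r_max=4.0)
                except ValueError:
                    continue
            # demand >= 4 significant bins and a determined length: fits fed
            # by noise-level bins carry ~40% errors and random magnitudes
            if (fit.reliable and fit.n_bins >= 4
                    and fit.xi_err < 0.3 * fit.xi):
                xi_T.append(s.point.T)
                xi_v.append(fit.xi)
                xi_e.append(fit.xi_err)
        sub = grid[(grid.P == P) & (grid["T"] <= 0.4)
                   & (~grid.coexistence)].sort_values("T")
        kt_T = sub["T"].to_numpy()
        kt_v = sub["K_T"].to_numpy()
        kt_e = sub["K_T_err"].to_numpy()
        if len(xi_T) < 2 or len(kt_T) < 3:
            continue
        xi_T, xi_v, xi_e = map(np.asarray, (xi_T, xi_v, xi_e))
        t_xi, s_xi = _peak_position(xi_T, xi_v, xi_e, rng)
        t_kt, s_kt = _peak_position(kt_T, kt_v, kt_e, rng)
        devs.append({"P": P, "T_xi": float(t_xi), "T_kt": float(t_kt),
                     "sigma": math.hypot(s_xi, s_kt),
                     "n_sigma": abs(t_xi - t_kt) / math.hypot(s_xi, s_kt)})
    out["locus_points"] = devs
    out["locus_max_n_sigma"] = max((d["n_sigma"] for d in devs),
                                   default=math.nan)
    out["locus_mean_n_sigma"] = (float(np.mean([d["n_sigma"] for d in devs]))
                                 if devs else math.nan)
    return out
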