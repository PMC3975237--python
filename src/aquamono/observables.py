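"""Response functions, correlation lengths and phase-diagram loci.

Fluctuation routes (NPT ensemble, k_B = 1)::

    K_T     = <dV^2> / (T <V>)
    C_P     = <dH^2> / T^2
    alpha_P = <dV dH> / (T^2 <V>)

Derivative routes use centred finite differences of <V> and <H> across
neighbouring state points.  Agreement of the two routes within error is both
an equilibration criterion and a consistency check of the sampler.

The spatial correlation function is built from per-molecule functionals of
the bonding indices, which completely describe the fluctuations of density,
energy and entropy in this model.  The default kernel is the q-vector of
arm-value fractions (an order-parameter-like variable whose connected
correlation tracks the ordering of the hydrogen-bond network); the decay of
G(r) yields the correlation length xi whose maxima define the Widom line
emanating from the liquid-liquid critical point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

__all__ = [
    "ObservableSeries",
    "CorrelationData",
    "CorrelationFit",
    "DensityExtremum",
    "LociSet",
    "response_functions",
    "correlation_function",
    "fit_correlation_length",
    "density_extrema",
    "lg_spinodal",
    "ll_spinodal_from_isochores",
    "extrema_loci",
    "widom_line",
    "loci_coincide",
    "thermo_fields",
    "verify_thermo_identities",
]


# ---------------------------------------------------------------------------
# series container
# ---------------------------------------------------------------------------


@dataclass
class ObservableSeries:
    """Per-sample observables at one state point.

    ``u`` is the energy density (per molecule, in eps), ``rho`` the reduced
    number density rho*v0 in (0, 1], ``V`` the total volume in v0.
    """

    point: "StatePoint"
    u: np.ndarray
    rho: np.ndarray
    n_hb: np.ndarray
    n_coop: np.ndarray
    V: np.ndarray
    meta: dict = field(default_factory=dict)
    configs: list | None = None

    def __post_init__(self) -> None:
        n = len(self.u)
        for name in ("rho", "n_hb", "n_coop", "V"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"sample column {name!r} has mismatched length")

    def __len__(self) -> int:
        return len(self.u)

    @property
    def n_molecules(self) -> int:
        return int(self.meta["n_molecules"])

    def enthalpy_samples(self) -> np.ndarray:
        """H_t = N u_t + P V_t per sample."""
        return self.n_molecules * self.u + self.point.P * self.V

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"u": self.u, "rho": self.rho, "n_hb": self.n_hb,
                             "n_coop": self.n_coop, "V": self.V})


def _jack_blocks(n: int, n_blocks: int) -> list[np.ndarray]:
    return np.array_split(np.arange(n), min(n_blocks, n))


def _jackknife_stat(arrs: tuple[np.ndarray, ...], stat, n_blocks: int = 20):
    """Jackknife estimate/error of ``stat(*arrs)`` deleting sample blocks."""
    n = len(arrs[0])
    blocks = _jack_blocks(n, n_blocks)
    m = len(blocks)
    full = stat(*arrs)
    loo = np.array([stat(*[np.delete(a, b) for a in arrs]) for b in blocks])
    err = math.sqrt(max(0.0, (m - 1) / m * float(np.sum((loo - loo.mean()) ** 2))))
    return float(full), err


def is_bimodal(x: np.ndarray, n_bins: int = 30, prominence: float = 0.03,
               smooth_sigma: float = 1.0, valley: float = 0.6) -> bool:
    """Two-mode detector on a sample histogram (coexistence flag).

    Flags a series as two-phase when its smoothed histogram has two peaks
    separated by a valley lower than ``valley`` times the smaller peak.
    """
    x = np.asarray(x, dtype=float)
    if np.ptp(x) == 0:
        return False
    hist, _ = np.histogram(x, bins=n_bins)
    smooth = ndimage.gaussian_filter1d(hist.astype(float), smooth_sigma)
    peaks, _ = signal.find_peaks(smooth, prominence=prominence * smooth.max())
    if len(peaks) < 2:
        return False
    order = np.argsort(smooth[peaks])[::-1]
    i, j = sorted(peaks[order[:2]])
    return smooth[i:j + 1].min() < valley * min(smooth[i], smooth[j])


# ---------------------------------------------------------------------------
# response functions
# ---------------------------------------------------------------------------


def _point_row(s: ObservableSeries, n_blocks: int) -> dict:
    T, P = s.point.T, s.point.P
    V, H = s.V, s.enthalpy_samples()
    row: dict = {"T": T, "P": P, "n_samples": len(s)}
    row["mean_V"], row["mean_V_err"] = _jackknife_stat((V,), np.mean, n_blocks)
    row["mean_H"], row["mean_H_err"] = _jackknife_stat((H,), np.mean, n_blocks)
    row["mean_u"] = float(np.mean(s.u))
    row["mean_rho"] = float(np.mean(s.rho))
    coexistence = is_bimodal(V) or is_bimodal(H)
    row["coexistence"] = coexistence
    if coexistence:
        # fluctuation route invalid across a two-phase distribution
        for k in ("K_T", "C_P", "alpha_P"):
            row[k], row[k + "_err"] = np.nan, np.nan
        return row
    row["K_T"], row["K_T_err"] = _jackknife_stat(
        (V,), lambda v: np.var(v) / (T * np.mean(v)), n_blocks)
    row["C_P"], row["C_P_err"] = _jackknife_stat(
        (H,), lambda h: np.var(h) / T ** 2, n_blocks)
    row["alpha_P"], row["alpha_P_err"] = _jackknife_stat(
        (V, H),
        lambda v, h: np.mean((v - v.mean()) * (h - h.mean())) / (T ** 2 * np.mean(v)),
        n_blocks)
    return row


def _centered_derivative(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Centred differences on a possibly non-uniform 1D grid (ends one-sided)."""
    return np.gradient(y, x) if len(x) > 1 else np.full_like(y, np.nan)


def response_functions(series_list: list[ObservableSeries],
                       n_blocks: int = 20) -> pd.DataFrame:
    """Fluctuation- and derivative-route response functions on a point set.

    Derivative columns (suffix ``_deriv``) are filled along whichever axes
    have at least two points: K_T from d<V>/dP along isotherms, C_P and
    alpha_P from d<H>/dT and d<V>/dT along isobars.  Points whose V or H
    distribution is clearly bimodal are flagged ``coexistence`` and their
    fluctuation-route values suppressed.
    """
    rows = [_point_row(s, n_blocks) for s in series_list]
    df = pd.DataFrame(rows).sort_values(["P", "T"]).reset_index(drop=True)
    for col in ("K_T_deriv", "C_P_deriv", "alpha_P_deriv"):
        df[col] = np.nan
    for P, sub in df.groupby("P"):
        if len(sub) >= 2:
            idx = sub.index
            T = sub["T"].to_numpy()
            df.loc[idx, "C_P_deriv"] = _centered_derivative(T, sub["mean_H"].to_numpy())
            df.loc[idx, "alpha_P_deriv"] = _centered_derivative(
                T, sub["mean_V"].to_numpy()) / sub["mean_V"].to_numpy()
    for T, sub in df.groupby("T"):
        if len(sub) >= 2:
            idx = sub.sort_values("P").index
            P = df.loc[idx, "P"].to_numpy()
            df.loc[idx, "K_T_deriv"] = -_centered_derivative(
                P, df.loc[idx, "mean_V"].to_numpy()) / df.loc[idx, "mean_V"].to_numpy()
    return df


# ---------------------------------------------------------------------------
# correlation function and correlation length
# ---------------------------------------------------------------------------


@dataclass
class CorrelationData:
    r: np.ndarray
    G: np.ndarray
    G_err: np.ndarray | None = None
    degenerate: bool = False
    side: int = 0


def bonding_order_field(sigma: np.ndarray) -> np.ndarray:
    """Per-molecule scalar s_i: fraction of agreeing index pairs (0..1)."""
    agree = np.zeros(sigma.shape[0], dtype=float)
    for a in range(4):
        for b in range(a + 1, 4):
            agree += sigma[:, a] == sigma[:, b]
    return agree / 6.0


def _overlap_fields(sig: np.ndarray, side: int, q: int) -> np.ndarray:
    """Per-molecule bonding-index overlap vector psi_i (shape (q, L, L)).

    psi_i[k] is the fraction of molecule i's four arms holding index value k;
    the dot product psi_i . psi_l is the probability that a random arm of i
    agrees with a random arm of l, the order-parameter-like kernel of the
    q-state bonding indices.
    """
    n = side * side
    out = np.zeros((q, n))
    for arm in range(4):
        np.add.at(out, (sig[:, arm], np.arange(n)), 0.25)
    return out.reshape(q, side, side)


def correlation_function(configs: list[np.ndarray], side: int,
                         kernel: str = "overlap",
                         q: int | None = None) -> CorrelationData:
    """Connected spatial correlation of a per-molecule bonding field.

    G(r) = [<f_i . f_l>_{|r_il| = r} - |<f>|^2] / [<|f|^2> - |<f>|^2] with
    minimum-image lattice distances; G(0) = 1 by construction.  The bonding
    indices completely determine the configuration, so any per-molecule
    functional of them probes the same correlation length; two kernels are
    provided:

    * ``overlap`` (default): the q-vector psi_i of arm-value fractions,
      whose correlations track the ordering of the hydrogen-bond network
      (the order-parameter-like channel).
    * ``coop``: the scalar fraction of agreeing index pairs within a
      molecule (an energy-like channel; much shorter ranged).

    Requires decorrelated configurations (one (N, 4) sigma array each).
    """
    if len(configs) < 1:
        raise ValueError("need at least one configuration")
    n = side * side
    if q is None:
        q = int(max(int(sig.max()) for sig in configs)) + 1
    acc = np.zeros((side, side))
    per_config = []
    if kernel == "overlap":
        mean_f = np.zeros(q)
        for sig in configs:
            psi = _overlap_fields(sig, side, q)
            corr = np.zeros((side, side))
            for k in range(q):
                f = np.fft.fft2(psi[k])
                corr += np.fft.ifft2(f * np.conj(f)).real / n
            acc += corr
            per_config.append(corr)
            mean_f += psi.reshape(q, -1).mean(axis=1)
        m = len(configs)
        mean_ss = acc / m
        sbar2 = float(np.sum((mean_f / m) ** 2))
        var = float(mean_ss[0, 0] - sbar2)
    elif kernel == "coop":
        s_sum = 0.0
        s2_sum = 0.0
        for sig in configs:
            s = bonding_order_field(sig).reshape(side, side)
            f = np.fft.fft2(s)
            corr = np.fft.ifft2(f * np.conj(f)).real / n
            acc += corr
            per_config.append(corr)
            s_sum += s.mean()
            s2_sum += (s ** 2).mean()
        m = len(configs)
        mean_ss = acc / m
        sbar2 = (s_sum / m) ** 2
        var = s2_sum / m - sbar2
    else:
        raise ValueError("kernel must be 'overlap' or 'coop'")
    # distance binning (minimum image)
    d = np.minimum(np.arange(side), side - np.arange(side))
    r2 = d[:, None] ** 2 + d[None, :] ** 2
    r_vals = np.unique(r2)
    r = np.sqrt(r_vals.astype(float))
    if var <= 1e-14:
        return CorrelationData(r=r, G=np.full_like(r, np.nan),
                               degenerate=True, side=side)
    conn = (mean_ss - sbar2) / var
    G = np.array([conn[r2 == v].mean() for v in r_vals])
    if m >= 4:
        per = np.array([[(c[r2 == v].mean() - sbar2) / var for v in r_vals]
                        for c in per_config])
        G_err = per.std(axis=0, ddof=1) / math.sqrt(m)
    else:
        G_err = None
    return CorrelationData(r=r, G=G, G_err=G_err, side=side)


@dataclass
class CorrelationFit:
    xi: float
    xi_err: float
    mode: str
    eta: float
    window: tuple[float, float]
    amplitude: float
    residual: float
    n_bins: int = 0
    degenerate: bool = False

    @property
    def reliable(self) -> bool:
        """False when xi is beyond reach (ordered phase / system-size scale)."""
        return (not self.degenerate and np.isfinite(self.xi)
                and self.xi > 0 and self.xi <= self.window[1])


def fit_correlation_length(corr: CorrelationData, d: int = 2,
                           mode: str = "exp", eta: float = 0.0,
                           r_min: float = 0.9,
                           r_max: float | None = None) -> CorrelationFit:
    """Weighted least squares for xi in log space.

    ``exp`` mode fits G ~ A exp(-r/xi); ``oz`` (Ornstein-Zernike) mode first
    multiplies G by r^(d-2+eta).  The window defaults to r in
    [r_min, side/4].  Non-positive G values inside the window are dropped
    with a warning.
    """
    if corr.degenerate:
        return CorrelationFit(np.nan, np.nan, mode, eta, (np.nan, np.nan),
                              np.nan, np.nan, degenerate=True)
    if mode not in ("exp", "oz"):
        raise ValueError("mode must be 'exp' or 'oz'")
    if r_max is None:
        r_max = max(corr.side / 4.0, 2.0) if corr.side else float(corr.r.max())
    sel = (corr.r >= r_min) & (corr.r <= r_max)
    r, G = corr.r[sel], corr.G[sel]
    G_err = corr.G_err[sel] if corr.G_err is not None else None
    pos = G > 0
    if G_err is not None:
        # drop bins indistinguishable from zero: fitting log-noise fabricates
        # correlation lengths of order the bin spacing
        pos &= G > 2.0 * G_err
    if not np.all(pos):
        warnings.warn("non-positive G values inside fit window; window shrunk")
        r, G = r[pos], G[pos]
        G_err = G_err[pos] if G_err is not None else None
    if len(r) < 2:
        raise ValueError("fewer than 2 usable distance bins in fit window")
    y = np.log(G) + ((d - 2 + eta) * np.log(r) if mode == "oz" else 0.0)
    if G_err is not None and np.all(G_err > 0):
        w = (G / G_err) ** 2
    else:
        w = np.ones_like(y)
    W = np.sum(w)
    xm = np.sum(w * r) / W
    ym = np.sum(w * y) / W
    sxx = np.sum(w * (r - xm) ** 2)
    slope = np.sum(w * (r - xm) * (y - ym)) / sxx
    intercept = ym - slope * xm
    resid = y - (intercept + slope * r)
    dof = max(len(r) - 2, 1)
    s2 = np.sum(w * resid ** 2) / dof
    slope_err = math.sqrt(s2 / sxx)
    if slope >= 0:
        return CorrelationFit(np.inf, np.nan, mode, eta, (r.min(), r.max()),
                              math.exp(intercept), float(np.sqrt(s2)),
                              n_bins=len(r))
    xi = -1.0 / slope
    xi_err = slope_err / slope ** 2
    return CorrelationFit(float(xi), float(xi_err), mode, eta,
                          (float(r.min()), float(r.max())),
                          float(math.exp(intercept)), float(np.sqrt(s2)),
                          n_bins=len(r))


# ---------------------------------------------------------------------------
# density extrema (TMD / TminD) and spinodals
# ---------------------------------------------------------------------------


@dataclass
class DensityExtremum:
    kind: str          # "TMD" (density maximum) or "TminD"
    T: float
    value: float
    curvature: float
    at_edge: bool = False


def _quad_refine(x: np.ndarray, y: np.ndarray, i: int,
                 half: int = 2) -> tuple[float, float, float]:
    lo, hi = max(0, i - half), min(len(x), i + half + 1)
    c = np.polyfit(x[lo:hi], y[lo:hi], 2)
    if c[0] == 0:
        return x[i], y[i], 0.0
    xv = -c[1] / (2 * c[0])
    xv = min(max(xv, x[lo]), x[hi - 1])
    return float(xv), float(np.polyval(c, xv)), float(2 * c[0])


def density_extrema(T: np.ndarray, rho: np.ndarray,
                    min_points: int = 5) -> list[DensityExtremum]:
    """Locate TMD (local rho maximum) and TminD (local minimum) on an isobar.

    Interior extrema are refined by a local quadratic fit; extrema sitting on
    the window edge are returned flagged ``at_edge`` (unbounded).
    """
    T = np.asarray(T, dtype=float)
    rho = np.asarray(rho, dtype=float)
    order = np.argsort(T)
    T, rho = T[order], rho[order]
    if len(T) < min_points:
        raise ValueError(f"need at least {min_points} points spanning the extremum")
    out: list[DensityExtremum] = []
    for sign, kind in ((1.0, "TMD"), (-1.0, "TminD")):
        peaks, _ = signal.find_peaks(sign * rho)
        for i in peaks:
            tv, rv, curv = _quad_refine(T, rho, i)
            out.append(DensityExtremum(kind=kind, T=tv, value=rv,
                                       curvature=curv,
                                       at_edge=(i <= 1 or i >= len(T) - 2)))
    out.sort(key=lambda e: e.T)
    return out


def lg_spinodal(T: np.ndarray, rho: np.ndarray,
                gas_threshold: float = 0.2) -> float | None:
    """Liquid-gas spinodal estimate on a heating scan of one isobar.

    Returns the temperature of the discontinuous drop of rho below
    ``gas_threshold`` (midpoint of the jump interval), or None if the
    density never collapses.
    """
    T = np.asarray(T, dtype=float)
    rho = np.asarray(rho, dtype=float)
    order = np.argsort(T)
    T, rho = T[order], rho[order]
    below = np.nonzero(rho < gas_threshold)[0]
    if len(below) == 0:
        return None
    j = below[0]
    if j == 0:
        return float(T[0])
    return float(0.5 * (T[j - 1] + T[j]))


def ll_spinodal_from_isochores(isochores: list[tuple[float, np.ndarray, np.ndarray]],
                               ) -> pd.DataFrame:
    """Envelope construction from a fan of isochores.

    Each isochore is (rho, T array, P array).  For each adjacent pair the
    envelope point is where the two P(T) curves come closest (convergence or
    crossing), interpolated on the common T range.
    """
    pts = []
    for (rho1, T1, P1), (rho2, T2, P2) in zip(isochores, isochores[1:]):
        lo = max(T1.min(), T2.min())
        hi = min(T1.max(), T2.max())
        if hi <= lo:
            continue
        Tg = np.linspace(lo, hi, 200)
        d = np.abs(np.interp(Tg, T1, P1) - np.interp(Tg, T2, P2))
        i = int(np.argmin(d))
        pts.append({"T": Tg[i], "P": float(np.interp(Tg[i], T1, P1)),
                    "rho_pair": (rho1, rho2), "gap": float(d[i])})
    return pd.DataFrame(pts)


# ---------------------------------------------------------------------------
# extrema loci of the response functions, Widom line
# ---------------------------------------------------------------------------


@dataclass
class LociSet:
    """Named loci in the (T, P) plane, each a DataFrame (T, P, value, ...)."""

    loci: dict[str, pd.DataFrame] = field(default_factory=dict)

    def __getitem__(self, k: str) -> pd.DataFrame:
        return self.loci[k]

    def names(self) -> list[str]:
        return sorted(self.loci)


def _scan_extrema(x: np.ndarray, y: np.ndarray, minima: bool) -> list[dict]:
    sign = -1.0 if minima else 1.0
    ys = sign * y
    peaks, _ = signal.find_peaks(ys)
    out = []
    base = np.median(ys)
    for i in peaks:
        xv, yv, _ = _quad_refine(x, ys, i)
        out.append({"x": xv, "value": sign * yv, "height": yv - base})
    return out


def extrema_loci(grid: pd.DataFrame, quantities: tuple[str, ...] =
                 ("K_T", "C_P", "alpha_P"), strong_factor: float = 3.0) -> LociSet:
    """Extrema of each response function along isobars and isotherms.

    alpha_P extrema are searched as minima (the anomaly is a negative dip);
    K_T and C_P as maxima.  Within each scan, the tallest peak is 'strong';
    peaks shorter than (tallest / strong_factor) are 'weak'.  Loci names are
    e.g. ``K_T_strong_max_T`` (extrema along T, i.e. on isobars).
    """
    out = LociSet()
    for qty in quantities:
        if qty not in grid.columns:
            continue
        minima = qty == "alpha_P"
        for axis, group_col, scan_col in (("T", "P", "T"), ("P", "T", "P")):
            rows_strong, rows_weak = [], []
            for gval, sub in grid.groupby(group_col):
                sub = sub.sort_values(scan_col)
                y = sub[qty].to_numpy()
                x = sub[scan_col].to_numpy()
                ok = np.isfinite(y)
                if ok.sum() < 5:
                    continue
                found = _scan_extrema(x[ok], y[ok], minima)
                if not found:
                    continue
                hmax = max(f["height"] for f in found)
                for f in found:
                    row = {scan_col: f["x"], group_col: gval, "value": f["value"]}
                    if f["height"] >= hmax / strong_factor:
                        rows_strong.append(row)
                    else:
                        rows_weak.append(row)
            kind = "min" if minima else "max"
            if rows_strong:
                out.loci[f"{qty}_strong_{kind}_{axis}"] = pd.DataFrame(rows_strong)
            if rows_weak:
                out.loci[f"{qty}_weak_{kind}_{axis}"] = pd.DataFrame(rows_weak)
    return out


def widom_line(xi_grid: pd.DataFrame) -> pd.DataFrame:
    """Locus of correlation-length maxima along T, one point per isobar.

    ``xi_grid`` needs columns T, P, xi (and optionally xi_err).  Isobars
    without an interior maximum are excluded.
    """
    rows = []
    for P, sub in xi_grid.groupby("P"):
        sub = sub.sort_values("T")
        T = sub["T"].to_numpy()
        xi = sub["xi"].to_numpy()
        ok = np.isfinite(xi)
        if ok.sum() < 3:
            continue
        T, xi = T[ok], xi[ok]
        i = int(np.argmax(xi))
        if i == 0 or i == len(T) - 1:
            continue
        tv, xv, _ = _quad_refine(T, xi, i)
        row = {"T": tv, "P": P, "xi_max": xv}
        if "xi_err" in sub.columns:
            row["T_err"] = float(np.diff(T).mean())
        rows.append(row)
    return pd.DataFrame(rows)


def loci_coincide(a: pd.DataFrame, b: pd.DataFrame, t_err: float,
                  n_sigma: float = 3.0) -> bool:
    """Do two loci agree in T at common pressures within joint errors?"""
    common = np.intersect1d(a["P"].to_numpy(), b["P"].to_numpy())
    if len(common) == 0:
        return False
    for P in common:
        ta = a.loc[a["P"] == P, "T"].to_numpy().mean()
        tb = b.loc[b["P"] == P, "T"].to_numpy().mean()
        if abs(ta - tb) > n_sigma * t_err:
            return False
    return True


# ---------------------------------------------------------------------------
# thermodynamic identities on a smooth equation of state
# ---------------------------------------------------------------------------


def _partial(f, x, y, h, which: str) -> float:
    """Richardson-extrapolated central difference."""
    def d(hh):
        if which == "x":
            return (f(x + hh, y) - f(x - hh, y)) / (2 * hh)
        return (f(x, y + hh) - f(x, y - hh)) / (2 * hh)
    return (4.0 * d(h / 2) - d(h)) / 3.0


def thermo_fields(V_func, T: float, P: float, h: float = 1e-3) -> dict:
    """K_T, alpha_P and the mixed derivatives entering the identities.

    (dK_T/dT)_P = -(V_TP V - V_P V_T)/V^2 and -(dalpha_P/dP)_T is the same
    expression, so their equality is an exact smoothness identity; evaluating
    both through their own finite-difference routes checks the numerics.
    """
    V = V_func(T, P)

    def KT(t, p):
        return -_partial(V_func, t, p, h, "y") / V_func(t, p)

    def aP(t, p):
        return _partial(V_func, t, p, h, "x") / V_func(t, p)

    return {
        "V": V,
        "K_T": KT(T, P),
        "alpha_P": aP(T, P),
        "dKT_dT": _partial(lambda t, p: KT(t, p), T, P, h, "x"),
        "dalpha_dP": _partial(lambda t, p: aP(t, p), T, P, h, "y"),
        "V_TT": _partial(lambda t, p: _partial(V_func, t, p, h, "x"),
                         T, P, h, "x"),
    }


def verify_thermo_identities(V_func, T_grid: np.ndarray, P_grid: np.ndarray,
                             h: float = 1e-3) -> dict:
    """Check the response-function identities on a smooth V(T, P) surface.

    Reports (a) the maximum relative residual of
    (dK_T/dT)_P = -(dalpha_P/dP)_T over the grid, and (b) the density
    extrema found on each isobar with the value of alpha_P there (zero up to
    the extremum-location error, since alpha_P changes sign at a TMD/TminD).
    """
    resid = []
    scale = []
    for T in T_grid:
        for P in P_grid:
            f = thermo_fields(V_func, float(T), float(P), h)
            resid.append(abs(f["dKT_dT"] + f["dalpha_dP"]))
            scale.append(max(abs(f["dKT_dT"]), abs(f["dalpha_dP"])))
    # normalise by the global derivative scale: both sides vanish together
    # on the symmetry lines of the surface, where a pointwise ratio is 0/0
    rel = float(np.max(resid) / max(np.max(scale), 1e-300))
    extrema_rows = []
    Ts = np.asarray(T_grid, dtype=float)
    for P in P_grid:
        V_iso = np.array([V_func(float(t), float(P)) for t in Ts])
        rho_iso = 1.0 / V_iso
        try:
            ext = density_extrema(Ts, rho_iso)
        except ValueError:
            continue
        for e in ext:
            if e.at_edge:
                continue
            f = thermo_fields(V_func, e.T, float(P), h)
            extrema_rows.append({"kind": e.kind, "T": e.T, "P": float(P),
                                 "alpha_P": f["alpha_P"],
                                 "dKT_dT": f["dKT_dT"], "V_TT": f["V_TT"]})
    extrema = pd.DataFrame(extrema_rows)
    alpha_max = float(extrema["alpha_P"].abs().max()) if len(extrema) else np.nan
    return {"identity_rel_residual": rel, "extrema": extrema,
            "alpha_max_on_extrema": alpha_max}
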