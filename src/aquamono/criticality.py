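"""Mixed-field finite-size scaling of the liquid-liquid critical point.

At a fluid-fluid critical point the ordering field is not the density alone:
the scaling operator is the mixed-field combination ``M = rho* + s u*`` of
the reduced number density and the energy density, with ``s`` the field-
mixing parameter.  At the (size-dependent) critical point the distribution
``Q_N(M)``, rescaled to zero mean and unit variance via
``x = B (M - M_c)``, collapses onto the universal Ising fixed-point
distribution ``P_d(x)`` of the matching dimensionality.

This module locates the apparent critical point by tuning (s, T, P) until
``Q_N(x)`` is symmetric, quantifies its distance from the d = 2 and d = 3
Ising references (Kullback-Leibler divergence and the peak-vs-centre
deviation ``W_d``), measures the interfacial free-energy cost
``Delta G / k_B T_c = ln(Q_max / Q_min)``, and performs the finite-size
extrapolations: T_c(N) and P_c(N) linear in the correction-to-scaling
variable N^-(theta+1)/(2 nu) (theta = 2, nu = 1), B(N) ~ N^(beta / d nu)
(beta = 1/8), and a two-slope fit of Delta G(N) whose breakpoint marks the
2D-3D crossover.

The universal references are generated by Wolff simulation of the standard
Ising model at its critical coupling (2D: beta_c = ln(1 + sqrt 2)/2 exactly;
3D: beta_c = 0.221 654 55) and shipped as versioned text tables; the
seeded regeneration procedure is part of the public API.
"""

from __future__ import annotations

import importlib.resources
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy import optimize, signal

from .mc import _next_u64, _rand01, make_rng_state
from .reweighting import WhamSolution, project_order_parameter, reweight, solve_wham

__all__ = [
    "CriticalFit",
    "UniversalReference",
    "DeviationReport",
    "ISING_BETA_C",
    "mixed_field_series",
    "rescale_distribution",
    "reference_distribution",
    "generate_ising_reference",
    "clb_parameter",
    "kl_divergence",
    "liu_deviation",
    "interface_free_energy",
    "fit_critical_point",
    "wham_qn_provider",
    "extrapolate_critical",
    "b_scaling_exponent",
    "piecewise_loglog",
]

#: exact 2D and literature 3D critical couplings of the n.n. Ising model
ISING_BETA_C = {2: math.log(1.0 + math.sqrt(2.0)) / 2.0, 3: 0.22165455}

#: Ising critical exponents used in the finite-size forms
EXPONENTS = {"beta": 1.0 / 8.0, "nu": 1.0, "theta": 2.0}


# ---------------------------------------------------------------------------
# order parameter and rescaling
# ---------------------------------------------------------------------------


def mixed_field_series(series, s: float) -> np.ndarray:
    """Per-sample order parameter M_t = rho*_t + s u*_t."""
    return series.rho + s * series.u


def rescale_distribution(M: np.ndarray, Q: np.ndarray
                         ) -> tuple[np.ndarray, np.ndarray, float, float]:
    """Affine-rescale a distribution Q(M) to zero mean, unit variance.

    Returns (x grid, Q(x), B, M_c) with x = B (M - M_c), B = 1/std and
    Q(x) = Q(M)/B so the mass is conserved.  Works on a density sampled on
    a uniform M grid.
    """
    M = np.asarray(M, dtype=float)
    Q = np.asarray(Q, dtype=float)
    w = Q / Q.sum()
    m_c = float(np.sum(w * M))
    var = float(np.sum(w * (M - m_c) ** 2))
    if var <= 0:
        raise ValueError("zero-variance distribution cannot be rescaled")
    B = 1.0 / math.sqrt(var)
    x = B * (M - m_c)
    return x, Q / B, B, m_c


# ---------------------------------------------------------------------------
# universal Ising reference distributions
# ---------------------------------------------------------------------------


@dataclass
class UniversalReference:
    """Tabulated critical order-parameter distribution P_d(x)."""

    d: int
    x: np.ndarray
    pdf: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __call__(self, xq: np.ndarray) -> np.ndarray:
        return np.interp(xq, self.x, self.pdf, left=0.0, right=0.0)

    def delta(self) -> float:
        """Peak height minus the value at x = 0."""
        return float(self.pdf.max() - self(np.array([0.0]))[0])


def _ising_neighbours(L: int, d: int) -> np.ndarray:
    shape = (L,) * d
    n = L ** d
    idx = np.arange(n).reshape(shape)
    nbr = np.empty((n, 2 * d), dtype=np.int64)
    for ax in range(d):
        nbr[:, 2 * ax] = np.roll(idx, -1, axis=ax).reshape(-1)
        nbr[:, 2 * ax + 1] = np.roll(idx, 1, axis=ax).reshape(-1)
    return nbr


@njit(cache=True)
def _ising_wolff(spins, nbr, p_add, n_clusters, sample_every, rng, mags):
    n = spins.shape[0]
    stack = np.empty(n, dtype=np.int64)
    k = 0
    for step in range(n_clusters):
        seed = int(_next_u64(rng) % np.uint64(n))
        s0 = spins[seed]
        spins[seed] = -s0
        stack[0] = seed
        sp = 1
        while sp > 0:
            sp -= 1
            i = stack[sp]
            for jj in range(nbr.shape[1]):
                b = nbr[i, jj]
                if spins[b] == s0 and _rand01(rng) < p_add:
                    spins[b] = -s0
                    stack[sp] = b
                    sp += 1
        if (step + 1) % sample_every == 0:
            tot = 0
            for i in range(n):
                tot += spins[i]
            mags[k] = tot
            k += 1
    return k


def generate_ising_reference(d: int, L: int | None = None,
                             n_clusters: int = 200_000,
                             sample_every: int = 2, seed: int = 2014,
                             n_bins: int = 121) -> UniversalReference:
    """Simulate the critical Ising model and tabulate its rescaled P(m).

    The magnetization histogram at beta_c, rescaled to unit variance and
    symmetrized (the Hamiltonian is Z2-symmetric), approximates the
    universal fixed-point distribution on moderate lattices.
    """
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if L is None:
        L = 48 if d == 2 else 12
    beta_c = ISING_BETA_C[d]
    p_add = 1.0 - math.exp(-2.0 * beta_c)
    nbr = _ising_neighbours(L, d)
    n = L ** d
    rng = make_rng_state(seed, stream=d)
    spins = np.ones(n, dtype=np.int8)
    # warm up
    warm = np.empty(1, dtype=np.int64)
    _ising_wolff(spins, nbr, p_add, 2000, 2001, rng, warm)
    mags = np.empty(n_clusters // sample_every, dtype=np.int64)
    k = _ising_wolff(spins, nbr, p_add, n_clusters, sample_every, rng, mags)
    m = mags[:k].astype(float) / n
    m = np.concatenate([m, -m])  # symmetrize
    std = m.std()
    x = m / std
    lim = min(np.abs(x).max(), 4.5)
    hist, edges = np.histogram(x, bins=n_bins, range=(-lim, lim), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return UniversalReference(
        d=d, x=centers, pdf=hist,
        provenance={"L": L, "beta_c": beta_c, "n_clusters": n_clusters,
                    "sample_every": sample_every, "seed": seed})


def _data_path(name: str):
    return importlib.resources.files("aquamono").joinpath("data", name)


def reference_distribution(d: int, regenerate: bool = False,
                           **kwargs) -> UniversalReference:
    """Packaged universal P_d(x) table, or a fresh seeded regeneration."""
    if d not in (2, 3):
        raise ValueError("d must be 2 or 3")
    if regenerate:
        return generate_ising_reference(d, **kwargs)
    path = _data_path(f"ising_universal_{d}d.tsv")
    prov: dict = {}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                if ":" in line:
                    k, v = line.lstrip("# ").split(":", 1)
                    prov[k.strip()] = v.strip()
                continue
            if line:
                rows.append([float(t) for t in line.split("\t")])
    arr = np.asarray(rows)
    return UniversalReference(d=d, x=arr[:, 0], pdf=arr[:, 1], provenance=prov)


# ---------------------------------------------------------------------------
# bimodality diagnostics
# ---------------------------------------------------------------------------


def clb_parameter(M: np.ndarray, weights: np.ndarray | None = None,
                  n_blocks: int = 20) -> tuple[float, float]:
    """Challa-Landau-Binder parameter U_M = 1 - <M^4> / (3 <M^2>^2).

    Non-centred moments; tends to 2/3 for any point mass (no coexistence)
    and drops below 2/3 when Q_N(M) is bimodal.  Returns (U_M, jackknife
    error); the error is zero when explicit distribution weights are given.
    """
    M = np.asarray(M, dtype=float)
    if weights is not None:
        w = np.asarray(weights, dtype=float)
        w = w / w.sum()
        m2 = float(np.sum(w * M ** 2))
        if m2 == 0:
            raise ValueError("all-zero order parameter")
        m4 = float(np.sum(w * M ** 4))
        return 1.0 - m4 / (3.0 * m2 ** 2), 0.0
    if np.all(M == 0):
        raise ValueError("all-zero order parameter")

    def stat(x):
        m2 = np.mean(x ** 2)
        return 1.0 - np.mean(x ** 4) / (3.0 * m2 ** 2)

    n = len(M)
    blocks = np.array_split(np.arange(n), min(n_blocks, n))
    full = stat(M)
    loo = np.array([stat(np.delete(M, b)) for b in blocks])
    nb = len(blocks)
    err = math.sqrt(max(0.0, (nb - 1) / nb * float(np.sum((loo - loo.mean()) ** 2))))
    return float(full), err


def kl_divergence(x: np.ndarray, p: np.ndarray, ref: UniversalReference,
                  floor: float = 1e-12) -> float:
    """D_KL(P_N || P_d) on the P_N grid, in nats.

    Both distributions are converted to bin masses on the common x grid;
    the reference is floored at ``floor`` to keep the sum finite, and a
    genuinely disjoint support returns +inf with a warning.
    """
    x = np.asarray(x, dtype=float)
    p = np.asarray(p, dtype=float)
    dx = np.diff(x).mean() if len(x) > 1 else 1.0
    pm = p * dx
    pm = pm / pm.sum()
    qm = ref(x) * dx
    if qm.sum() <= 0 or np.all(qm[pm > 0] <= 0):
        warnings.warn("disjoint supports: KL divergence is infinite")
        return float("inf")
    qm = np.maximum(qm / qm.sum(), floor)
    sel = pm > 0
    return float(np.sum(pm[sel] * np.log(pm[sel] / qm[sel])))


def liu_deviation(x: np.ndarray, p: np.ndarray, ref: UniversalReference) -> float:
    """Relative peak-vs-centre deviation W_d.

    Delta(P) = max(P) - P(0); W_d = |Delta(P_N) - Delta(P_d)| / Delta(P_d).
    Zero when the shapes agree; 1 for a unimodal P_N centred at 0.
    """
    d_ref = ref.delta()
    if d_ref <= 0:
        raise ValueError("reference has no peak-centre contrast (Delta = 0)")
    p0 = float(np.interp(0.0, x, p))
    d_p = float(np.max(p) - p0)
    return abs(d_p - d_ref) / d_ref


def interface_free_energy(x: np.ndarray, Q: np.ndarray) -> float:
    """ln(Q_max / Q_min): free-energy cost of the liquid-liquid interface.

    Q_max is the mean of the two peak heights (they differ only by sampling
    noise), Q_min the minimum between them.  Requires a bimodal input.
    Invariant under renormalisation of Q.
    """
    Q = np.asarray(Q, dtype=float)
    peaks, props = signal.find_peaks(Q, prominence=0.01 * Q.max())
    if len(peaks) < 2:
        raise ValueError("unimodal distribution: no interface to measure")
    order = np.argsort(Q[peaks])[::-1]
    i, j = sorted(peaks[order[:2]])
    q_max = 0.5 * (Q[i] + Q[j])
    q_min = Q[i:j + 1].min()
    if q_min <= 0:
        return float("inf")
    return float(math.log(q_max / q_min))


# ---------------------------------------------------------------------------
# critical-point fit
# ---------------------------------------------------------------------------


@dataclass
class CriticalFit:
    n_molecules: int
    s: float
    T_c: float
    P_c: float
    B: float
    M_c: float
    asymmetry: float
    d_kl: dict[int, float]
    s_err: float = np.nan
    T_c_err: float = np.nan
    P_c_err: float = np.nan
    converged: bool = True
    x: np.ndarray | None = None
    Q: np.ndarray | None = None


@dataclass
class DeviationReport:
    n_molecules: int
    d_kl: dict[int, float]
    w_d: dict[int, float]
    delta_g: float
    better_dimension: int


def wham_qn_provider(sol: WhamSolution):
    """Q_N(x) provider over (T, P, s) backed by a WHAM solution."""

    def provider(T: float, P: float, s: float):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            h = reweight(sol, T, P)
        M, Q = project_order_parameter(h, s)
        return rescale_distribution(M, Q)

    return provider


def _asymmetry(x: np.ndarray, Q: np.ndarray) -> float:
    """Integrated |Q(x) - Q(-x)| / 2 over the common support."""
    Qm = np.interp(-x, x, Q, left=0.0, right=0.0)
    dx = np.diff(x).mean() if len(x) > 1 else 1.0
    return 0.5 * float(np.sum(np.abs(Q - Qm)) * dx)


def fit_critical_point(provider, n_molecules: int, start: tuple[float, float, float],
                       references: dict[int, UniversalReference] | None = None,
                       steps: tuple[float, float, float] = (0.01, 0.01, 0.05),
                       bounds: dict | None = None,
                       n_boot: int = 0, boot_seed: int = 0,
                       maxiter: int = 400) -> CriticalFit:
    """Locate the apparent critical point by symmetrising Q_N(x).

    Stage one minimises the asymmetry of Q_N(x) over (T, P, s) from ``start``
    with a Nelder-Mead simplex scaled by ``steps``; stage two evaluates the
    distance (D_KL) to each supplied universal reference at the optimum.
    ``provider(T, P, s)`` must return (x, Q, B, M_c); use
    :func:`wham_qn_provider` for simulation data.  Optional multinomial
    bootstrap of the provider is delegated to the caller via refits; here
    ``n_boot`` jitters the starting simplex to estimate optimiser spread.
    """
    lo = {"T": 0.0, "P": -np.inf, "s": -np.inf}
    hi = {"T": np.inf, "P": np.inf, "s": np.inf}
    if bounds:
        for k, (a, b) in bounds.items():
            lo[k], hi[k] = a, b

    def objective(theta):
        T, P, s = theta
        if not (lo["T"] < T < hi["T"] and lo["P"] <= P <= hi["P"]
                and lo["s"] <= s <= hi["s"]):
            return 1e6
        try:
            x, Q, _, _ = provider(T, P, s)
        except (ValueError, FloatingPointError):
            return 1e6
        return _asymmetry(x, Q)

    def run_fit(x0):
        simplex = [np.asarray(x0, dtype=float)]
        for k in range(3):
            v = np.asarray(x0, dtype=float).copy()
            v[k] += steps[k]
            simplex.append(v)
        res = optimize.minimize(objective, x0, method="Nelder-Mead",
                                options={"initial_simplex": np.array(simplex),
                                         "xatol": 1e-5, "fatol": 1e-7,
                                         "maxiter": maxiter})
        return res

    res = run_fit(np.asarray(start, dtype=float))
    T_c, P_c, s_fit = res.x
    x, Q, B, M_c = provider(T_c, P_c, s_fit)
    dkl = {}
    if references:
        for d, ref in references.items():
            dkl[d] = kl_divergence(x, Q, ref)
    errs = (np.nan, np.nan, np.nan)
    if n_boot > 0:
        rng = np.random.default_rng(boot_seed)
        sols = []
        for _ in range(n_boot):
            x0 = res.x + rng.normal(scale=np.asarray(steps)) * 2.0
            r = run_fit(x0)
            sols.append(r.x)
        spread = np.std(np.asarray(sols), axis=0, ddof=1)
        errs = tuple(float(max(e, st / 2)) for e, st in zip(spread, steps))
    converged = bool(res.success) and all(
        lo[k] + 1e-9 < v < hi[k] - 1e-9 or not np.isfinite(lo[k]) or
        not np.isfinite(hi[k])
        for k, v in zip(("T", "P", "s"), res.x))
    return CriticalFit(n_molecules=n_molecules, s=float(s_fit), T_c=float(T_c),
                       P_c=float(P_c), B=float(B), M_c=float(M_c),
                       asymmetry=float(res.fun), d_kl=dkl,
                       T_c_err=errs[0], P_c_err=errs[1], s_err=errs[2],
                       converged=converged, x=x, Q=Q)


def deviation_report(x: np.ndarray, Q: np.ndarray, n_molecules: int,
                     references: dict[int, UniversalReference]) -> DeviationReport:
    """D_KL and W_d against each reference, plus the interface cost."""
    dkl = {d: kl_divergence(x, Q, r) for d, r in references.items()}
    wd = {d: liu_deviation(x, Q, r) for d, r in references.items()}
    try:
        dg = interface_free_energy(x, Q)
    except ValueError:
        dg = float("nan")
    better = min(dkl, key=dkl.get)
    return DeviationReport(n_molecules=n_molecules, d_kl=dkl, w_d=wd,
                           delta_g=dg, better_dimension=better)


# ---------------------------------------------------------------------------
# finite-size scaling fits
# ---------------------------------------------------------------------------


def extrapolate_critical(N: np.ndarray, y: np.ndarray,
                         theta: float = 2.0, nu: float = 1.0
                         ) -> tuple[float, float]:
    """Linear extrapolation of T_c(N) or P_c(N) to N -> infinity.

    The abscissa is the correction-to-scaling variable L^-(theta+1)/nu with
    L = sqrt(N), i.e. N^-(theta+1)/(2 nu) (= N^-3/2 at the 2D Ising values).
    Returns (intercept, slope).
    """
    N = np.asarray(N, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(N) < 2:
        raise ValueError("need at least 2 sizes")
    xvar = N ** (-(theta + 1.0) / (2.0 * nu))
    slope, intercept = np.polyfit(xvar, y, 1)
    return float(intercept), float(slope)


def b_scaling_exponent(N: np.ndarray, B: np.ndarray) -> float:
    """Log-log slope of B(N); compare with beta/(d nu) (1/16 in 2D)."""
    N = np.asarray(N, dtype=float)
    B = np.asarray(B, dtype=float)
    if len(N) < 2:
        raise ValueError("need at least 2 sizes")
    slope, _ = np.polyfit(np.log(N), np.log(B), 1)
    return float(slope)


def piecewise_loglog(N: np.ndarray, y: np.ndarray,
                     n_grid: int = 200) -> dict:
    """Continuous two-slope fit of log y vs log N with one breakpoint.

    Model: log y = a + s1 * t + (s2 - s1) * max(t - t_b, 0), t = log N.
    The breakpoint is grid-searched; returns both slopes and the crossover
    size N_cross = exp(t_b).
    """
    N = np.asarray(N, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(N) < 4:
        raise ValueError("need at least 4 sizes for a breakpoint fit")
    t = np.log(N)
    z = np.log(y)
    order = np.argsort(t)
    t, z = t[order], z[order]
    best = None
    for tb in np.linspace(t[1], t[-2], n_grid):
        X = np.column_stack([np.ones_like(t), t, np.maximum(t - tb, 0.0)])
        coef, res, *_ = np.linalg.lstsq(X, z, rcond=None)
        sse = float(np.sum((X @ coef - z) ** 2))
        if best is None or sse < best[0]:
            best = (sse, tb, coef)
    sse, tb, coef = best
    return {"slope_small": float(coef[1]),
            "slope_large": float(coef[1] + coef[2]),
            "N_cross": float(math.exp(tb)),
            "sse": sse}
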