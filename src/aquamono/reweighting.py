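"""Multiple-histogram reweighting over (u, rho) in the NPT ensemble.

Each run i at (beta_i, P_i) contributes a 2D histogram h_i(u, rho) on shared
bin edges, where u is the energy density and rho the reduced number density
rho*v0; a bin maps back to extensive microstate descriptors E = N u and
V = N v0 / rho.  The combined (unnormalised) density-of-states estimate is::

    Omega(b) = sum_i h_i(b) / sum_j N_j exp(C_j - beta_j (E_b + P_j V_b))

with the constants C_j (beta_j times the Gibbs free energy of run j, up to a
common gauge) determined self-consistently from::

    exp(-C_j) = sum_b Omega(b) exp(-beta_j (E_b + P_j V_b)).

The fixed point is iterated from C_j = 0 until the maximum change drops
below a tolerance (default 1e-3), entirely in log space so that the
exponentials never overflow at large N.  Reweighting to a nearby (beta', P')
then weights Omega by exp(-beta' (E + P' V)).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .observables import ObservableSeries

__all__ = [
    "Histogram2D",
    "WhamSolution",
    "build_histogram",
    "common_edges",
    "solve_wham",
    "reweight",
    "gibbs_along_isotherm",
    "project_order_parameter",
    "save_histograms",
    "load_histograms",
]


def save_histograms(path, histograms: list["Histogram2D"]) -> None:
    """Store a run set of histograms in one hierarchical (HDF5) container."""
    import h5py

    with h5py.File(path, "w") as fh:
        for k, h in enumerate(histograms):
            h.save(fh.create_group(f"run_{k:03d}"))


def load_histograms(path) -> list["Histogram2D"]:
    import h5py

    with h5py.File(path, "r") as fh:
        return [Histogram2D.load(fh[k]) for k in sorted(fh.keys())]


@dataclass
class Histogram2D:
    """Binned joint distribution over (u, rho) with run metadata."""

    u_edges: np.ndarray
    rho_edges: np.ndarray
    counts: np.ndarray          # shape (n_u, n_rho)
    T: float
    P: float
    n_samples: int
    n_molecules: int
    v0: float = 1.0
    meta: dict = field(default_factory=dict)

    @property
    def u_centers(self) -> np.ndarray:
        return 0.5 * (self.u_edges[:-1] + self.u_edges[1:])

    @property
    def rho_centers(self) -> np.ndarray:
        return 0.5 * (self.rho_edges[:-1] + self.rho_edges[1:])

    def normalized(self) -> np.ndarray:
        tot = self.counts.sum()
        return self.counts / tot if tot > 0 else self.counts

    def save(self, h5group) -> None:
        for k in ("u_edges", "rho_edges", "counts"):
            h5group.create_dataset(k, data=getattr(self, k))
        for k in ("T", "P", "n_samples", "n_molecules", "v0"):
            h5group.attrs[k] = getattr(self, k)

    @classmethod
    def load(cls, h5group) -> "Histogram2D":
        return cls(u_edges=h5group["u_edges"][...],
                   rho_edges=h5group["rho_edges"][...],
                   counts=h5group["counts"][...],
                   T=float(h5group.attrs["T"]), P=float(h5group.attrs["P"]),
                   n_samples=int(h5group.attrs["n_samples"]),
                   n_molecules=int(h5group.attrs["n_molecules"]),
                   v0=float(h5group.attrs["v0"]))


def common_edges(series_list: list[ObservableSeries],
                 bins: tuple[int, int] = (200, 200),
                 pad: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Shared (u, rho) bin edges covering all runs, padded by ``pad``."""
    u_all = np.concatenate([s.u for s in series_list])
    r_all = np.concatenate([s.rho for s in series_list])

    def padded(lo, hi):
        span = max(hi - lo, 1e-12)
        return lo - pad * span, hi + pad * span

    ulo, uhi = padded(u_all.min(), u_all.max())
    rlo, rhi = padded(r_all.min(), r_all.max())
    return np.linspace(ulo, uhi, bins[0] + 1), np.linspace(rlo, rhi, bins[1] + 1)


def build_histogram(series: ObservableSeries,
                    u_edges: np.ndarray | None = None,
                    rho_edges: np.ndarray | None = None,
                    bins: tuple[int, int] = (200, 200),
                    v0: float = 1.0) -> Histogram2D:
    """Histogram one run's (u, rho) samples on given or self-derived edges."""
    if len(series) == 0:
        raise ValueError("empty series")
    if u_edges is None or rho_edges is None:
        u_edges, rho_edges = common_edges([series], bins)
    counts, _, _ = np.histogram2d(series.u, series.rho,
                                  bins=(u_edges, rho_edges))
    return Histogram2D(u_edges=u_edges, rho_edges=rho_edges, counts=counts,
                       T=series.point.T, P=series.point.P,
                       n_samples=len(series),
                       n_molecules=series.n_molecules, v0=v0,
                       meta=dict(series.meta))


@dataclass
class WhamSolution:
    """Converged constants C_i and the combined density-of-states estimate."""

    C: np.ndarray                # gauge-fixed: C[0] = 0
    log_omega: np.ndarray        # shape (n_u, n_rho); -inf on empty bins
    u_edges: np.ndarray
    rho_edges: np.ndarray
    n_molecules: int
    v0: float
    runs: list[tuple[float, float, int]]   # (T_i, P_i, N_i)
    n_iterations: int
    max_change: float
    converged: bool
    trace: list[float] = field(default_factory=list)

    @property
    def u_centers(self) -> np.ndarray:
        return 0.5 * (self.u_edges[:-1] + self.u_edges[1:])

    @property
    def rho_centers(self) -> np.ndarray:
        return 0.5 * (self.rho_edges[:-1] + self.rho_edges[1:])


def _bin_EV(u_centers, rho_centers, n_molecules, v0):
    shape = (len(u_centers), len(rho_centers))
    E = np.broadcast_to(n_molecules * u_centers[:, None], shape)
    V = np.broadcast_to(n_molecules * v0 / rho_centers[None, :], shape)
    return E, V


def solve_wham(histograms: list[Histogram2D], tolerance: float = 1e-3,
               max_iter: int = 100_000) -> WhamSolution:
    """Self-consistent solution of the multiple-histogram equations.

    Starts from C_i = 0 and iterates until max_i |C_i^(k+1) - C_i^(k)| <
    ``tolerance``; the result is gauge-fixed to C_0 = 0.  Non-overlapping
    run supports make the iteration diverge; this is detected and reported.
    """
    if not histograms:
        raise ValueError("need at least one histogram")
    h0 = histograms[0]
    for h in histograms[1:]:
        if not (np.array_equal(h.u_edges, h0.u_edges)
                and np.array_equal(h.rho_edges, h0.rho_edges)):
            raise ValueError("histograms must share bin edges (use common_edges)")
    m = len(histograms)
    E, V = _bin_EV(h0.u_centers, h0.rho_centers, h0.n_molecules, h0.v0)
    total = np.sum([h.counts for h in histograms], axis=0)
    occupied = total > 0
    log_total = np.where(occupied, np.log(np.maximum(total, 1e-300)), -np.inf)
    betas = np.array([1.0 / h.T for h in histograms])
    Ps = np.array([h.P for h in histograms])
    Ns = np.array([float(h.n_samples) for h in histograms])
    # log w_j(b) = -beta_j (E_b + P_j V_b), shifted by a common gauge per bin
    log_w = np.stack([-betas[j] * (E + Ps[j] * V) for j in range(m)])
    C = np.zeros(m)
    trace: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        denom = logsumexp(np.log(Ns)[:, None, None] + C[:, None, None] + log_w,
                          axis=0)
        log_omega = np.where(occupied, log_total - denom, -np.inf)
        new_C = np.empty(m)
        for j in range(m):
            lz = logsumexp((log_omega + log_w[j])[occupied])
            new_C[j] = -lz
        new_C -= new_C[0]  # gauge
        change = float(np.max(np.abs(new_C - C)))
        trace.append(change)
        C = new_C
        if not np.isfinite(change):
            raise RuntimeError(
                "WHAM iteration diverged: runs likely have non-overlapping "
                "(u, rho) supports")
        if change < tolerance:
            converged = True
            break
    denom = logsumexp(np.log(Ns)[:, None, None] + C[:, None, None] + log_w,
                      axis=0)
    log_omega = np.where(occupied, log_total - denom, -np.inf)
    if not converged:
        warnings.warn(f"WHAM did not converge in {max_iter} iterations "
                      f"(last change {trace[-1]:.3g})")
    return WhamSolution(C=C, log_omega=log_omega,
                        u_edges=h0.u_edges, rho_edges=h0.rho_edges,
                        n_molecules=h0.n_molecules, v0=h0.v0,
                        runs=[(h.T, h.P, h.n_samples) for h in histograms],
                        n_iterations=it, max_change=trace[-1] if trace else 0.0,
                        converged=converged, trace=trace)


def _log_weights(sol: WhamSolution, beta: float, P: float) -> np.ndarray:
    E, V = _bin_EV(sol.u_centers, sol.rho_centers, sol.n_molecules, sol.v0)
    return sol.log_omega - beta * (E + P * V)


def reweight(sol: WhamSolution, T: float, P: float,
             ess_warn_fraction: float = 0.01) -> Histogram2D:
    """Normalised joint (u, rho) distribution at a new state point.

    The counts array holds probabilities (summing to one).  A Kish effective
    sample size far below the pooled sample count triggers a warning: the
    target point is too far from the simulated ones.
    """
    beta = 1.0 / T
    lw = _log_weights(sol, beta, P)
    finite = np.isfinite(lw)
    if not finite.any():
        raise ValueError("no support: all bins empty")
    lz = logsumexp(lw[finite])
    prob = np.zeros_like(lw)
    prob[finite] = np.exp(lw[finite] - lz)
    n_pool = sum(n for _, _, n in sol.runs)
    ess = 1.0 / np.sum(prob[finite] ** 2)
    if ess < ess_warn_fraction * min(n_pool, prob[finite].size):
        warnings.warn(f"low effective sample size at (T={T}, P={P}): "
                      f"ESS = {ess:.1f}")
    h = Histogram2D(u_edges=sol.u_edges, rho_edges=sol.rho_edges,
                    counts=prob, T=T, P=P, n_samples=n_pool,
                    n_molecules=sol.n_molecules, v0=sol.v0,
                    meta={"reweighted": True, "ess": float(ess)})
    return h


def reweighted_moments(sol: WhamSolution, T: float, P: float) -> dict:
    """First moments and fluctuation-route response functions at (T, P)."""
    h = reweight(sol, T, P)
    p = h.counts
    E, V = _bin_EV(h.u_centers, h.rho_centers, h.n_molecules, h.v0)
    H = E + P * V
    mV = float(np.sum(p * V))
    mH = float(np.sum(p * H))
    varV = float(np.sum(p * (V - mV) ** 2))
    varH = float(np.sum(p * (H - mH) ** 2))
    covVH = float(np.sum(p * (V - mV) * (H - mH)))
    return {
        "u": float(np.sum(p * (E / h.n_molecules))),
        "rho": float(np.sum(p * (h.n_molecules * h.v0 / V))),
        "V": mV, "H": mH,
        "K_T": varV / (T * mV),
        "C_P": varH / T ** 2,
        "alpha_P": covVH / (T ** 2 * mV),
        "ess": h.meta["ess"],
    }


def gibbs_along_isotherm(sol: WhamSolution, T: float,
                         P_values: np.ndarray) -> "pd.DataFrame":
    """Gibbs free energy G(P) on an isotherm, shifted to 0 at the lowest P.

    G(T, P) = -T ln sum_b Omega(b) exp(-beta (E_b + P V_b)) up to a
    P-independent constant; the numerical dG/dP and the reweighted <V> are
    both reported so the thermodynamic identity V = dG/dP can be verified.
    """
    import pandas as pd

    beta = 1.0 / T
    P_values = np.sort(np.asarray(P_values, dtype=float))
    G = np.empty_like(P_values)
    mV = np.empty_like(P_values)
    for k, P in enumerate(P_values):
        lw = _log_weights(sol, beta, P)
        finite = np.isfinite(lw)
        G[k] = -T * logsumexp(lw[finite])
        E, V = _bin_EV(sol.u_centers, sol.rho_centers, sol.n_molecules, sol.v0)
        prob = np.exp(lw[finite] + G[k] / T)
        mV[k] = np.sum(prob * V[finite])
    G -= G[0]
    dGdP = np.gradient(G, P_values)
    return pd.DataFrame({"P": P_values, "G": G, "dG_dP": dGdP, "mean_V": mV})


def project_order_parameter(hist: Histogram2D, s: float,
                            n_bins: int | None = None
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Project the joint (u, rho) distribution onto M = rho* + s u*.

    Integrates the joint density along the direction perpendicular to the
    line rho + s u, i.e. histograms the bin centres' M values weighted by
    their probabilities.  Returns (M bin centres, probability density with
    unit total mass).  s = 0 recovers the rho marginal.
    """
    p = hist.normalized()
    M = hist.rho_centers[None, :] + s * hist.u_centers[:, None]
    M = np.broadcast_to(M, p.shape).ravel()
    w = p.ravel()
    if M.max() == M.min():
        warnings.warn("degenerate single-bin input: delta output")
        return np.array([M[0]]), np.array([1.0])
    span = M.max() - M.min()
    if n_bins is None:
        du = hist.u_edges[1] - hist.u_edges[0]
        drho = hist.rho_edges[1] - hist.rho_edges[0]
        width = math.hypot(drho, s * du)
        n_bins = max(int(round(span / max(width, 1e-300))) + 1, 1)
        n_bins = min(n_bins, 4 * max(len(hist.u_centers), len(hist.rho_centers)))
    # anchor edges so input values sit at bin centres (no half-bin shift)
    width = span / max(n_bins - 1, 1)
    edges = M.min() - 0.5 * width + width * np.arange(n_bins + 1)
    mass, _ = np.histogram(M, bins=edges, weights=w)
    centers = 0.5 * (edges[:-1] + edges[1:])
    density = mass / (mass.sum() * width)
    return centers, density
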