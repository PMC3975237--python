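"""NPT cluster Monte Carlo for the monolayer model.

Sampling alternates two kinds of moves:

* **Cluster updates of the bonding indices** (Wolff-type).  A random arm is
  seeded; same-valued arms join the cluster across intra-molecular links with
  probability ``1 - exp(-beta * J_sigma)`` and across inter-molecular (facing)
  links with probability ``1 - exp(-beta * J_eff)``, where
  ``J_eff = max(J - P * v_HB, 0)`` and facing links are active only while the
  cells are occupied.  The whole cluster is then relabelled to a uniformly
  chosen different index value.  Folding the bond-volume enthalpy ``P * v_HB``
  into the link coupling makes the move rejection-free in the NPT ensemble:
  the sigma-conditional stationary weight is exactly
  ``exp(beta * (J - P v_HB) * n * N_match + beta * J_sigma * N_coop)``.

* **Volume moves.**  ``V0`` takes a symmetric uniform step, accepted with the
  Metropolis rule on the full enthalpy change (isotropic energy, mechanical
  work ``P dV0``, and -- when the occupancy flag flips -- the hydrogen-bond
  term ``-(J - P v_HB) dN_HB``).  Proposals below the hard-core bound
  ``N * v0`` are rejected outright.

Randomness comes from an explicit splitmix64 counter generator so every run
is bit-reproducible from (seed, stream) alone.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import (
    HardCoreViolation,
    LatticeState,
    ModelParams,
    StatePoint,
    lattice_shells,
    neighbour_table,
)
from .observables import ObservableSeries

__all__ = [
    "MCConfig",
    "cluster_sweep",
    "volume_move",
    "run_state_point",
    "anneal",
    "check_equilibration",
    "integrated_autocorr_time",
]

_U64 = np.uint64


# ---------------------------------------------------------------------------
# splitmix64 counter RNG (numba-side)
# ---------------------------------------------------------------------------


@njit(cache=True, inline="always")
def _next_u64(state):
    state[0] = state[0] + _U64(0x9E3779B97F4A7C15)
    z = state[0]
    z = (z ^ (z >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> _U64(27))) * _U64(0x94D049BB133111EB)
    return z ^ (z >> _U64(31))


@njit(cache=True, inline="always")
def _rand01(state):
    return float(_next_u64(state) >> _U64(11)) * (1.0 / 9007199254740992.0)


def make_rng_state(seed: int, stream: int = 0) -> np.ndarray:
    """64-bit splitmix state from a small seed and a stream id."""
    mix = (int(seed) * 0x9E3779B97F4A7C15 + int(stream) * 0xD1B54A32D192ED03)
    return np.array([mix & 0xFFFFFFFFFFFFFFFF], dtype=np.uint64)


# ---------------------------------------------------------------------------
# kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _u_iso_kernel(ell, dists, mults, r0, rc, eps):
    tot = 0.0
    for k in range(dists.shape[0]):
        r = ell * dists[k]
        if r <= rc:
            x6 = (r0 / r) ** 6
            tot += mults[k] * (x6 * x6 - x6)
    return eps * tot


@njit(cache=True)
def _count_match(sig_flat, partner):
    tot = 0
    for a in range(sig_flat.shape[0]):
        b = partner[a]
        if b > a and sig_flat[a] == sig_flat[b]:
            tot += 1
    return tot


@njit(cache=True)
def _count_coop(sig_flat):
    n_mol = sig_flat.shape[0] // 4
    tot = 0
    for i in range(n_mol):
        base = 4 * i
        for a in range(4):
            for b in range(a + 1, 4):
                if sig_flat[base + a] == sig_flat[base + b]:
                    tot += 1
    return tot


@njit(cache=True)
def _sigma_sweep(sig_flat, partner, q, p_intra, p_inter, n_clusters,
                 rng, stack, members, in_cl):
    """n_clusters single-cluster Wolff updates; returns total flipped arms."""
    n_arms = sig_flat.shape[0]
    flipped = 0
    for _ in range(n_clusters):
        seed = int(_next_u64(rng) % _U64(n_arms))
        old = sig_flat[seed]
        shift = 1 + int(_next_u64(rng) % _U64(q - 1))
        newv = (old + shift) % q
        sp = 0
        msize = 0
        stack[sp] = seed
        sp += 1
        in_cl[seed] = True
        members[msize] = seed
        msize += 1
        while sp > 0:
            sp -= 1
            a = stack[sp]
            base = (a // 4) * 4
            if p_intra > 0.0:
                for b in range(base, base + 4):
                    if b != a and not in_cl[b] and sig_flat[b] == old:
                        if _rand01(rng) < p_intra:
                            in_cl[b] = True
                            stack[sp] = b
                            sp += 1
                            members[msize] = b
                            msize += 1
            if p_inter > 0.0:
                b = partner[a]
                if not in_cl[b] and sig_flat[b] == old:
                    if _rand01(rng) < p_inter:
                        in_cl[b] = True
                        stack[sp] = b
                        sp += 1
                        members[msize] = b
                        msize += 1
        for k in range(msize):
            a = members[k]
            sig_flat[a] = newv
            in_cl[a] = False
        flipped += msize
    return flipped


@njit(cache=True)
def _volume_moves(V0, u_iso, n_match, n_mol, dists, mults, r0, rc, eps, v0,
                  occ_vol, j, v_hb, beta, P, step, n_moves, fv_exp, rng):
    """Metropolis volume moves; returns (V0, u_iso, accepted).

    ``fv_exp`` is the exponent of the translational measure V0^fv_exp
    (N with free-volume entropy on, 0 for the bare measure).
    """
    acc = 0
    vmin = n_mol * v0
    for _ in range(n_moves):
        v_new = V0 + (2.0 * _rand01(rng) - 1.0) * step
        if v_new < vmin:
            continue
        ell = math.sqrt(v_new / n_mol)
        u_new = _u_iso_kernel(ell, dists, mults, r0, rc, eps) if eps != 0.0 else 0.0
        n_old = 1 if V0 < occ_vol else 0
        n_new = 1 if v_new < occ_vol else 0
        dh = (u_new - u_iso) + P * (v_new - V0)
        if n_new != n_old:
            dh += (n_new - n_old) * (-j + P * v_hb) * n_match
        log_acc = -beta * dh + fv_exp * math.log(v_new / V0)
        if log_acc >= 0.0 or _rand01(rng) < math.exp(log_acc):
            V0 = v_new
            u_iso = u_new
            acc += 1
    return V0, u_iso, acc


# ---------------------------------------------------------------------------
# python-level moves (thin wrappers used directly in tests)
# ---------------------------------------------------------------------------


def _partner_table(side: int) -> np.ndarray:
    nbr = neighbour_table(side)
    opp = np.array([1, 0, 3, 2])
    n = side * side
    partner = np.empty(4 * n, dtype=np.int64)
    for arm in range(4):
        partner[4 * np.arange(n) + arm] = 4 * nbr[:, arm] + opp[arm]
    return partner


def link_probabilities(point: StatePoint, params: ModelParams,
                       occupied: int) -> tuple[float, float]:
    """(p_intra, p_inter) for the cluster move at this state point."""
    beta = point.beta
    p_intra = 1.0 - math.exp(-beta * params.j_sigma)
    j_eff = max(params.j - point.P * params.v_hb, 0.0)
    p_inter = (1.0 - math.exp(-beta * j_eff)) if occupied else 0.0
    return p_intra, p_inter


def cluster_sweep(state: LatticeState, point: StatePoint, params: ModelParams,
                  rng: np.ndarray, n_clusters: int | None = None) -> int:
    """One cluster sweep (one Wolff seed per arm by default), in place."""
    sig = np.ascontiguousarray(state.sigma.reshape(-1))
    partner = _partner_table(state.side)
    p_intra, p_inter = link_probabilities(point, params, state.occupancy)
    n_arms = sig.shape[0]
    if n_clusters is None:
        n_clusters = n_arms
    stack = np.empty(n_arms, dtype=np.int64)
    members = np.empty(n_arms, dtype=np.int64)
    in_cl = np.zeros(n_arms, dtype=np.bool_)
    flipped = _sigma_sweep(sig, partner, params.q, p_intra, p_inter,
                           n_clusters, rng, stack, members, in_cl)
    state.sigma = sig.reshape(state.sigma.shape)
    return flipped


def volume_move(state: LatticeState, point: StatePoint, params: ModelParams,
                rng: np.ndarray, step: float, n_moves: int = 1) -> int:
    """Metropolis volume moves on V0, in place; returns acceptances."""
    from .model import count_matching_edges, total_isotropic_energy

    n_mol = state.n_molecules
    dists, mults = lattice_shells(state.side)
    u_iso = total_isotropic_energy(state.V0, n_mol, state.side, params)
    n_match = count_matching_edges(state.sigma, state.side)
    occ_vol = n_mol * params.v0 / params.occupancy_threshold
    fv_exp = float(n_mol) if params.free_volume_entropy else 0.0
    V0, _, acc = _volume_moves(
        state.V0, u_iso, n_match, n_mol, dists, mults, params.r0,
        params.r_cut * params.r0, params.eps, params.v0, occ_vol,
        params.j, params.v_hb, point.beta, point.P, step, n_moves,
        fv_exp, rng)
    state.V0 = V0
    return acc


# ---------------------------------------------------------------------------
# sampling protocol
# ---------------------------------------------------------------------------


@dataclass
class MCConfig:
    """Sampling protocol: one output series per state point in ``schedule``."""

    schedule: list[StatePoint]
    seed: int = 1
    n_equil: int = 500
    n_sample: int = 1000
    decorrelation_stride: int | None = None  # None -> estimate from tau_int
    volume_step: float = 1.0
    volume_moves_per_sweep: int = 4
    clusters_per_sweep: int | None = None    # None -> one per arm
    collect_configs: bool = False
    config_stride: int = 1

    def __post_init__(self) -> None:
        if self.n_sample <= 0:
            raise ValueError("n_sample must be > 0")
        if self.volume_step <= 0:
            raise ValueError("volume_step must be > 0")


def integrated_autocorr_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time with Sokal's adaptive window."""
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 8 or np.var(x) == 0:
        return 1.0
    xc = x - x.mean()
    f = np.fft.rfft(xc, n=2 * n)
    acf = np.fft.irfft(f * np.conjugate(f))[:n].real
    acf /= acf[0]
    tau = 1.0
    for m in range(1, n // 2):
        tau += 2.0 * acf[m]
        if m >= c * tau:
            break
    return max(tau, 1.0)


class _PointSampler:
    """Drives one state point: tuning, equilibration, sampling."""

    def __init__(self, state: LatticeState, point: StatePoint,
                 params: ModelParams, cfg: MCConfig, rng: np.ndarray):
        self.state, self.point, self.params, self.cfg = state, point, params, cfg
        self.rng = rng
        self.step = cfg.volume_step
        n_arms = 4 * state.n_molecules
        self.n_clusters = cfg.clusters_per_sweep or n_arms
        self._stack = np.empty(n_arms, dtype=np.int64)
        self._members = np.empty(n_arms, dtype=np.int64)
        self._in_cl = np.zeros(n_arms, dtype=np.bool_)
        self._partner = _partner_table(state.side)
        self._dists, self._mults = lattice_shells(state.side)
        self._sig = np.ascontiguousarray(state.sigma.reshape(-1))
        from .model import total_isotropic_energy
        self._u_iso = total_isotropic_energy(
            state.V0, state.n_molecules, state.side, params)
        self._occ_vol = state.n_molecules * params.v0 / params.occupancy_threshold

    @property
    def occupied(self) -> int:
        return 1 if self.state.V0 < self._occ_vol else 0

    def sweep(self) -> int:
        p = self.params
        pt = self.point
        p_intra, p_inter = link_probabilities(pt, p, self.occupied)
        _sigma_sweep(self._sig, self._partner, p.q, p_intra, p_inter,
                     self.n_clusters, self.rng, self._stack, self._members,
                     self._in_cl)
        n_match = _count_match(self._sig, self._partner)
        fv_exp = float(self.state.n_molecules) if p.free_volume_entropy else 0.0
        V0, u_iso, acc = _volume_moves(
            self.state.V0, self._u_iso, n_match, self.state.n_molecules,
            self._dists, self._mults, p.r0, p.r_cut * p.r0, p.eps, p.v0,
            self._occ_vol, p.j, p.v_hb, pt.beta, pt.P, self.step,
            self.cfg.volume_moves_per_sweep, fv_exp, self.rng)
        self.state.V0, self._u_iso = V0, u_iso
        return acc

    def measure(self) -> tuple[float, float, int, int, float]:
        p = self.params
        n_mol = self.state.n_molecules
        n_match = _count_match(self._sig, self._partner)
        n_coop = _count_coop(self._sig)
        n_hb = self.occupied * n_match
        V = self.state.V0 + n_hb * p.v_hb
        u = (self._u_iso - p.j * n_hb - p.j_sigma * n_coop) / n_mol
        rho = n_mol * p.v0 / V
        return u, rho, n_hb, n_coop, V

    def equilibrate(self) -> tuple[float, list[float]]:
        """Tune the volume step, relax, and record u for stride estimation."""
        cfg = self.cfg
        u_trace: list[float] = []
        batch = max(20, cfg.n_equil // 10)
        done = 0
        while done < cfg.n_equil:
            todo = min(batch, cfg.n_equil - done)
            acc = 0
            for _ in range(todo):
                acc += self.sweep()
                u_trace.append(self.measure()[0])
            done += todo
            rate = acc / max(1, todo * cfg.volume_moves_per_sweep)
            # steer toward 30-50% acceptance while relaxing
            if done < cfg.n_equil:
                if rate > 0.5:
                    self.step *= 1.25
                elif rate < 0.3:
                    self.step = max(self.step * 0.8, 1e-6)
        return self.step, u_trace

    def finish_state(self) -> LatticeState:
        self.state.sigma = self._sig.reshape(self.state.sigma.shape)
        return self.state


def run_state_point(state: LatticeState, point: StatePoint,
                    params: ModelParams, cfg: MCConfig,
                    rng: np.ndarray) -> ObservableSeries:
    """Equilibrate and sample one state point; mutates ``state`` in place."""
    sampler = _PointSampler(state, point, params, cfg, rng)
    _, u_trace = sampler.equilibrate()
    if cfg.decorrelation_stride is None:
        tail = np.asarray(u_trace[len(u_trace) // 2:])
        stride = int(min(50, max(1, math.ceil(
            2.0 * integrated_autocorr_time(tail)))))
    else:
        stride = cfg.decorrelation_stride
    n = cfg.n_sample
    u = np.empty(n)
    rho = np.empty(n)
    n_hb = np.empty(n, dtype=np.int64)
    n_coop = np.empty(n, dtype=np.int64)
    V = np.empty(n)
    configs = [] if cfg.collect_configs else None
    for t in range(n):
        for _ in range(stride):
            sampler.sweep()
        u[t], rho[t], n_hb[t], n_coop[t], V[t] = sampler.measure()
        if configs is not None and t % cfg.config_stride == 0:
            configs.append(sampler._sig.reshape(-1, 4).copy())
    sampler.finish_state()
    meta = {"n_molecules": state.n_molecules, "side": state.side,
            "seed": cfg.seed, "stride": stride,
            "volume_step": sampler.step}
    return ObservableSeries(point=point, u=u, rho=rho, n_hb=n_hb,
                            n_coop=n_coop, V=V, meta=meta, configs=configs)


def anneal(cfg: MCConfig, params: ModelParams, side: int,
           initial_state: LatticeState | None = None,
           stream: int = 0) -> list[ObservableSeries]:
    """Run the state-point schedule, chaining final states.

    The schedule is meant to be ordered from high to low T within each
    isobar (annealing from a random high-T start); the final configuration
    at each point seeds the next one.
    """
    rng = make_rng_state(cfg.seed, stream)
    np_rng = np.random.default_rng(cfg.seed + 1_000_003 * stream)
    state = initial_state or LatticeState.random(side, params, np_rng)
    out = []
    for k, point in enumerate(cfg.schedule):
        series = run_state_point(state, point, params, cfg, rng)
        series.meta["schedule_index"] = k
        series.meta["stream"] = stream
        out.append(series)
        if not np.isfinite(series.V).all() or (series.V <= 0).any():
            raise HardCoreViolation(
                f"state point {point} produced unphysical volumes")
    return out


# ---------------------------------------------------------------------------
# equilibration check (fluctuation-dissipation)
# ---------------------------------------------------------------------------


def _jackknife(samples: np.ndarray, stat, n_blocks: int = 20):
    samples = np.asarray(samples)
    n = samples.shape[-1]
    n_blocks = min(n_blocks, n)
    blocks = np.array_split(np.arange(n), n_blocks)
    full = stat(samples)
    loo = np.array([stat(np.delete(samples, b, axis=-1)) for b in blocks])
    err = math.sqrt(max(0.0, (n_blocks - 1) / n_blocks *
                        float(np.sum((loo - loo.mean(axis=0)) ** 2))))
    return full, err


def check_equilibration(series_list: list[ObservableSeries],
                        n_blocks: int = 20, n_sigma: float = 3.0) -> dict:
    """Fluctuation-dissipation consistency across neighbouring state points.

    Given at least three series along one axis of the (T, P) plane, compares
    the fluctuation-route response at the middle point with the centred
    finite difference of the conjugate first moment: ``K_T`` against
    ``-(1/<V>) d<V>/dP`` on isotherms, ``C_P`` against ``d<H>/dT`` on
    isobars.  Passing this check is the operational definition of
    equilibration used throughout the package.
    """
    if len(series_list) < 3:
        raise ValueError("need at least 3 series at neighbouring state points")
    T_vals = np.array([x.point.T for x in series_list])
    P_vals = np.array([x.point.P for x in series_list])
    along_T = np.ptp(T_vals) > 0
    along_P = np.ptp(P_vals) > 0
    if along_T and along_P:
        raise ValueError("series must vary along a single axis (T or P)")
    series_list = sorted(series_list,
                         key=lambda s: s.point.P if along_P else s.point.T)
    T_vals = np.array([x.point.T for x in series_list])
    P_vals = np.array([x.point.P for x in series_list])
    mid = len(series_list) // 2
    s = series_list[mid]
    T, P = s.point.T, s.point.P
    H = s.enthalpy_samples()
    report: dict = {"point": s.point, "checks": {}}

    def compare(name, fluct, fluct_err, deriv, deriv_err):
        sigma = math.hypot(fluct_err, deriv_err)
        ok = abs(fluct - deriv) <= n_sigma * sigma if sigma > 0 else \
            math.isclose(fluct, deriv)
        report["checks"][name] = {
            "fluctuation": fluct, "fluctuation_err": fluct_err,
            "derivative": deriv, "derivative_err": deriv_err,
            "pass": bool(ok)}

    if along_P:
        order = np.argsort(P_vals)
        lo, hi = series_list[order[mid - 1]], series_list[order[mid + 1]]
        kt_f, kt_fe = _jackknife(
            s.V, lambda v: np.var(v) / (T * np.mean(v)), n_blocks)
        dP = hi.point.P - lo.point.P
        vbar = float(np.mean(s.V))

        meanV_lo, e_lo = _jackknife(lo.V, np.mean, n_blocks)
        meanV_hi, e_hi = _jackknife(hi.V, np.mean, n_blocks)
        kt_d = -(meanV_hi - meanV_lo) / dP / vbar
        kt_de = math.hypot(e_lo, e_hi) / abs(dP) / vbar
        compare("K_T", kt_f, kt_fe, kt_d, kt_de)
    else:
        order = np.argsort(T_vals)
        lo, hi = series_list[order[mid - 1]], series_list[order[mid + 1]]
        cp_f, cp_fe = _jackknife(H, lambda h: np.var(h) / T ** 2, n_blocks)
        dT = hi.point.T - lo.point.T
        meanH_lo, e_lo = _jackknife(lo.enthalpy_samples(), np.mean, n_blocks)
        meanH_hi, e_hi = _jackknife(hi.enthalpy_samples(), np.mean, n_blocks)
        cp_d = (meanH_hi - meanH_lo) / dT
        cp_de = math.hypot(e_lo, e_hi) / abs(dT)
        compare("C_P", cp_f, cp_fe, cp_d, cp_de)
    report["pass"] = all(c["pass"] for c in report["checks"].values())
    return report
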