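"""Configuration, exact-enumeration oracles, synthetic fixtures and pipeline.

Everything here exists so the physics modules can be exercised and validated
without long simulations:

* :func:`enumerate_exact` sums the Boltzmann weights of *every* configuration
  of a tiny lattice (side 2, reduced q) over a quadrature grid in V0 and
  returns exact averages and response functions -- the reference against
  which the Monte Carlo sampler and the fluctuation formulas are checked.
  :func:`enumerate_bruteforce` is an independent second implementation
  (plain loop over all states through the public energy functions) used for
  double-entry validation of the oracle itself.
* :func:`synthetic_series` produces observable series with prescribed
  statistical structure (Gaussian, double-Gaussian, Ising-like, drifted,
  constant) so every analysis stage has fast fixture-driven tests.
* :func:`synthetic_critical_runs` emulates a family of runs around a known
  mixed-field critical point, for parameter-recovery tests of the
  finite-size-scaling fit.
* :class:`RunConfig` + :func:`run_pipeline` tie simulate -> observables ->
  reweighting together behind one structured-text config file.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import math
import tomllib
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np

from .model import (
    ModelParams,
    StatePoint,
    count_cooperative,
    count_matching_edges,
    occupancy_from_volume,
    total_isotropic_energy,
)
from .observables import ObservableSeries

__all__ = [
    "OracleResult",
    "enumerate_exact",
    "enumerate_bruteforce",
    "sigma_density_of_states",
    "synthetic_series",
    "synthetic_critical_runs",
    "RunConfig",
    "run_pipeline",
    "write_series",
    "read_series",
]


# ---------------------------------------------------------------------------
# exact enumeration oracle (2x2 lattice, reduced q)
# ---------------------------------------------------------------------------


@dataclass
class OracleResult:
    """Exact ensemble averages and response functions at one state point."""

    point: StatePoint
    log_Z: float
    means: dict
    response: dict
    n_molecules: int = 4

    def __getitem__(self, k: str):
        return self.means[k]


def _molecule_states(q: int) -> np.ndarray:
    return np.array(list(itertools.product(range(q), repeat=4)), dtype=np.int64)


def sigma_density_of_states(q: int) -> np.ndarray:
    """Joint density of states g[N_match, N_coop] of the 2x2 sigma lattice.

    With periodic boundaries on a 2x2 lattice each pair of neighbouring
    molecules is connected by two facing-arm edges (8 edges total), so with
    molecule states s0..s3 (arm order +x, -x, +y, -y) and pair match counts
    h(A, B) = d(A0, B1) + d(A1, B0), v(A, B) = d(A2, B3) + d(A3, B2)::

        N_match = h(s0, s1) + h(s2, s3) + v(s0, s2) + v(s1, s3)

    The sum of g equals q^16.  N_match <= 8, N_coop <= 24.
    """
    if not 2 <= q <= 3:
        raise ValueError("enumeration supports q in {2, 3} (state space q^16)")
    st = _molecule_states(q)
    m = len(st)
    coop = np.zeros(m, dtype=np.int64)
    for a in range(4):
        for b in range(a + 1, 4):
            coop += st[:, a] == st[:, b]
    h = ((st[:, 0][:, None] == st[:, 1][None, :]).astype(np.int64)
         + (st[:, 1][:, None] == st[:, 0][None, :]).astype(np.int64))
    v = ((st[:, 2][:, None] == st[:, 3][None, :]).astype(np.int64)
         + (st[:, 3][:, None] == st[:, 2][None, :]).astype(np.int64))
    g = np.zeros(9 * 25, dtype=np.float64)
    # axes of the vectorised block: (s1, s2, s3)
    coop_123 = (coop[:, None, None] + coop[None, :, None] + coop[None, None, :])
    for s0 in range(m):
        nm = (h[s0][:, None, None]        # h(s0, s1)
              + h[None, :, :]             # h(s2, s3)
              + v[s0][None, :, None]      # v(s0, s2)
              + v[:, None, :])            # v(s1, s3)
        nc = coop[s0] + coop_123
        idx = (nm * 25 + nc).ravel()
        g += np.bincount(idx, minlength=9 * 25)
    return g.reshape(9, 25)


def _oracle_tables(point: StatePoint, params: ModelParams,
                   v0_grid: np.ndarray, g: np.ndarray):
    """Per-(grid node, DOS bin) log-weights and observable values."""
    n_mol = 4
    v0_grid = np.atleast_1d(np.asarray(v0_grid, dtype=float))
    if len(v0_grid) > 1:
        dx = np.gradient(v0_grid)
        quad_w = dx.copy()
        quad_w[0] *= 0.5
        quad_w[-1] *= 0.5
    else:
        quad_w = np.ones(1)
    nm_vals, nc_vals = np.nonzero(g)
    g_vals = g[nm_vals, nc_vals]
    rows = []
    beta = point.beta
    fv_exp = float(n_mol) if params.free_volume_entropy else 0.0
    for V0, w in zip(v0_grid, quad_w):
        n = occupancy_from_volume(V0, n_mol, params)
        U = total_isotropic_energy(V0, n_mol, 2, params)
        n_hb = n * nm_vals
        E = U - params.j * n_hb - params.j_sigma * nc_vals
        V = V0 + n_hb * params.v_hb
        H = E + point.P * V
        logw = (np.log(g_vals) - beta * H + math.log(w)
                + fv_exp * math.log(V0 / (n_mol * params.v0)))
        rows.append((logw, E / n_mol, n_mol * params.v0 / V,
                     n_hb.astype(float), nc_vals.astype(float), V, H,
                     nm_vals.astype(float)))
    logw = np.concatenate([r[0] for r in rows])
    cols = {name: np.concatenate([r[i] for r in rows])
            for i, name in enumerate(
                ("logw", "u", "rho", "n_hb", "n_coop", "V", "H", "n_match"))
            if i > 0}
    return logw, cols


def enumerate_exact(point: StatePoint, params: ModelParams,
                    v0_grid: np.ndarray, q: int | None = None,
                    g: np.ndarray | None = None,
                    derivative_step: float = 1e-4) -> OracleResult:
    """Exact NPT averages of the 2x2 system by exhaustive summation.

    The sigma sum runs over all q^16 configurations (via the density of
    states); the continuous V0 is handled by trapezoid quadrature on
    ``v0_grid`` (a single node pins the volume).  Response functions are
    returned by both the exact fluctuation route and centred numerical
    derivatives of the enumerated averages.
    """
    if g is None:
        g = sigma_density_of_states(q if q is not None else params.q)

    def moments(pt: StatePoint) -> dict:
        logw, cols = _oracle_tables(pt, params, v0_grid, g)
        shift = logw.max()
        w = np.exp(logw - shift)
        Z = w.sum()
        out = {k: float(np.sum(w * v) / Z) for k, v in cols.items()}
        for k in ("V", "H"):
            out[f"{k}2"] = float(np.sum(w * cols[k] ** 2) / Z)
        out["VH"] = float(np.sum(w * cols["V"] * cols["H"]) / Z)
        out["log_Z"] = float(math.log(Z) + shift)
        return out

    mom = moments(point)
    T = point.T
    varV = mom["V2"] - mom["V"] ** 2
    varH = mom["H2"] - mom["H"] ** 2
    covVH = mom["VH"] - mom["V"] * mom["H"]
    response = {
        "K_T": varV / (T * mom["V"]),
        "C_P": varH / T ** 2,
        "alpha_P": covVH / (T ** 2 * mom["V"]),
    }
    dP = derivative_step * max(abs(point.P), 1.0)
    dT = derivative_step * T
    m_pp = moments(StatePoint(T, point.P + dP))
    m_pm = moments(StatePoint(T, point.P - dP))
    m_tp = moments(StatePoint(T + dT, point.P))
    m_tm = moments(StatePoint(T - dT, point.P))
    response["K_T_deriv"] = -(m_pp["V"] - m_pm["V"]) / (2 * dP) / mom["V"]
    response["C_P_deriv"] = (m_tp["H"] - m_tm["H"]) / (2 * dT)
    response["alpha_P_deriv"] = (m_tp["V"] - m_tm["V"]) / (2 * dT) / mom["V"]
    means = {k: mom[k] for k in
             ("u", "rho", "n_hb", "n_coop", "V", "H", "n_match")}
    # per-edge match probability, not gated by occupancy
    means["edge_match"] = means["n_match"] / 8.0
    return OracleResult(point=point, log_Z=mom["log_Z"], means=means,
                        response=response)


def enumerate_bruteforce(point: StatePoint, params: ModelParams,
                         v0_grid: np.ndarray, q: int = 2) -> dict:
    """Independent double-entry oracle: plain loop over all sigma states.

    Uses the public counting/energy functions configuration by
    configuration; q = 2 only (65536 states).  Returns exact means.
    """
    if q != 2:
        raise ValueError("brute force is limited to q = 2")
    n_mol = 4
    v0_grid = np.atleast_1d(np.asarray(v0_grid, dtype=float))
    if len(v0_grid) > 1:
        dx = np.gradient(v0_grid)
        quad_w = dx.copy()
        quad_w[0] *= 0.5
        quad_w[-1] *= 0.5
    else:
        quad_w = np.ones(1)
    beta = point.beta
    Z = 0.0
    acc = {k: 0.0 for k in ("u", "rho", "n_hb", "n_coop", "V", "H")}
    node_cache = []
    fv_exp = float(n_mol) if params.free_volume_entropy else 0.0
    for V0, w in zip(v0_grid, quad_w):
        n = occupancy_from_volume(V0, n_mol, params)
        U = total_isotropic_energy(V0, n_mol, 2, params)
        w = w * (V0 / (n_mol * params.v0)) ** fv_exp
        node_cache.append((V0, w, n, U))
    for arms in itertools.product(range(q), repeat=16):
        sigma = np.asarray(arms, dtype=np.int64).reshape(4, 4)
        nm = count_matching_edges(sigma, 2)
        nc = count_cooperative(sigma)
        for V0, w, n, U in node_cache:
            n_hb = n * nm
            E = U - params.j * n_hb - params.j_sigma * nc
            V = V0 + n_hb * params.v_hb
            H = E + point.P * V
            bw = w * math.exp(-beta * H)
            Z += bw
            acc["u"] += bw * E / n_mol
            acc["rho"] += bw * n_mol * params.v0 / V
            acc["n_hb"] += bw * n_hb
            acc["n_coop"] += bw * nc
            acc["V"] += bw * V
            acc["H"] += bw * H
    return {k: v / Z for k, v in acc.items()}


def sample_oracle_series(point: StatePoint, params: ModelParams,
                         v0_grid: np.ndarray, n: int, q: int,
                         seed: int) -> ObservableSeries:
    """I.i.d. samples drawn from the exact enumerated joint distribution.

    Useful for validating estimators with zero autocorrelation and known
    truth; the samples are bin-valued (sigma sector x V0 node).
    """
    g = sigma_density_of_states(q)
    logw, cols = _oracle_tables(point, params, v0_grid, g)
    p = np.exp(logw - logw.max())
    p /= p.sum()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(p), size=n, p=p)
    return ObservableSeries(
        point=point, u=cols["u"][idx], rho=cols["rho"][idx],
        n_hb=cols["n_hb"][idx].astype(np.int64),
        n_coop=cols["n_coop"][idx].astype(np.int64), V=cols["V"][idx],
        meta={"n_molecules": 4, "seed": seed, "kind": "oracle_iid"})


# ---------------------------------------------------------------------------
# synthetic fixtures
# ---------------------------------------------------------------------------


def synthetic_series(kind: str, seed: int, n: int = 5000,
                     point: StatePoint | None = None,
                     n_molecules: int = 1000, **kw) -> ObservableSeries:
    """Observable series with prescribed statistical structure.

    kinds: ``gaussian`` (mean_u, mean_rho, cov), ``double_gaussian``
    (two (u, rho) modes at +-separation/2 along ``direction``),
    ``ising_like`` (rho carries a critical 2D Ising order parameter),
    ``drifted`` (gaussian plus a linear drift in time) and ``constant``.
    """
    rng = np.random.default_rng(seed)
    point = point or StatePoint(T=1.0, P=0.1)
    if kind == "gaussian":
        mean = np.array([kw.get("mean_u", -1.0), kw.get("mean_rho", 0.5)])
        cov = np.asarray(kw.get("cov", [[0.01, 0.0], [0.0, 0.01]]))
        u, rho = rng.multivariate_normal(mean, cov, size=n).T
    elif kind == "double_gaussian":
        sep = kw.get("separation", 0.2)
        width = kw.get("width", 0.02)
        direction = np.asarray(kw.get("direction", [0.0, 1.0]), dtype=float)
        direction = direction / np.linalg.norm(direction)
        mean = np.array([kw.get("mean_u", -1.0), kw.get("mean_rho", 0.5)])
        side = rng.integers(0, 2, size=n) * 2 - 1
        centers = mean[None, :] + 0.5 * sep * side[:, None] * direction[None, :]
        u, rho = (centers + rng.normal(scale=width, size=(n, 2))).T
    elif kind == "ising_like":
        from .criticality import reference_distribution
        ref = reference_distribution(2)
        u_noise = kw.get("u_std", 0.0)
        x = _sample_from_pdf(ref.x, ref.pdf, n, rng)
        rho = kw.get("mean_rho", 0.5) + kw.get("rho_scale", 0.05) * x
        u = np.full(n, kw.get("mean_u", 0.0)) + \
            (rng.normal(scale=u_noise, size=n) if u_noise else 0.0)
    elif kind == "drifted":
        base = synthetic_series("gaussian", seed, n=n, point=point,
                                n_molecules=n_molecules, **kw)
        drift = kw.get("drift", 0.5) * np.linspace(0, 1, n)
        u, rho = base.u + drift, base.rho
    elif kind == "constant":
        u = np.full(n, kw.get("mean_u", -1.0))
        rho = np.full(n, kw.get("mean_rho", 0.5))
    else:
        raise ValueError(f"unknown synthetic kind {kind!r}")
    rho = np.clip(rho, 1e-6, None)
    V = n_molecules / rho
    return ObservableSeries(point=point, u=np.asarray(u, dtype=float),
                            rho=np.asarray(rho, dtype=float),
                            n_hb=np.zeros(n, dtype=np.int64),
                            n_coop=np.zeros(n, dtype=np.int64),
                            V=V, meta={"n_molecules": n_molecules,
                                       "seed": seed, "kind": kind})


def _sample_from_pdf(x: np.ndarray, pdf: np.ndarray, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Inverse-CDF sampling from a tabulated density (linear interpolation)."""
    cdf = np.cumsum(pdf)
    cdf = cdf / cdf[-1]
    u = rng.uniform(size=n)
    return np.interp(u, cdf, x)


def synthetic_critical_runs(s_true: float, T_c: float, P_c: float,
                            run_points: list[StatePoint], seed: int,
                            n_per_run: int = 4000, n_molecules: int = 200,
                            mean_u: float = -1.0, slope_u: float = -0.5,
                            skew_shape: float = 1.5, u_scale: float = 0.2,
                            m_c: float = 0.5, m_scale: float = 0.08,
                            ) -> list[ObservableSeries]:
    """Runs drawn from a known mixed-field critical family.

    At (T_c, P_c) the order parameter M = rho + s_true * u follows the 2D
    Ising universal distribution; the energy density is correlated with M
    and carries a skewed residual, so projecting along a wrong s direction
    produces a visibly asymmetric distribution.  Runs at other (T, P) are
    produced by exact NPT reweighting (importance resampling with weights
    exp(-d(beta) E - d(beta P) V)), making the family self-consistent with
    the WHAM machinery.
    """
    rng = np.random.default_rng(seed)
    from .criticality import reference_distribution
    ref = reference_distribution(2)
    n_pool = max(20 * n_per_run, 100_000)
    x = _sample_from_pdf(ref.x, ref.pdf, n_pool, rng)
    M = m_c + m_scale * x
    skew = rng.gamma(skew_shape, 1.0, size=n_pool) - skew_shape
    eps_u = u_scale * skew / math.sqrt(skew_shape)
    u = mean_u + slope_u * (M - m_c) + eps_u
    rho = M - s_true * u
    rho = np.clip(rho, 1e-3, None)
    E = n_molecules * u
    V = n_molecules / rho
    beta_c = 1.0 / T_c
    out = []
    for k, pt in enumerate(run_points):
        beta = 1.0 / pt.T
        logw = -(beta - beta_c) * E - (beta * pt.P - beta_c * P_c) * V
        logw -= logw.max()
        w = np.exp(logw)
        w /= w.sum()
        idx = rng.choice(n_pool, size=n_per_run, replace=True, p=w)
        out.append(ObservableSeries(
            point=pt, u=u[idx], rho=rho[idx],
            n_hb=np.zeros(n_per_run, dtype=np.int64),
            n_coop=np.zeros(n_per_run, dtype=np.int64), V=V[idx],
            meta={"n_molecules": n_molecules, "seed": seed, "run": k,
                  "kind": "synthetic_critical"}))
    return out


# ---------------------------------------------------------------------------
# series I/O (tab-separated text with a key-value header)
# ---------------------------------------------------------------------------


def write_series(path: Path | str, series: ObservableSeries) -> None:
    path = Path(path)
    lines = [f"# T: {series.point.T!r}", f"# P: {series.point.P!r}"]
    for k, v in series.meta.items():
        lines.append(f"# {k}: {v!r}")
    lines.append("u\trho\tn_hb\tn_coop\tV")
    for t in range(len(series)):
        lines.append(f"{float(series.u[t])!r}\t{float(series.rho[t])!r}\t"
                     f"{int(series.n_hb[t])}\t{int(series.n_coop[t])}\t"
                     f"{float(series.V[t])!r}")
    path.write_text("\n".join(lines) + "\n")


def read_series(path: Path | str) -> ObservableSeries:
    import ast

    meta: dict = {}
    rows = []
    header_seen = False
    for line in Path(path).read_text().splitlines():
        if line.startswith("#"):
            k, v = line.lstrip("# ").split(":", 1)
            try:
                meta[k.strip()] = ast.literal_eval(v.strip())
            except (ValueError, SyntaxError):
                meta[k.strip()] = v.strip()
        elif not header_seen:
            header_seen = True
        elif line.strip():
            rows.append([float(t) for t in line.split("\t")])
    arr = np.asarray(rows)
    point = StatePoint(T=float(meta.pop("T")), P=float(meta.pop("P")))
    return ObservableSeries(point=point, u=arr[:, 0], rho=arr[:, 1],
                            n_hb=arr[:, 2].astype(np.int64),
                            n_coop=arr[:, 3].astype(np.int64),
                            V=arr[:, 4], meta=meta)


# ---------------------------------------------------------------------------
# run configuration and pipeline
# ---------------------------------------------------------------------------


@dataclass
class RunConfig:
    """Structured run description: [model], [mc] and [analysis] sections."""

    model: ModelParams = field(default_factory=ModelParams)
    side: int = 16
    seed: int = 1
    n_equil: int = 400
    n_sample: int = 400
    stride: int | None = None
    volume_step: float = 2.0
    T_values: list[float] = field(default_factory=lambda: [0.5, 0.4, 0.3])
    P_values: list[float] = field(default_factory=lambda: [0.2])
    bins: int = 100
    collect_configs: bool = False

    @classmethod
    def from_toml(cls, path: Path | str) -> "RunConfig":
        with open(path, "rb") as fh:
            doc = tomllib.load(fh)
        model_kw = doc.get("model", {})
        params = ModelParams(**model_kw)
        mc = doc.get("mc", {})
        an = doc.get("analysis", {})
        return cls(model=params,
                   side=mc.get("side", 16), seed=mc.get("seed", 1),
                   n_equil=mc.get("n_equil", 400),
                   n_sample=mc.get("n_sample", 400),
                   stride=mc.get("stride"),
                   volume_step=mc.get("volume_step", 2.0),
                   T_values=mc.get("T_values", [0.5, 0.4, 0.3]),
                   P_values=mc.get("P_values", [0.2]),
                   bins=an.get("bins", 100),
                   collect_configs=an.get("collect_configs", False))

    def to_toml(self) -> str:
        def fmt(v):
            if isinstance(v, bool):
                return "true" if v else "false"
            return repr(v)

        lines = ["[model]"]
        for f in fields(ModelParams):
            lines.append(f"{f.name} = {fmt(getattr(self.model, f.name))}")
        lines += ["", "[mc]"]
        for k in ("side", "seed", "n_equil", "n_sample", "volume_step",
                  "T_values", "P_values"):
            lines.append(f"{k} = {getattr(self, k)!r}")
        if self.stride is not None:
            lines.append(f"stride = {self.stride!r}")
        lines += ["", "[analysis]", f"bins = {self.bins!r}",
                  f"collect_configs = {str(self.collect_configs).lower()}"]
        return "\n".join(lines) + "\n"


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(cfg: RunConfig, outdir: Path | str) -> dict:
    """simulate -> response functions -> density extrema -> manifest.

    One annealed schedule (high to low T) per isobar; per-state-point series
    land as TSV files, the response grid and detected loci as TSV tables,
    and a manifest records seeds, sizes and output checksums.
    """
    from .mc import MCConfig, anneal
    from .observables import density_extrema, response_functions

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    all_series = []
    for stream, P in enumerate(sorted(cfg.P_values, key=float)):
        schedule = [StatePoint(T=float(t), P=float(P))
                    for t in sorted(cfg.T_values, reverse=True)]
        mc_cfg = MCConfig(schedule=schedule, seed=cfg.seed,
                          n_equil=cfg.n_equil, n_sample=cfg.n_sample,
                          decorrelation_stride=cfg.stride,
                          volume_step=cfg.volume_step,
                          collect_configs=cfg.collect_configs)
        all_series.extend(anneal(mc_cfg, cfg.model, cfg.side, stream=stream))
    outputs = []
    for k, s in enumerate(all_series):
        p = outdir / f"series_{k:03d}.tsv"
        write_series(p, s)
        outputs.append(p)
    grid = response_functions(all_series)
    grid_path = outdir / "response_grid.tsv"
    grid.to_csv(grid_path, sep="\t", index=False)
    outputs.append(grid_path)
    extrema_rows = []
    for P, sub in grid.groupby("P"):
        sub = sub.sort_values("T")
        if len(sub) >= 5:
            for e in density_extrema(sub["T"].to_numpy(),
                                     sub["mean_rho"].to_numpy()):
                if not e.at_edge:
                    extrema_rows.append({"kind": e.kind, "T": e.T, "P": P,
                                         "rho": e.value})
    import pandas as pd

    loci_path = outdir / "density_extrema.tsv"
    pd.DataFrame(extrema_rows).to_csv(loci_path, sep="\t", index=False)
    outputs.append(loci_path)
    manifest = {
        "seed": cfg.seed, "side": cfg.side,
        "n_state_points": len(all_series),
        "outputs": {p.name: _sha256(p) for p in outputs},
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
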