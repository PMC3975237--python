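"""Hamiltonian, geometry and energy bookkeeping of the confined water monolayer.

A monolayer of N water molecules sits between two flat hydrophobic walls
(excluded-volume interaction only) separated by about half a nanometre.  The
volume is partitioned into N equivalent square cells on an L x L lattice with
periodic boundary conditions; each cell hosts one molecule and carries

* a discretised density field ``n_i`` in {0, 1}: the cell counts as liquid
  (``n_i = 1``) when its density exceeds half the full-occupancy density;
* four bonding indices ``sigma_ij`` in {1, .., q}, one per arm facing each of
  the four nearest neighbours, encoding the orientation class of that arm.

The enthalpy of a configuration is::

    H = U_iso(V0)  -  J * N_HB  -  J_sigma * N_coop  +  P * V,
    V = V0 + N_HB * v_HB

where ``U_iso`` is an isotropic Lennard-Jones-like pair sum over all molecules
within a cutoff ``r_c``, ``N_HB`` is the number of hydrogen bonds (facing
indices equal, both cells occupied), ``N_coop`` counts equal pairs among the
four indices of each molecule (the many-body cooperative term), and each bond
carries a volume increment ``v_HB`` so that bond formation costs enthalpy
``P * v_HB``.

Internal units: lengths in ``r0`` (the van der Waals diameter), projected cell
volumes in ``v0 = r0**2``, energies in ``eps`` (the isotropic well depth),
temperature in ``eps / k_B`` and pressure in ``eps / v0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache

import numpy as np

__all__ = [
    "ModelParams",
    "StatePoint",
    "LatticeState",
    "EnergyBreakdown",
    "HardCoreViolation",
    "occupancy_from_volume",
    "hb_distance_cutoff",
    "isotropic_pair_energy",
    "lattice_shells",
    "total_isotropic_energy",
    "count_matching_edges",
    "count_hbonds",
    "count_cooperative",
    "enthalpy",
]


class HardCoreViolation(ValueError):
    """Raised when a configuration puts molecules inside the hard core."""


# ---------------------------------------------------------------------------
# parameters and state containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ModelParams:
    """Coupling constants and geometry of the monolayer Hamiltonian.

    All values are in internal units (see module docstring).  ``j`` and
    ``j_sigma`` default to the values used throughout this model family;
    both are plain configuration knobs.

    ``free_volume_entropy`` keeps the translational measure V0^N that the
    coarse-grained density field inherits from the molecules' positional
    degrees of freedom.  It gives the cell volume an extensive entropy
    -N k_B ln(V0/N v0), which is what produces thermal expansion, the
    liquid-gas transition and hence the density anomaly; switching it off
    leaves the bare single-variable measure dV0 (useful for closed-form
    checks, e.g. the exponential excess-volume law of the ideal system).
    """

    j: float = 0.5              # directional HB coupling, in eps
    j_sigma: float = 0.05       # cooperative (many-body) coupling, in eps
    eps: float = 1.0            # isotropic attraction scale
    q: int = 6                  # bonding-index states per arm
    v_hb: float = 0.5           # HB volume increment, in v0
    r0: float = 1.0             # van der Waals diameter (unit of length)
    r_cut: float = 25.0         # isotropic cutoff, in r0
    h: float = 1.724            # wall separation, in r0 (~0.5 nm / 2.9 A)
    occupancy_threshold: float = 0.5  # rho_i/rho_0 above which n_i = 1
    free_volume_entropy: bool = True  # translational measure V0^N (see docs)

    def __post_init__(self) -> None:
        if self.q < 2:
            raise ValueError("q must be >= 2")
        if self.j <= 0:
            raise ValueError("j must be > 0")
        if self.j_sigma < 0 or self.eps < 0 or self.v_hb < 0:
            raise ValueError("j_sigma, eps and v_hb must be >= 0")
        if self.r_cut <= 1.0:
            raise ValueError("r_cut must exceed r0 (in units of r0)")
        if not 0.0 < self.occupancy_threshold < 1.0:
            raise ValueError("occupancy_threshold must be in (0, 1)")

    @property
    def v0(self) -> float:
        """Projected cell volume at full occupancy (r0**2)."""
        return self.r0 * self.r0

    def with_(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class StatePoint:
    """A thermodynamic state point (T, P) in internal units (k_B = 1)."""

    T: float
    P: float

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("temperature must be > 0")

    @property
    def beta(self) -> float:
        return 1.0 / self.T


@dataclass
class LatticeState:
    """Occupancy/bonding configuration plus the continuous volume V0.

    ``sigma`` has shape (N, 4) with values in 0..q-1 (arm order: +x, -x,
    +y, -y).  Cells are homogeneous: a single stochastic volume ``V0`` is
    shared, so the occupancy flag ``n`` is global.
    """

    side: int
    sigma: np.ndarray
    V0: float
    params: ModelParams = field(default_factory=ModelParams)

    @classmethod
    def random(cls, side: int, params: ModelParams, rng: np.random.Generator,
               V0: float | None = None) -> "LatticeState":
        n = side * side
        sigma = rng.integers(0, params.q, size=(n, 4), dtype=np.int8)
        if V0 is None:
            V0 = 1.2 * n * params.v0
        return cls(side=side, sigma=sigma, V0=float(V0), params=params)

    @property
    def n_molecules(self) -> int:
        return self.side * self.side

    @property
    def occupancy(self) -> int:
        return occupancy_from_volume(self.V0, self.n_molecules, self.params)

    @property
    def cell_side(self) -> float:
        """Instantaneous lattice spacing ell = sqrt(V0 / N)."""
        return math.sqrt(self.V0 / self.n_molecules)


@dataclass(frozen=True)
class EnergyBreakdown:
    """All terms of the enthalpy at one configuration."""

    u_iso: float
    n_hb: int
    n_coop: int
    e_hb: float
    e_coop: float
    V0: float
    V: float
    H: float
    u: float  # energy density (U_iso + E_HB + E_coop) / N


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------


def occupancy_from_volume(V0: float, n_molecules: int, params: ModelParams) -> int:
    """Global occupancy flag from the shared cell volume.

    A cell is liquid (n = 1) when its density ratio rho_i/rho_0 =
    v0 / (V0/N) exceeds the threshold; at the default threshold 1/2 this
    reads V0/N < 2 v0.  The boundary (ratio exactly at threshold) is empty.
    """
    if V0 < n_molecules * params.v0 - 1e-12:
        raise HardCoreViolation(
            f"V0 = {V0} below hard-core bound N*v0 = {n_molecules * params.v0}")
    ratio = params.v0 / (V0 / n_molecules)
    return 1 if ratio > params.occupancy_threshold else 0


def hb_distance_cutoff(params: ModelParams, r0_angstrom: float | None = None,
                       r_oh_angstrom: float | None = None):
    """Nearest-neighbour distance at which hydrogen bonds switch off.

    Bonds require both cells occupied; occupancy dies when the cell density
    ratio drops to the threshold, i.e. when the cell area reaches
    ``v0 / threshold``, whose side is ``r0 / sqrt(threshold)``.  At the
    default threshold 1/2 this is ``r_max = r0 * sqrt(2)``.

    When ``r0_angstrom`` is given, returns ``r_max`` in angstrom as well;
    with ``r_oh_angstrom`` additionally the derived OH--O breaking distance
    ``r_max - r_OH``.
    """
    r_max = params.r0 / math.sqrt(params.occupancy_threshold)
    out = {"r_max": r_max}
    if r0_angstrom is not None:
        r_max_a = r0_angstrom / math.sqrt(params.occupancy_threshold)
        out["r_max_angstrom"] = r_max_a
        if r_oh_angstrom is not None:
            out["oh_o_threshold_angstrom"] = r_max_a - r_oh_angstrom
    return out


# ---------------------------------------------------------------------------
# isotropic pair interaction
# ---------------------------------------------------------------------------

#: sentinel returned for hard-core overlap; a rejection signal, not a float inf
HARD_CORE = float("inf")


def isotropic_pair_energy(r: float, params: ModelParams) -> float:
    """Isotropic O-O pair potential.

    Hard core below r0, a Lennard-Jones well eps*[(r0/r)^12 - (r0/r)^6]
    between r0 and the cutoff r_c, and exactly zero beyond r_c.  The well
    shape is a documented modelling choice of this package.
    """
    if r <= 0:
        raise ValueError("pair distance must be positive")
    if r < params.r0:
        return HARD_CORE
    if r > params.r_cut * params.r0:
        return 0.0
    x = params.r0 / r
    x6 = x ** 6
    return params.eps * (x6 * x6 - x6)


@lru_cache(maxsize=32)
def lattice_shells(side: int) -> tuple[np.ndarray, np.ndarray]:
    """Distinct minimum-image pair distances on a side x side square lattice.

    Returns (distances in lattice-spacing units, pair multiplicities) where
    multiplicities sum to N(N-1)/2.  Because cells are homogeneous every
    molecule sees the same shell structure, so the full O(N^2) pair sum
    collapses onto these shells.
    """
    if side < 2:
        raise ValueError("side must be >= 2")
    dx = np.arange(side)
    dmin = np.minimum(dx, side - dx)
    d2 = dmin[:, None] ** 2 + dmin[None, :] ** 2
    d2 = d2.ravel()[1:]  # drop the (0, 0) displacement
    vals, counts = np.unique(d2, return_counts=True)
    n = side * side
    mult = counts * n / 2.0
    return np.sqrt(vals.astype(float)), mult


def total_isotropic_energy(V0: float, n_molecules: int, side: int,
                           params: ModelParams) -> float:
    """Isotropic energy of the homogeneous lattice at shared volume V0.

    Distances are lattice shells scaled by the instantaneous spacing
    ell = sqrt(V0/N); pairs beyond the cutoff contribute zero.
    """
    if params.eps == 0.0:
        if V0 < n_molecules * params.v0 - 1e-12:
            raise HardCoreViolation("cell side below r0")
        return 0.0
    ell = math.sqrt(V0 / n_molecules)
    if ell < params.r0 - 1e-12:
        raise HardCoreViolation("cell side below r0")
    dists, mult = lattice_shells(side)
    r = ell * dists
    mask = r <= params.r_cut * params.r0
    if not np.any(mask):
        return 0.0
    x6 = (params.r0 / r[mask]) ** 6
    return float(params.eps * np.sum(mult[mask] * (x6 * x6 - x6)))


# ---------------------------------------------------------------------------
# bond counting
# ---------------------------------------------------------------------------

# arm order: 0 = +x, 1 = -x, 2 = +y, 3 = -y; facing arm of a is a ^ 1
_OPPOSITE = np.array([1, 0, 3, 2], dtype=np.int64)


def neighbour_table(side: int) -> np.ndarray:
    """Index of the neighbour molecule across each arm; shape (N, 4)."""
    n = side * side
    idx = np.arange(n)
    x, y = idx % side, idx // side
    nbr = np.empty((n, 4), dtype=np.int64)
    nbr[:, 0] = (x + 1) % side + y * side
    nbr[:, 1] = (x - 1) % side + y * side
    nbr[:, 2] = x + ((y + 1) % side) * side
    nbr[:, 3] = x + ((y - 1) % side) * side
    return nbr


def count_matching_edges(sigma: np.ndarray, side: int) -> int:
    """Number of lattice edges whose two facing bonding indices agree."""
    nbr = neighbour_table(side)
    total = 0
    for arm in (0, 2):  # each edge counted once via its +x / +y endpoint
        facing = sigma[nbr[:, arm], _OPPOSITE[arm]]
        total += int(np.count_nonzero(sigma[:, arm] == facing))
    return total


def count_hbonds(state: LatticeState) -> int:
    """Hydrogen-bond count: matching facing indices gated by occupancy."""
    return state.occupancy * count_matching_edges(state.sigma, state.side)


def count_cooperative(sigma: np.ndarray) -> int:
    """Equal pairs among the four indices of each molecule, summed over all.

    Each molecule contributes delta(sigma_il, sigma_ik) over its six
    unordered arm pairs, so the total lies in [0, 6N].
    """
    total = 0
    for a in range(4):
        for b in range(a + 1, 4):
            total += int(np.count_nonzero(sigma[:, a] == sigma[:, b]))
    return total


def enthalpy(state: LatticeState, point: StatePoint,
             params: ModelParams | None = None) -> EnergyBreakdown:
    """Full enthalpy H = U_iso - J*N_HB - J_sigma*N_coop + P*V of a state."""
    p = params if params is not None else state.params
    n = state.n_molecules
    u_iso = total_isotropic_energy(state.V0, n, state.side, p)
    n_hb = occupancy_from_volume(state.V0, n, p) * \
        count_matching_edges(state.sigma, state.side)
    n_coop = count_cooperative(state.sigma)
    e_hb = -p.j * n_hb
    e_coop = -p.j_sigma * n_coop
    V = state.V0 + n_hb * p.v_hb
    H = u_iso + e_hb + e_coop + point.P * V
    return EnergyBreakdown(
        u_iso=u_iso, n_hb=n_hb, n_coop=n_coop, e_hb=e_hb, e_coop=e_coop,
        V0=state.V0, V=V, H=H, u=(u_iso + e_hb + e_coop) / n)
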