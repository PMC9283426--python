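"""Free-energy landscape of a hard nanoparticle in a Gaussian-chain cell.

The particle-network free energy is ``F(r_np) = -k_B T ln Z(r_np)`` where
``Z`` integrates over cross-link positions and all strand conformations of
an ideal (theta-solvent) network, subject to hard-sphere exclusion of the
particle.  The implementation evaluates the cross-link integral at its
saddle point (a constrained minimization of the summed strand free
energies) and retains strand-level fluctuations through the survival
probability of free Gaussian bridges around the particle:

    F_strand(r_i, r_j) = (3/2) |r_i - r_j|^2 / (N b^2)  -  ln P_survive

with ``P_survive`` the probability that a discrete ``N``-step Gaussian
bridge between the cross-links avoids the particle.  Energies are in units
of ``k_B T`` and lengths in units of the mesh size ``a_x``.

Particle sizes are classified against the cell radii: Regime I
(``R > r_out``, whole-cell dilation), Regime II (``r_mid < R < r_out``,
strand deformation), Regime III (``r_in < R < r_mid``, obstruction at the
faces) and Regime IV (``R < r_in``, free passage).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from enum import Enum

import numpy as np
from scipy.optimize import minimize

from .cells import (
    BeadSpringNetwork,
    MEPFrame,
    PolyhedralCell,
    RadiiTriple,
    mep_frame,
    radii_geometric,
    to_bead_network,
)

__all__ = [
    "ParticleSpec",
    "Regime",
    "LandscapeConfig",
    "MEPProfile",
    "FreeEnergyField",
    "classify_regime",
    "taut_length",
    "bridge_survival",
    "strand_free_energy",
    "relax_crosslinks",
    "free_energy_point",
    "mep_profile",
    "free_energy_field",
]


@dataclass(frozen=True)
class ParticleSpec:
    """Hard spherical nanoparticle of diameter ``d`` (units of ``a_x``)."""

    d: float

    def __post_init__(self) -> None:
        if self.d <= 0:
            raise ValueError("particle diameter must be positive")

    @property
    def R(self) -> float:
        return 0.5 * self.d


class Regime(str, Enum):
    I = "I"
    II = "II"
    III = "III"
    IV = "IV"


def classify_regime(particle: ParticleSpec, radii: RadiiTriple) -> Regime:
    """Particle-size regime from the cell radii (ties go to the larger-particle regime)."""
    R = particle.R
    if R >= radii.r_out:
        return Regime.I
    if R >= radii.r_mid:
        return Regime.II
    if R >= radii.r_in:
        return Regime.III
    return Regime.IV


@dataclass
class LandscapeConfig:
    """Numerical controls of the landscape estimator.

    ``N`` is the number of bridge steps per strand (the theory's strand
    discretization), ``n_samples`` the Monte-Carlo sample count per strand
    survival estimate.  ``fluctuations=False`` drops the bridge-entropy
    term and returns the deterministic saddle-point energy only.
    """

    N: int = 8
    n_samples: int = 20000
    seed: int = 0
    fluctuations: bool = True
    replicate_neighbors: bool = True
    min_survivors: int = 30      # below this the MC estimate is unresolved
    opt_tol: float = 1e-10
    opt_maxiter: int = 300


@dataclass
class MEPProfile:
    """Free-energy change along the minimum-energy path.

    ``dF[i] = F(z[i]) - F(0)`` in ``k_B T``; ``U_b = max(dF)`` is the
    hopping barrier between neighboring cells.
    """

    z: np.ndarray
    dF: np.ndarray
    d: float
    g_label: int
    z_face: float
    regime: Regime | None = None
    truncated: bool = False

    @property
    def U_b(self) -> float:
        return float(np.max(self.dF))


@dataclass
class FreeEnergyField:
    """DeltaF sampled on a regular 3-D grid covering the cell interior."""

    grid: np.ndarray       # (nx, ny, nz, 3) positions
    values: np.ndarray     # (nx, ny, nz) DeltaF in k_B T (inf where infeasible)
    d: float
    g_label: int


# ---------------------------------------------------------------------------
# taut-string geometry


def taut_length(a: np.ndarray, b: np.ndarray, center: np.ndarray, R: float) -> float:
    """Length of the taut path from ``a`` to ``b`` around a hard sphere.

    Straight if the segment clears the sphere; otherwise the planar
    tangent-arc-tangent path in the plane of the endpoints and the sphere
    center.  The true 3-D geodesic may tilt out of that plane and be
    shorter by a few percent at intermediate impact parameters; the planar
    form is used as a smooth, differentiable upper bound.  Endpoints
    inside the sphere are infeasible (returns ``inf``).
    """
    L, _, _ = _taut_length_grad(a, b, center, R)
    return L


def _taut_length_grad(a, b, center, R):
    """Taut length and its gradients with respect to both endpoints."""
    u = a - center
    v = b - center
    dA = math.sqrt(float(u @ u))
    dB = math.sqrt(float(v @ v))
    if dA <= R or dB <= R:
        return math.inf, np.zeros(3), np.zeros(3)
    ab = b - a
    lab = math.sqrt(float(ab @ ab))
    if lab < 1e-14:
        return 0.0, np.zeros(3), np.zeros(3)
    # closest approach of the segment to the sphere center
    t = min(max(float(-(a - center) @ ab) / (lab * lab), 0.0), 1.0)
    closest = a + t * ab - center
    if math.sqrt(float(closest @ closest)) >= R:
        g = ab / lab
        return lab, -g, g
    tA = math.sqrt(dA * dA - R * R)
    tB = math.sqrt(dB * dB - R * R)
    uh = u / dA
    vh = v / dB
    c = min(max(float(uh @ vh), -1.0), 1.0)
    alpha = math.acos(c)
    wrap = alpha - math.acos(R / dA) - math.acos(R / dB)
    if wrap <= 0.0:  # tangent cones overlap: straight path grazes
        g = ab / lab
        return lab, -g, g
    L = tA + tB + R * wrap
    s = math.sqrt(max(1.0 - c * c, 1e-24))
    gA = (tA / dA) * uh - R * (vh - c * uh) / (dA * s)
    gB = (tB / dB) * vh - R * (uh - c * vh) / (dB * s)
    return L, gA, gB


# ---------------------------------------------------------------------------
# Gaussian-bridge survival


def bridge_survival(
    r_i: np.ndarray,
    r_j: np.ndarray,
    sphere_center: np.ndarray,
    R: float,
    N: int,
    b: float,
    n_samples: int = 20000,
    seed: int = 0,
) -> float:
    """Probability that a discrete Gaussian bridge avoids a hard sphere.

    The bridge has ``N`` steps of per-coordinate variance ``b^2/3`` from
    ``r_i`` to ``r_j``; interior points are sampled by the sequential
    bridge construction and the walk survives if every interior point stays
    outside the sphere.  Deterministic for a given ``seed``.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    sphere_center = np.asarray(sphere_center, dtype=float)
    if np.linalg.norm(r_i - sphere_center) <= R or np.linalg.norm(r_j - sphere_center) <= R:
        return 0.0
    if N <= 1:
        return 1.0  # no interior points
    rng = np.random.default_rng(seed)
    var = b * b / 3.0
    alive = np.ones(n_samples, dtype=bool)
    x = np.broadcast_to(r_i, (n_samples, 3)).copy()
    R2 = R * R
    for k in range(1, N):
        remaining = N - k + 1
        mean = x + (r_j - x) / remaining
        sigma = math.sqrt(var * (remaining - 1) / remaining)
        x = mean + sigma * rng.standard_normal((n_samples, 3))
        dd = x - sphere_center
        alive &= np.einsum("ij,ij->i", dd, dd) > R2
        if not alive.any():
            return 0.0
    return float(alive.mean())


def bridge_neg_log_survival(
    r_i: np.ndarray,
    r_j: np.ndarray,
    sphere_center: np.ndarray,
    R: float,
    N: int,
    b: float,
    n_walkers: int = 4000,
    seed: int = 0,
) -> float:
    """-ln P_survive by sequential bridge sampling with resampling.

    Propagates a population of Gaussian bridges step by step, killing
    walkers that enter the sphere and resampling the survivors, and
    accumulates the per-step survival fractions.  Resolves survival
    probabilities far below ``1/n_walkers`` (deep confinement), where the
    plain estimator of :func:`bridge_survival` returns zero.
    """
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    sphere_center = np.asarray(sphere_center, dtype=float)
    if np.linalg.norm(r_i - sphere_center) <= R or np.linalg.norm(r_j - sphere_center) <= R:
        return math.inf
    if N <= 1 or R <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    var = b * b / 3.0
    x = np.broadcast_to(r_i, (n_walkers, 3)).copy()
    R2 = R * R
    neg_log = 0.0
    for k in range(1, N):
        remaining = N - k + 1
        mean = x + (r_j - x) / remaining
        sigma = math.sqrt(var * (remaining - 1) / remaining)
        x = mean + sigma * rng.standard_normal((n_walkers, 3))
        dd = x - sphere_center
        alive = np.einsum("ij,ij->i", dd, dd) > R2
        n_alive = int(alive.sum())
        if n_alive == 0:
            return math.inf
        neg_log -= math.log(n_alive / n_walkers)
        if n_alive < n_walkers:
            dead = np.where(~alive)[0]
            x[dead] = x[rng.choice(np.where(alive)[0], size=len(dead))]
    return neg_log


def strand_free_energy(
    r_i: np.ndarray,
    r_j: np.ndarray,
    sphere_center: np.ndarray,
    R: float,
    N: int,
    b: float,
    n_samples: int = 20000,
    seed: int = 0,
) -> float:
    """Free energy of one strand in ``k_B T``: Gaussian stretching plus
    the confinement penalty ``-ln P_survive``.  Returns ``inf`` when no
    sampled bridge survives."""
    r_i = np.asarray(r_i, dtype=float)
    r_j = np.asarray(r_j, dtype=float)
    stretch = 1.5 * float(np.sum((r_i - r_j) ** 2)) / (N * b * b)
    if R <= 0:
        return stretch
    p = bridge_survival(r_i, r_j, sphere_center, R, N, b, n_samples, seed)
    if p <= 0.0:
        return math.inf
    return stretch - math.log(p)


# ---------------------------------------------------------------------------
# cross-link relaxation (saddle point of the cross-link integral)


@dataclass
class RelaxResult:
    positions: np.ndarray      # all cross-link positions (relaxed where free)
    energy: float              # minimized saddle energy, k_B T
    feasible: bool
    n_iter: int = 0


def relax_crosslinks(
    network: BeadSpringNetwork,
    particle: ParticleSpec,
    position: np.ndarray,
    config: LandscapeConfig | None = None,
    x0: np.ndarray | None = None,
) -> RelaxResult:
    """Minimize the summed strand saddle energies over free cross-links.

    Each strand contributes ``(3/2) L_taut^2 / (N b^2)`` where ``L_taut``
    is the shortest strand path around the particle; free cross-links obey
    the hard constraint ``|r_k - position| >= R``.  Pinned (image-shell)
    cross-links provide the boundary condition.
    """
    config = config or LandscapeConfig()
    position = np.asarray(position, dtype=float)
    R = particle.R
    Nb2 = network.N * network.b * network.b
    pref = 1.5 / Nb2

    xl_idx = np.where(network.is_crosslink)[0]
    free_xl = np.array([network.free[i] for i in xl_idx])
    pos0 = network.positions[xl_idx].copy()
    n_xl = len(xl_idx)
    free_list = np.where(free_xl)[0]
    site_to_local = {int(s): li for li, s in enumerate(xl_idx)}
    strand_pairs = np.array(
        [[site_to_local[int(i)], site_to_local[int(j)]] for i, j, _ in network.strands]
    )

    # feasible start: push cross-links radially outside the particle
    start = pos0.copy()
    for li in free_list:
        dv = start[li] - position
        dn = np.linalg.norm(dv)
        if dn < R * (1.0 + 1e-9):
            if dn < 1e-12:
                dv = np.array([0.0, 0.0, 1.0])
                dn = 1.0
            start[li] = position + dv / dn * R * (1.0 + 1e-7)
    if x0 is not None:
        start[free_list] = x0.reshape(-1, 3)

    # pinned cross-links inside the particle make the state infeasible
    pinned = np.setdiff1d(np.arange(n_xl), free_list)
    if len(pinned) and np.any(
        np.linalg.norm(pos0[pinned] - position, axis=1) < R * (1.0 - 1e-9)
    ):
        return RelaxResult(pos0, math.inf, feasible=False)

    if len(free_list) == 0:
        e = sum(
            pref * taut_length(pos0[i], pos0[j], position, R) ** 2
            for i, j in strand_pairs
        )
        return RelaxResult(pos0, e, feasible=math.isfinite(e))

    def unpack(xflat):
        p = pos0.copy()
        p[free_list] = xflat.reshape(-1, 3)
        return p

    def objective(xflat):
        p = unpack(xflat)
        total = 0.0
        grad = np.zeros_like(p)
        for i, j in strand_pairs:
            L, gA, gB = _taut_length_grad(p[i], p[j], position, R)
            if not math.isfinite(L):
                return 1e12, np.zeros(3 * len(free_list))
            total += pref * L * L
            grad[i] += 2.0 * pref * L * gA
            grad[j] += 2.0 * pref * L * gB
        return total, grad[free_list].ravel()

    def cons_f(xflat):
        p = xflat.reshape(-1, 3)
        return np.sum((p - position) ** 2, axis=1) - R * R

    def cons_jac(xflat):
        p = xflat.reshape(-1, 3)
        J = np.zeros((len(p), 3 * len(p)))
        for k in range(len(p)):
            J[k, 3 * k : 3 * k + 3] = 2.0 * (p[k] - position)
        return J

    x = start[free_list].ravel()
    e_prev = math.inf
    nit = 0
    for _restart in range(6):  # SLSQP can stall from a projected start
        res = minimize(
            objective,
            x,
            jac=True,
            method="SLSQP",
            constraints=[{"type": "ineq", "fun": cons_f, "jac": cons_jac}],
            options={"maxiter": config.opt_maxiter, "ftol": config.opt_tol},
        )
        x = res.x
        nit += res.nit
        e_now, _ = objective(x)
        if e_prev - e_now < 1e-8:
            break
        e_prev = e_now
    p_final = unpack(x)
    e_final, _ = objective(x)
    feasible = e_final < 1e11
    return RelaxResult(p_final, float(e_final), feasible, n_iter=nit)


# ---------------------------------------------------------------------------
# point, profile and field evaluators


def _network_for(cell: PolyhedralCell, config: LandscapeConfig) -> BeadSpringNetwork:
    return to_bead_network(
        cell, N=config.N, replicate_neighbors=config.replicate_neighbors
    )


def _total_free_energy(
    network: BeadSpringNetwork,
    particle: ParticleSpec,
    position: np.ndarray,
    config: LandscapeConfig,
    x0: np.ndarray | None = None,
):
    """Saddle energy plus (optionally) the bridge-entropy correction.

    Strand seeds are derived per strand index from ``config.seed`` so that
    evaluations at different particle positions share random streams
    (common random numbers cancel most sampling noise in differences).
    """
    relax = relax_crosslinks(network, particle, position, config, x0=x0)
    if not relax.feasible:
        return math.inf, relax
    if not config.fluctuations:
        return relax.energy, relax

    xl_idx = np.where(network.is_crosslink)[0]
    site_to_local = {int(s): li for li, s in enumerate(xl_idx)}
    R = particle.R
    Nb2 = network.N * network.b * network.b
    pref = 1.5 / Nb2
    total = 0.0
    ss = np.random.SeedSequence(config.seed)
    strand_seeds = ss.generate_state(len(network.strands))
    for si, (i, j, _) in enumerate(network.strands):
        a = relax.positions[site_to_local[int(i)]]
        b_ = relax.positions[site_to_local[int(j)]]
        stretch = pref * float(np.sum((a - b_) ** 2))
        # skip sampling for strands far from the particle (survival ~ 1)
        seg_mid = 0.5 * (a + b_)
        clearance = min(
            np.linalg.norm(a - position),
            np.linalg.norm(b_ - position),
            np.linalg.norm(seg_mid - position),
        )
        if clearance > R + 2.5 * network.a_x:
            total += stretch
            continue
        neg_log = bridge_neg_log_survival(
            a, b_, position, R, network.N, network.b,
            n_walkers=config.n_samples, seed=int(strand_seeds[si]),
        )
        if not math.isfinite(neg_log):
            return math.inf, relax
        total += stretch + neg_log
    return total, relax


def free_energy_point(
    cell: PolyhedralCell,
    particle: ParticleSpec,
    position: np.ndarray,
    config: LandscapeConfig | None = None,
    _network: BeadSpringNetwork | None = None,
) -> float:
    """DeltaF(position) = F(position) - F(center) in ``k_B T``."""
    config = config or LandscapeConfig()
    network = _network if _network is not None else _network_for(cell, config)
    position = np.asarray(position, dtype=float)
    if np.allclose(position, 0.0):
        return 0.0
    f_here, _ = _total_free_energy(network, particle, position, config)
    f_center, _ = _total_free_energy(network, particle, np.zeros(3), config)
    return f_here - f_center


def mep_profile(
    cell: PolyhedralCell,
    particle: ParticleSpec,
    n_z: int = 32,
    config: LandscapeConfig | None = None,
    frame: MEPFrame | None = None,
) -> MEPProfile:
    """DeltaF(z) at ``n_z`` points along the MEP from cell center to face center."""
    if n_z < 8:
        raise ValueError("need at least 8 points along the path")
    config = config or LandscapeConfig()
    frame = frame or mep_frame(cell, 0)
    network = _network_for(cell, config)
    zs = np.linspace(0.0, frame.z_face, n_z)
    xl_idx = np.where(network.is_crosslink)[0]
    free_local = np.where(network.free[xl_idx])[0]

    def sweep(order):
        """One warm-started pass over the path; hysteresis is resolved by
        keeping the lower of the forward and backward passes per point."""
        vals = np.full(n_z, math.inf)
        x0 = None
        for idx in order:
            pos = frame.origin + zs[idx] * frame.axis
            f, relax = _total_free_energy(network, particle, pos, config, x0=x0)
            if relax.feasible:
                x0 = relax.positions[free_local].copy()
            vals[idx] = f
        return vals

    fwd = sweep(range(n_z))
    bwd = sweep(range(n_z - 1, -1, -1))
    absolute = np.minimum(fwd, bwd)
    truncated = bool(~np.isfinite(absolute).all())
    f0 = absolute[0]
    values = absolute - f0 if math.isfinite(f0) else np.full(n_z, math.inf)
    if math.isfinite(f0):
        values[0] = 0.0
    regime = classify_regime(particle, radii_geometric(cell))
    return MEPProfile(
        z=zs, dF=values, d=particle.d, g_label=cell.g_label,
        z_face=frame.z_face, regime=regime, truncated=truncated,
    )


def free_energy_field(
    cell: PolyhedralCell,
    particle: ParticleSpec,
    n_grid: int = 9,
    extent: float | None = None,
    config: LandscapeConfig | None = None,
) -> FreeEnergyField:
    """DeltaF on a cubic grid spanning the cell interior.

    Infeasible nodes (particle violating the pinned boundary) carry
    ``inf``.  Intended for isosurface export and symmetry checks, so the
    default resolution is deliberately coarse.
    """
    config = config or LandscapeConfig()
    network = _network_for(cell, config)
    radii = radii_geometric(cell)
    half = extent if extent is not None else radii.r_in
    axis_pts = np.linspace(-half, half, n_grid)
    grid = np.stack(np.meshgrid(axis_pts, axis_pts, axis_pts, indexing="ij"), axis=-1)
    f_center, _ = _total_free_energy(network, particle, np.zeros(3), config)
    values = np.empty((n_grid, n_grid, n_grid))
    for ix in range(n_grid):
        for iy in range(n_grid):
            for iz in range(n_grid):
                pos = grid[ix, iy, iz]
                if np.allclose(pos, 0.0):
                    values[ix, iy, iz] = 0.0
                    continue
                f, _ = _total_free_energy(network, particle, pos, config)
                values[ix, iy, iz] = f - f_center
    return FreeEnergyField(grid=grid, values=values, d=particle.d, g_label=cell.g_label)
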