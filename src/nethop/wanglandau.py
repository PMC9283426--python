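"""Wang-Landau flat-histogram sampling of F(z) for a bead-spring cell.

The particle is constrained to the minimum-energy-path axis and carries a
bias ``f(z)`` accumulated in bins along ``[0, z_face]``.  Whenever the
visit histogram is flat (every bin at least ``flatness`` times the mean
count) the penalty increment halves, starting from ``f0 = 0.5 k_B T`` and
terminating below ``1e-4 k_B T``; the free energy is the negative of the
converged bias, reported as ``F(z) - F(0)``.

Network beads and free cross-links move in 3-D under the Gaussian spring
Hamiltonian ``(3/2) k_B T |dr|^2 / b^2`` per spring with hard-sphere
rejection against the particle; image-shell cross-links are pinned.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .cells import BeadSpringNetwork, MEPFrame
from .landscape import MEPProfile, ParticleSpec

__all__ = [
    "MCConfig",
    "WLResult",
    "wang_landau_profile",
    "multi_run_error",
    "metropolis_reference",
]


@dataclass
class MCConfig:
    """Wang-Landau schedule and move parameters."""

    f0: float = 0.5            # initial penalty increment, k_B T
    flatness: float = 0.8      # histogram flatness criterion
    reduction: float = 0.5     # penalty reduction per stage
    f_min: float = 1e-4        # terminate once the increment falls below this
    n_bins: int = 32
    n_sweeps_max: int = 2_000_000
    check_every: int = 200     # sweeps between flatness checks
    bead_step: float = 0.15    # a_x
    particle_step: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.flatness < 1.0):
            raise ValueError("flatness must lie in (0, 1)")
        if not (0.0 < self.reduction < 1.0):
            raise ValueError("reduction must lie in (0, 1)")


@dataclass
class WLResult:
    profile: MEPProfile
    bias: np.ndarray
    histogram: np.ndarray
    stages: int
    sweeps: int
    converged: bool
    stage_log: list = field(default_factory=list)


@njit(cache=True)
def _wl_kernel(
    pos, springs, neigh_idx, neigh_ptr, free_idx, kspring,
    axis, z_face, R, n_bins, f0, flatness, reduction, f_min,
    n_sweeps_max, check_every, bead_step, part_step, seed, wl_update,
):
    np.random.seed(seed)
    n_sites = pos.shape[0]
    n_free = free_idx.shape[0]
    bias = np.zeros(n_bins)
    hist = np.zeros(n_bins, dtype=np.int64)
    dz = z_face / n_bins
    z = 0.5 * dz  # start at the cell-center bin
    f_cur = f0
    stage = 0
    sweeps_done = 0
    R2 = R * R

    # push any overlapping site radially off the particle to start feasible
    for s in range(n_sites):
        cx = axis[0] * z
        cy = axis[1] * z
        cz = axis[2] * z
        ddx = pos[s, 0] - cx
        ddy = pos[s, 1] - cy
        ddz = pos[s, 2] - cz
        dd = ddx * ddx + ddy * ddy + ddz * ddz
        if dd < R2:
            dn = math.sqrt(dd)
            if dn < 1e-12:
                ddx, ddy, ddz, dn = 0.0, 0.0, 1.0, 1.0
            fac = (R * 1.0001) / dn
            pos[s, 0] = cx + ddx * fac
            pos[s, 1] = cy + ddy * fac
            pos[s, 2] = cz + ddz * fac

    moves_per_sweep = n_free + 1
    while sweeps_done < n_sweeps_max:
        for _ in range(check_every):
            for _m in range(moves_per_sweep):
                pick = np.random.randint(0, moves_per_sweep)
                if pick < n_free:
                    s = free_idx[pick]
                    ox, oy, oz = pos[s, 0], pos[s, 1], pos[s, 2]
                    nx = ox + (np.random.random() - 0.5) * 2.0 * bead_step
                    ny = oy + (np.random.random() - 0.5) * 2.0 * bead_step
                    nz = oz + (np.random.random() - 0.5) * 2.0 * bead_step
                    cx = axis[0] * z
                    cy = axis[1] * z
                    cz = axis[2] * z
                    ddx = nx - cx
                    ddy = ny - cy
                    ddz = nz - cz
                    if ddx * ddx + ddy * ddy + ddz * ddz < R2:
                        pass  # overlap: reject
                    else:
                        dE = 0.0
                        for pp in range(neigh_ptr[s], neigh_ptr[s + 1]):
                            o = neigh_idx[pp]
                            dE += kspring * (
                                (nx - pos[o, 0]) ** 2
                                + (ny - pos[o, 1]) ** 2
                                + (nz - pos[o, 2]) ** 2
                                - (ox - pos[o, 0]) ** 2
                                - (oy - pos[o, 1]) ** 2
                                - (oz - pos[o, 2]) ** 2
                            )
                        if dE <= 0.0 or np.random.random() < math.exp(-dE):
                            pos[s, 0] = nx
                            pos[s, 1] = ny
                            pos[s, 2] = nz
                else:
                    znew = z + (np.random.random() - 0.5) * 2.0 * part_step
                    if 0.0 <= znew <= z_face:
                        cx = axis[0] * znew
                        cy = axis[1] * znew
                        cz = axis[2] * znew
                        ok = True
                        for s2 in range(n_sites):
                            ddx = pos[s2, 0] - cx
                            ddy = pos[s2, 1] - cy
                            ddz = pos[s2, 2] - cz
                            if ddx * ddx + ddy * ddy + ddz * ddz < R2:
                                ok = False
                                break
                        if ok:
                            b_old = min(int(z / dz), n_bins - 1)
                            b_new = min(int(znew / dz), n_bins - 1)
                            dB = bias[b_new] - bias[b_old]
                            if dB <= 0.0 or np.random.random() < math.exp(-dB):
                                z = znew
                # Wang-Landau bookkeeping on the current bin
                bz = min(int(z / dz), n_bins - 1)
                hist[bz] += 1
                if wl_update:
                    bias[bz] += f_cur
            sweeps_done += 1
        if wl_update:
            mean = hist.mean()
            if mean > 0 and hist.min() >= flatness * mean:
                stage += 1
                f_cur *= reduction
                hist[:] = 0
                if f_cur < f_min:
                    return bias, hist, stage, sweeps_done, True, z
    return bias, hist, stage, sweeps_done, f_cur < f_min, z


def _prepare(network: BeadSpringNetwork):
    """Flatten the spring adjacency into CSR arrays for the kernel."""
    n = network.n_sites
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in network.springs:
        adj[int(i)].append(int(j))
        adj[int(j)].append(int(i))
    ptr = np.zeros(n + 1, dtype=np.int64)
    for s in range(n):
        ptr[s + 1] = ptr[s] + len(adj[s])
    idx = np.concatenate([np.array(a, dtype=np.int64) for a in adj]) if ptr[-1] else np.zeros(0, dtype=np.int64)
    free_idx = np.where(network.free)[0].astype(np.int64)
    return idx, ptr, free_idx


def wang_landau_profile(
    network: BeadSpringNetwork,
    particle: ParticleSpec,
    frame: MEPFrame,
    config: MCConfig | None = None,
) -> WLResult:
    """Free-energy profile ``F(z) - F(0)`` along the MEP by Wang-Landau sampling."""
    config = config or MCConfig()
    idx, ptr, free_idx = _prepare(network)
    pos = network.positions.copy()
    bias, hist, stages, sweeps, converged, _ = _wl_kernel(
        pos, network.springs, idx, ptr, free_idx, network.spring_stiffness,
        np.asarray(frame.axis, dtype=float), frame.z_face, particle.R,
        config.n_bins, config.f0, config.flatness, config.reduction,
        config.f_min, config.n_sweeps_max, config.check_every,
        config.bead_step, config.particle_step, config.seed, True,
    )
    dzb = frame.z_face / config.n_bins
    centers = (np.arange(config.n_bins) + 0.5) * dzb
    F = -(bias - bias[0])  # beta F(z) = -f(z), pinned to F(0) = 0
    profile = MEPProfile(
        z=centers, dF=F, d=particle.d,
        g_label=-1, z_face=frame.z_face, truncated=not converged,
    )
    return WLResult(profile, bias, hist, stages, sweeps, converged)


def multi_run_error(
    network: BeadSpringNetwork,
    particle: ParticleSpec,
    frame: MEPFrame,
    config: MCConfig | None = None,
    n_runs: int = 50,
):
    """Per-bin mean and standard error of F(z) over independent WL runs.

    Seeds are spawned deterministically from ``config.seed``; runs that do
    not converge within the sweep budget are excluded and counted.
    """
    if n_runs < 2:
        raise ValueError("need at least two runs for a standard error")
    config = config or MCConfig()
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(n_runs) % (2**31 - 1)
    profiles = []
    n_failed = 0
    for s in seeds:
        cfg = MCConfig(**{**config.__dict__, "seed": int(s)})
        res = wang_landau_profile(network, particle, frame, cfg)
        if res.converged:
            profiles.append(res.profile.dF)
        else:
            n_failed += 1
    arr = np.array(profiles)
    mean = arr.mean(axis=0)
    sem = arr.std(axis=0, ddof=1) / math.sqrt(len(arr))
    z = (np.arange(config.n_bins) + 0.5) * frame.z_face / config.n_bins
    return z, mean, sem, n_failed


@njit(cache=True)
def _metropolis_kernel(
    pos, neigh_idx, neigh_ptr, free_idx, kspring, center, R,
    n_sweeps, n_burn, bead_step, seed, probe_center,
):
    np.random.seed(seed)
    n_sites = pos.shape[0]
    n_free = free_idx.shape[0]
    R2 = R * R
    # feasible start
    for s in range(n_sites):
        ddx = pos[s, 0] - center[0]
        ddy = pos[s, 1] - center[1]
        ddz = pos[s, 2] - center[2]
        dd = ddx * ddx + ddy * ddy + ddz * ddz
        if R > 0.0 and dd < R2:
            dn = math.sqrt(dd)
            if dn < 1e-12:
                ddx, ddy, ddz, dn = 0.0, 0.0, 1.0, 1.0
            fac = (R * 1.0001) / dn
            pos[s, 0] = center[0] + ddx * fac
            pos[s, 1] = center[1] + ddy * fac
            pos[s, 2] = center[2] + ddz * fac
    e_sum = 0.0
    e_n = 0
    acc = 0
    att = 0
    probe_ok = 0
    probe_n = 0
    for sweep in range(n_sweeps):
        for _m in range(n_free):
            s = free_idx[np.random.randint(0, n_free)]
            ox, oy, oz = pos[s, 0], pos[s, 1], pos[s, 2]
            nx = ox + (np.random.random() - 0.5) * 2.0 * bead_step
            ny = oy + (np.random.random() - 0.5) * 2.0 * bead_step
            nz = oz + (np.random.random() - 0.5) * 2.0 * bead_step
            att += 1
            ddx = nx - center[0]
            ddy = ny - center[1]
            ddz = nz - center[2]
            if R > 0.0 and ddx * ddx + ddy * ddy + ddz * ddz < R2:
                continue
            dE = 0.0
            for pp in range(neigh_ptr[s], neigh_ptr[s + 1]):
                o = neigh_idx[pp]
                dE += kspring * (
                    (nx - pos[o, 0]) ** 2 + (ny - pos[o, 1]) ** 2 + (nz - pos[o, 2]) ** 2
                    - (ox - pos[o, 0]) ** 2 - (oy - pos[o, 1]) ** 2 - (oz - pos[o, 2]) ** 2
                )
            if dE <= 0.0 or np.random.random() < math.exp(-dE):
                pos[s, 0] = nx
                pos[s, 1] = ny
                pos[s, 2] = nz
                acc += 1
        if sweep >= n_burn:
            e = 0.0
            for s in range(n_sites):
                for pp in range(neigh_ptr[s], neigh_ptr[s + 1]):
                    o = neigh_idx[pp]
                    if o > s:
                        e += kspring * (
                            (pos[s, 0] - pos[o, 0]) ** 2
                            + (pos[s, 1] - pos[o, 1]) ** 2
                            + (pos[s, 2] - pos[o, 2]) ** 2
                        )
            e_sum += e
            e_n += 1
            # survival probe: would the particle at probe_center overlap?
            ok = 1
            for s in range(n_sites):
                ddx = pos[s, 0] - probe_center[0]
                ddy = pos[s, 1] - probe_center[1]
                ddz = pos[s, 2] - probe_center[2]
                if R > 0.0 and ddx * ddx + ddy * ddy + ddz * ddz < R2:
                    ok = 0
                    break
            probe_ok += ok
            probe_n += 1
    return e_sum / max(e_n, 1), acc / max(att, 1), probe_ok / max(probe_n, 1)


def metropolis_reference(
    network: BeadSpringNetwork,
    particle: ParticleSpec | None,
    position: np.ndarray,
    n_sweeps: int = 4000,
    n_burn: int = 1000,
    bead_step: float = 0.15,
    seed: int = 0,
    probe_position: np.ndarray | None = None,
):
    """Unbiased Metropolis sampling with the particle frozen at ``position``.

    Returns ``(mean spring energy, acceptance fraction, probe survival)``.
    The probe survival is the fraction of sampled network configurations
    that would also accommodate the particle at ``probe_position``; by
    thermodynamic perturbation, ``-ln`` of it is ``F(probe) - F(position)``
    for adjacent positions.
    """
    idx, ptr, free_idx = _prepare(network)
    pos = network.positions.copy()
    R = particle.R if particle is not None else 0.0
    center = np.asarray(position, dtype=float)
    probe = np.asarray(probe_position, dtype=float) if probe_position is not None else center
    mean_e, acc, probe_surv = _metropolis_kernel(
        pos, idx, ptr, free_idx, network.spring_stiffness, center, R,
        n_sweeps, n_burn, bead_step, seed, probe,
    )
    if acc < 0.01:
        import warnings

        warnings.warn("Metropolis acceptance below 1%; reduce the move size")
    return mean_e, acc, probe_surv
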