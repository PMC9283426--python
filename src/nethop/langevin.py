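"""Underdamped Langevin transport of a nanoparticle on the MEP landscape.

The particle obeys the nonlinear Langevin equation

    m z'' = -dF/dz - gamma z' + xi(t),   <xi(t) xi(t')> = 2 gamma k_B T delta(t-t')

integrated by Euler-Maruyama in natural units (a_x = k_B T = m = 1, time
unit tau).  The free-energy profile on the half-path [0, z_face] is
periodized by even reflection (minima at even multiples of z_face, the
barrier at odd multiples), and trajectories are decomposed into waiting
and jump events between cells.

Two friction models connect the particle size to the bare friction: a
Stokes law (gamma ~ d) and a Rouse-coupling law (gamma ~ d^3 / a_x^2)
describing a particle whose drag is dominated by the local strand
dynamics, which makes the bare diffusivity scale as (d/a_x)^-3.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np
from numba import njit
from scipy.interpolate import CubicSpline

from .landscape import MEPProfile

__all__ = [
    "NLEConfig",
    "Trajectory",
    "EnsembleResult",
    "EventSeries",
    "MSDCurve",
    "VanHove",
    "PeriodicPotential",
    "periodic_potential",
    "simulate_nle",
    "simulate_ensemble",
    "diffusion_coefficient",
    "ensemble_msd",
    "detect_events",
    "van_hove",
    "classify_motion",
    "effective_friction",
]


@dataclass
class NLEConfig:
    """Euler-Maruyama integration parameters (natural units)."""

    dt: float = 0.01            # tau
    gamma_over_m: float = 10.0  # tau^-1
    m: float = 1.0
    kBT: float = 1.0
    t_total: float = 1e5        # tau
    seed: int = 0
    n_replicas: int = 32
    save_every: int = 10        # store z every this many steps
    n_v_fine: int = 200_000     # leading steps with velocity stored per replica

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.gamma_over_m <= 0:
            raise ValueError("dt and gamma/m must be positive")

    @property
    def gamma(self) -> float:
        return self.gamma_over_m * self.m

    @property
    def n_steps(self) -> int:
        return int(round(self.t_total / self.dt))


@dataclass
class Trajectory:
    t: np.ndarray
    z: np.ndarray
    v: np.ndarray | None = None
    t_v: np.ndarray | None = None


@dataclass
class EnsembleResult:
    """Replica trajectories: coarse positions plus fine leading velocities."""

    t: np.ndarray          # coarse times (n_save,)
    z: np.ndarray          # (n_replicas, n_save)
    v_fine: np.ndarray     # (n_replicas, n_v_fine)
    dt: float
    config: NLEConfig


@dataclass
class EventSeries:
    jump_times: np.ndarray
    jumps: np.ndarray      # signed displacements, multiples of the period
    waits: np.ndarray

    @property
    def t_w(self) -> float:
        if len(self.waits) == 0:
            return math.nan
        return float(np.mean(self.waits))

    @property
    def n_events(self) -> int:
        return len(self.jump_times)


@dataclass
class MSDCurve:
    t: np.ndarray
    msd: np.ndarray


@dataclass
class VanHove:
    t_slices: np.ndarray
    z_grid: np.ndarray
    G_s: np.ndarray  # (n_slices, n_bins) displacement densities


class PeriodicPotential:
    """Even-periodic extension of a half-path free-energy profile.

    Reflection about z = 0 and about z = z_face produces a profile with
    period ``2 z_face``, minima at even multiples of ``z_face`` (cell
    centers) and the barrier ``U_b`` at odd multiples (face centers).
    Cubic-spline interpolation gives a continuous force.
    """

    def __init__(self, profile: MEPProfile, clamp: bool = True):
        z = np.asarray(profile.z, dtype=float)
        dF = np.asarray(profile.dF, dtype=float)
        if not np.all(np.isfinite(dF)):
            raise ValueError("profile contains infeasible (non-finite) points")
        self.z_face = float(profile.z_face)
        self.period = 2.0 * self.z_face
        # one full period: [0, z_face] followed by the mirror image
        z_full = np.concatenate([z, 2.0 * self.z_face - z[-2::-1]])
        f_full = np.concatenate([dF, dF[-2::-1]])
        self._spline = CubicSpline(z_full, f_full, bc_type="periodic")
        self.U_b = float(np.max(dF))
        if clamp and float(self._spline(np.linspace(0, self.period, 4096)).min()) < -0.05 * max(self.U_b, 1.0):
            warnings.warn("interpolation overshoot below the profile minimum; check n_z")

    def __call__(self, z):
        return self._spline(np.mod(z, self.period))

    def force(self, z):
        """-dF/dz at z (periodic)."""
        return -self._spline(np.mod(z, self.period), 1)

    def force_table(self, n: int = 4096):
        """Uniform force lookup table over one period (for the integrator)."""
        zg = np.linspace(0.0, self.period, n, endpoint=False)
        return zg, self.force(zg)


class FlatPotential:
    """Free-diffusion landscape (Regime IV)."""

    period = math.inf
    U_b = 0.0

    def __call__(self, z):
        return np.zeros_like(np.asarray(z, dtype=float))

    def force(self, z):
        return np.zeros_like(np.asarray(z, dtype=float))

    def force_table(self, n: int = 8):
        return np.linspace(0.0, 1.0, n, endpoint=False), np.zeros(n)


def periodic_potential(profile: MEPProfile) -> PeriodicPotential:
    return PeriodicPotential(profile)


@njit(cache=True)
def _em_kernel(n_steps, dt, gamma, m, kBT, f_table, period, save_every,
               n_v_fine, seed, z0, v0):
    np.random.seed(seed)
    n_table = f_table.shape[0]
    has_force = period > 0.0 and np.isfinite(period)
    inv_dz = n_table / period if has_force else 0.0
    n_save = n_steps // save_every + 1
    z_out = np.empty(n_save)
    v_out = np.empty(min(n_v_fine, n_steps))
    z = z0
    v = v0
    z_out[0] = z
    sig = math.sqrt(2.0 * gamma * kBT * dt) / m
    isave = 1
    for step in range(n_steps):
        if has_force:
            zp = z % period
            idx = int(zp * inv_dz)
            if idx >= n_table:
                idx = n_table - 1
            F = f_table[idx]
        else:
            F = 0.0
        v += dt * (F - gamma * v) / m + sig * np.random.standard_normal()
        z += v * dt
        if abs(z) > 1e8 or abs(v) > 1e8:
            raise ValueError("NLE integration unstable; reduce dt")
        if step < v_out.shape[0]:
            v_out[step] = v
        if (step + 1) % save_every == 0:
            z_out[isave] = z
            isave += 1
    return z_out[:isave], v_out


def simulate_nle(potential, config: NLEConfig) -> Trajectory:
    """Single Euler-Maruyama trajectory; initial z = 0, Maxwell velocity."""
    rng = np.random.default_rng(config.seed)
    v0 = rng.normal(0.0, math.sqrt(config.kBT / config.m))
    _, f_table = potential.force_table()
    period = getattr(potential, "period", math.inf)
    z, v = _em_kernel(
        config.n_steps, config.dt, config.gamma, config.m, config.kBT,
        np.asarray(f_table, dtype=float),
        period if math.isfinite(period) else -1.0,
        config.save_every, config.n_v_fine, config.seed % (2**31 - 1), 0.0, v0,
    )
    t = np.arange(len(z)) * config.dt * config.save_every
    t_v = (np.arange(len(v)) + 1) * config.dt
    return Trajectory(t=t, z=z, v=v, t_v=t_v)


def simulate_ensemble(potential, config: NLEConfig) -> EnsembleResult:
    """Independent replicas with seeds spawned from ``config.seed``."""
    ss = np.random.SeedSequence(config.seed)
    seeds = ss.generate_state(config.n_replicas) % (2**31 - 1)
    rng = np.random.default_rng(config.seed)
    _, f_table = potential.force_table()
    f_table = np.asarray(f_table, dtype=float)
    period = getattr(potential, "period", math.inf)
    period_arg = period if math.isfinite(period) else -1.0
    zs, vs = [], []
    for s in seeds:
        v0 = rng.normal(0.0, math.sqrt(config.kBT / config.m))
        z, v = _em_kernel(
            config.n_steps, config.dt, config.gamma, config.m, config.kBT,
            f_table, period_arg, config.save_every, config.n_v_fine,
            int(s), 0.0, v0,
        )
        zs.append(z)
        vs.append(v)
    t = np.arange(len(zs[0])) * config.dt * config.save_every
    return EnsembleResult(t=t, z=np.array(zs), v_fine=np.array(vs), dt=config.dt, config=config)


def _autocorr_fft(x: np.ndarray) -> np.ndarray:
    n = len(x)
    m = 1 << (2 * n - 1).bit_length()
    fx = np.fft.rfft(x, m)
    acf = np.fft.irfft(fx * np.conj(fx), m)[:n].real
    return acf / np.arange(n, 0, -1)


def diffusion_coefficient(ensemble: EnsembleResult, max_lag_time: float | None = None):
    """D from the integrated velocity autocorrelation, MSD-slope cross-checked.

    The VACF is averaged over replicas; the integral cutoff is the first
    lag where the VACF stays below twice its replica standard error.
    Returns ``(D, info)`` with the MSD-slope estimate and a reliability
    flag in ``info``.
    """
    cfg = ensemble.config
    dt = ensemble.dt
    n_lag = int((max_lag_time or min(50.0 * cfg.m / cfg.gamma, ensemble.v_fine.shape[1] * dt / 4)) / dt)
    n_lag = max(min(n_lag, ensemble.v_fine.shape[1] // 2), 8)
    acfs = np.array([_autocorr_fft(v)[:n_lag] for v in ensemble.v_fine])
    vacf = acfs.mean(axis=0)
    sem = acfs.std(axis=0, ddof=1) / math.sqrt(len(acfs)) if len(acfs) > 1 else np.full(n_lag, np.inf)
    # cutoff: VACF indistinguishable from zero for 5 consecutive lags
    below = np.abs(vacf) < np.maximum(2.0 * sem, 1e-6 * abs(vacf[0]))
    cutoff = n_lag
    decayed = False
    run = 0
    for k in range(1, n_lag):
        run = run + 1 if below[k] else 0
        if run >= 5:
            cutoff = k
            decayed = True
            break
    # trapezoidal integral of the one-sided VACF (half-weighted endpoints)
    D = float(np.trapezoid(vacf[:cutoff + 1], dx=dt))
    D_err = float(np.sqrt(np.sum((sem[:cutoff + 1] * dt) ** 2))) if np.all(np.isfinite(sem[:cutoff + 1])) else math.nan

    # cross-check: long-time MSD slope / 2 over the final half of the run
    msd = ensemble_msd(ensemble, n_points=60)
    half = (msd.t > msd.t[-1] / 100) & (msd.t < msd.t[-1] / 5)
    if half.sum() >= 3 and np.all(msd.msd[half] > 0):
        slope = np.polyfit(msd.t[half], msd.msd[half], 1)[0]
        D_msd = slope / 2.0
    else:
        D_msd = math.nan
    return D, {"D_err": D_err, "D_msd": D_msd, "vacf_decayed": decayed, "cutoff_lag": cutoff}


def ensemble_msd(ensemble: EnsembleResult, n_points: int = 60) -> MSDCurve:
    """Ensemble- and time-origin-averaged MSD on a log-spaced lag grid."""
    z = ensemble.z
    n = z.shape[1]
    lags = np.unique(np.round(np.logspace(0, math.log10(n - 1), n_points)).astype(int))
    msd = np.empty(len(lags))
    for i, lag in enumerate(lags):
        diff = z[:, lag:] - z[:, :-lag]
        msd[i] = np.mean(diff * diff)
    t = lags * (ensemble.t[1] - ensemble.t[0])
    return MSDCurve(t=t, msd=msd)


def detect_events(traj_t: np.ndarray, traj_z: np.ndarray, period: float,
                  core_fraction: float = 0.25) -> EventSeries:
    """Jump/waiting decomposition of a trajectory.

    The particle's committed cell index changes only once it reaches the
    core of a new cell (within ``core_fraction * period`` of its center),
    which suppresses barrier-top recrossings.
    """
    idx = np.round(traj_z / period).astype(np.int64)
    in_core = np.abs(traj_z - idx * period) < core_fraction * period
    jump_times = []
    jumps = []
    current = idx[0] if in_core[0] else 0
    for k in range(1, len(traj_z)):
        if in_core[k] and idx[k] != current:
            jump_times.append(traj_t[k])
            jumps.append((idx[k] - current) * period)
            current = idx[k]
    jump_times = np.asarray(jump_times)
    jumps = np.asarray(jumps)
    if len(jump_times) >= 2:
        waits = np.diff(np.concatenate([[traj_t[0]], jump_times]))
    elif len(jump_times) == 1:
        waits = jump_times - traj_t[0]
    else:
        waits = np.empty(0)
    if 0 < len(jump_times) < 10:
        warnings.warn("fewer than 10 events; waiting-time statistics are wide")
    return EventSeries(jump_times=jump_times, jumps=jumps, waits=waits)


def van_hove(ensemble: EnsembleResult, t_slices, n_bins: int = 101,
             z_max: float | None = None) -> VanHove:
    """Self part of the displacement distribution at the requested times."""
    dt_save = ensemble.t[1] - ensemble.t[0]
    t_slices = np.asarray(t_slices, dtype=float)
    disp_all = []
    for ts in t_slices:
        lag = max(int(round(ts / dt_save)), 1)
        disp = (ensemble.z[:, lag:] - ensemble.z[:, :-lag]).ravel()
        disp_all.append(disp)
    zmax = z_max if z_max is not None else max(
        np.percentile(np.abs(d), 99.9) for d in disp_all
    ) * 1.1
    edges = np.linspace(-zmax, zmax, n_bins + 1)
    centers = 0.5 * (edges[1:] + edges[:-1])
    G = np.array([np.histogram(d, bins=edges, density=True)[0] for d in disp_all])
    return VanHove(t_slices=t_slices, z_grid=centers, G_s=G)


def classify_motion(msd: MSDCurve, events: EventSeries, config: NLEConfig) -> str:
    """Label the dynamics Brownian, hopping, trapped or mixed.

    Brownian: the local MSD log-slope stays near 1 after the ballistic
    regime.  Trapped: the MSD plateaus with no committed jump events.
    Hopping: a plateau followed by barrier crossings.
    """
    t_ballistic = 10.0 * config.m / config.gamma
    mask = (msd.t > t_ballistic) & (msd.t < msd.t[-1] / 20.0)  # drop poorly-averaged tail
    if mask.sum() < 5:
        raise ValueError("MSD curve too short to classify")
    logt = np.log(msd.t[mask])
    logm = np.log(np.maximum(msd.msd[mask], 1e-300))
    slopes = np.gradient(logm, logt)
    if len(slopes) >= 3:  # 3-point smoothing against sampling noise
        slopes = np.convolve(slopes, np.ones(3) / 3.0, mode="valid")
    # partition by the Brownian band: a dip below it signals caging
    caged = bool(np.min(slopes) < 0.8)
    plateau = bool(np.min(slopes) < 0.1)
    brownian = bool(np.all((slopes > 0.8) & (slopes < 1.2)))
    if brownian:
        return "Brownian"
    if plateau and events.n_events == 0:
        return "trapped"
    if caged and events.n_events > 0:
        return "hopping"
    return "mixed"


def effective_friction(d: float, model: str = "rouse_coupling",
                       gamma_ref: float = 10.0, a_x: float = 1.0) -> float:
    """Bare friction versus particle size.

    ``stokes``: gamma ~ d (continuum solvent drag).  ``rouse_coupling``:
    gamma ~ d^3/a_x^2, the strand-dominated drag that yields the
    D0 ~ (d/a_x)^-3 scaling of small-particle diffusion in networks.
    Normalized so gamma(d = a_x) = gamma_ref.
    """
    if d <= 0:
        raise ValueError("diameter must be positive")
    if model == "stokes":
        return gamma_ref * d / a_x
    if model == "rouse_coupling":
        return gamma_ref * (d / a_x) ** 3
    raise ValueError(f"unknown friction model {model!r}")
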