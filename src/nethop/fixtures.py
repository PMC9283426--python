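"""Programmatic test fixtures: small cells, short-run configs, exact series.

Everything here builds in well under a minute on one CPU; tests and the
command line (``nethop fixtures``) generate inputs at run time rather than
shipping data files.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .cells import build_cell, mep_frame, to_bead_network
from .landscape import LandscapeConfig, MEPProfile, ParticleSpec
from .langevin import NLEConfig

__all__ = [
    "free_diffusion_config",
    "cube_d14_particle",
    "power_law_series",
    "synthetic_telegraph",
    "synthetic_barrier_profile",
    "generate_fixtures",
]


def free_diffusion_config(seed: int = 0) -> NLEConfig:
    """Flat-landscape ensemble: 64 replicas of 1e4 tau."""
    return NLEConfig(t_total=1e4, n_replicas=64, seed=seed, n_v_fine=20000)


def cube_d14_particle():
    """Cube cell with the d/a_x = 1.4 particle and a low-resolution config."""
    cell = build_cell(6)
    return cell, ParticleSpec(1.4), LandscapeConfig(N=4, fluctuations=False)


def power_law_series(coeff: float = 3.0, exponent: float = 2.0, n: int = 20):
    """Exact y = coeff * x^exponent over one decade, for fit tests."""
    x = np.logspace(0.0, 1.0, n)
    return x, coeff * x**exponent


def synthetic_telegraph(jump_times, period: float = 1.0, t_total: float = 100.0, dt: float = 0.01):
    """Piecewise-constant trajectory with known jumps at ``jump_times``."""
    t = np.arange(0.0, t_total, dt)
    z = np.zeros_like(t)
    level = 0.0
    jt = sorted(jump_times)
    k = 0
    for i, ti in enumerate(t):
        while k < len(jt) and ti >= jt[k]:
            level += period
            k += 1
        z[i] = level
    return t, z


def synthetic_barrier_profile(U_b: float = 6.0, z_face: float = 0.5, n: int = 64) -> MEPProfile:
    """Smooth half-path profile 0 -> U_b with zero slope at both ends."""
    z = np.linspace(0.0, z_face, n)
    dF = U_b * np.sin(0.5 * np.pi * z / z_face) ** 2
    return MEPProfile(z=z, dF=dF, d=1.5, g_label=6, z_face=z_face)


def generate_fixtures(out_dir) -> dict:
    """Write the fixture suite to ``out_dir``; idempotent."""
    from . import io as nio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fixtures = {}

    cell, particle, _ = cube_d14_particle()
    nio.write_off(cell, out / "cube.off")
    net = to_bead_network(cell, N=4)
    nio.write_xyz(net, out / "cube_beads.xyz")
    nio.write_network_json(net, out / "cube_beads.json")
    fixtures["cube"] = str(out / "cube.off")

    x, y = power_law_series()
    np.savetxt(out / "power_law_series.csv", np.c_[x, y], delimiter=",", header="x,y", comments="")
    fixtures["power-law-series"] = str(out / "power_law_series.csv")

    prof = synthetic_barrier_profile()
    nio.write_profile_csv(prof.z, prof.dF, out / "barrier_profile.csv")
    fixtures["barrier-profile"] = str(out / "barrier_profile.csv")

    cfg = free_diffusion_config()
    nio.dump_config(
        {"kind": "nle", "t_total": cfg.t_total, "dt": cfg.dt, "gamma_over_m": cfg.gamma_over_m,
         "n_replicas": cfg.n_replicas, "seed": cfg.seed},
        out / "free_diffusion.yaml",
    )
    fixtures["free-diffusion"] = str(out / "free_diffusion.yaml")
    return fixtures
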