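"""Langevin engine: free-diffusion limits, equilibrium, events, classification."""

import math

import numpy as np
import pytest
from scipy import stats

from nethop import (
    NLEConfig,
    classify_motion,
    detect_events,
    diffusion_coefficient,
    effective_friction,
    ensemble_msd,
    periodic_potential,
    simulate_ensemble,
    simulate_nle,
    van_hove,
)
from nethop.fixtures import synthetic_barrier_profile, synthetic_telegraph
from nethop.landscape import MEPProfile
from nethop.langevin import FlatPotential


@pytest.fixture(scope="module")
def flat_ensemble():
    cfg = NLEConfig(t_total=1e4, n_replicas=32, seed=101, n_v_fine=30_000)
    return simulate_ensemble(FlatPotential(), cfg)


def test_periodic_potential_reflection_and_period():
    prof = synthetic_barrier_profile(U_b=4.0, z_face=0.5)
    pot = periodic_potential(prof)
    xs = np.linspace(0.0, 0.45, 7)
    assert np.allclose(pot(0.5 + xs), pot(0.5 - xs), atol=1e-9)
    assert pot(1.0) == pytest.approx(0.0, abs=1e-9)  # next cell center
    zz = np.linspace(0, pot.period, 2000)
    assert np.max(pot(zz)) == pytest.approx(4.0, rel=1e-3)


def test_free_diffusion_coefficient(flat_ensemble):
    """D0 = k_B T / gamma from the VACF integral, MSD cross-checked."""
    D, info = diffusion_coefficient(flat_ensemble)
    assert info["vacf_decayed"]
    assert D == pytest.approx(0.1, rel=0.05)
    assert info["D_msd"] == pytest.approx(D, rel=0.25)


def test_harmonic_equipartition():
    """Deep well: stationary <z^2> = k_B T / omega^2 (trapped particle)."""
    w2 = 200.0  # barrier 25 kBT: no escapes over the run
    z = np.linspace(0, 0.5, 64)
    prof = MEPProfile(z=z, dF=0.5 * w2 * z**2, d=1.0, g_label=6, z_face=0.5)
    pot = periodic_potential(prof)
    cfg = NLEConfig(t_total=5e3, n_replicas=16, seed=7)
    ens = simulate_ensemble(pot, cfg)
    zs = ens.z[:, ens.z.shape[1] // 5 :]
    assert np.mean(zs**2) == pytest.approx(1.0 / w2, rel=0.1)


def test_equilibrium_histogram_matches_boltzmann():
    """Long-run position histogram in a periodic landscape follows
    exp(-dF(z)) (chi-square test)."""
    prof = synthetic_barrier_profile(U_b=1.5, z_face=0.5)
    pot = periodic_potential(prof)
    cfg = NLEConfig(t_total=4e4, n_replicas=16, seed=23, save_every=50)
    ens = simulate_ensemble(pot, cfg)
    pos = np.mod(ens.z[:, 200:].ravel(), pot.period)
    n_bins = 16
    edges = np.linspace(0, pot.period, n_bins + 1)
    counts, _ = np.histogram(pos, bins=edges)
    centers = 0.5 * (edges[1:] + edges[:-1])
    expected = np.exp(-pot(centers))
    expected *= counts.sum() / expected.sum()
    # thin to approximately independent samples for the chi-square scale
    n_eff_frac = 0.05
    chi2 = float(np.sum((counts - expected) ** 2 / expected)) * n_eff_frac
    p = stats.chi2.sf(chi2, n_bins - 1)
    assert p > 0.01


def test_detect_events_exact_on_telegraph():
    jump_at = [10.0, 30.0, 55.0, 80.0]
    t, z = synthetic_telegraph(jump_at, period=1.0)
    ev = detect_events(t, z, period=1.0)
    assert ev.n_events == 4
    assert np.allclose(ev.jump_times, jump_at, atol=0.02)
    assert np.allclose(ev.jumps, 1.0)


def test_trapped_run_has_no_events():
    t = np.arange(0, 100, 0.1)
    z = 0.05 * np.sin(t)
    ev = detect_events(t, z, period=1.0)
    assert ev.n_events == 0
    assert math.isnan(ev.t_w)


def test_jump_count_grows_linearly_free_diffusion(flat_ensemble):
    """<N(t)> = t / t_w for cell crossings of a free walker."""
    period = 1.0
    counts = []
    for zr in flat_ensemble.z:
        ev = detect_events(flat_ensemble.t, zr, period)
        counts.append(ev)
    pooled_waits = np.concatenate([ev.waits for ev in counts if ev.n_events > 1])
    t_w = pooled_waits.mean()
    # cumulative mean N(t) across replicas on a time grid
    grid = np.linspace(500, flat_ensemble.t[-1], 30)
    mean_n = [
        np.mean([np.searchsorted(ev.jump_times, g) for ev in counts]) for g in grid
    ]
    slope, intercept, r, *_ = stats.linregress(grid, mean_n)
    assert r**2 > 0.99
    assert slope == pytest.approx(1.0 / t_w, rel=0.1)


def test_van_hove_free_diffusion_gaussian():
    cfg = NLEConfig(t_total=200.0, n_replicas=256, seed=71, save_every=10)
    ens = simulate_ensemble(FlatPotential(), cfg)
    t_slice = 50.0
    lag = int(round(t_slice / (ens.t[1] - ens.t[0])))
    disp = ens.z[:, lag] - ens.z[:, 0]  # independent across replicas
    ks = stats.kstest(disp, "norm", args=(0.0, math.sqrt(2 * 0.1 * t_slice)))
    assert ks.pvalue > 0.01
    vh = van_hove(ens, [t_slice])
    dz = vh.z_grid[1] - vh.z_grid[0]
    assert np.sum(vh.G_s[0]) * dz == pytest.approx(1.0, abs=1e-6)


def test_van_hove_multipeaked_in_hopping_regime():
    """High barrier: displacement distribution peaks at multiples of the period."""
    prof = synthetic_barrier_profile(U_b=5.0, z_face=0.5)
    pot = periodic_potential(prof)
    cfg = NLEConfig(t_total=2e4, n_replicas=32, seed=37, save_every=100)
    ens = simulate_ensemble(pot, cfg)
    waits = np.concatenate(
        [detect_events(ens.t, zr, pot.period).waits for zr in ens.z]
    )
    t_w = float(np.mean(waits))
    vh = van_hove(ens, [t_w], n_bins=81, z_max=2.5)
    g = vh.G_s[0]
    center_peak = g[np.abs(vh.z_grid) < 0.25].max()
    side_peak = g[(vh.z_grid > 0.75) & (vh.z_grid < 1.25)].max()
    trough = g[(vh.z_grid > 0.35) & (vh.z_grid < 0.65)].min()
    assert center_peak > side_peak > trough  # peaks at multiples of the period


def test_classification_three_regimes():
    cfg = NLEConfig(t_total=2e4, n_replicas=16, seed=55)
    # flat -> Brownian
    ens = simulate_ensemble(FlatPotential(), cfg)
    msd = ensemble_msd(ens)
    ev = detect_events(ens.t, ens.z[0], period=1.0)
    assert classify_motion(msd, ev, cfg) == "Brownian"
    # moderate barrier -> hopping
    pot = periodic_potential(synthetic_barrier_profile(U_b=4.5, z_face=0.5))
    ens2 = simulate_ensemble(pot, cfg)
    msd2 = ensemble_msd(ens2)
    ev2 = detect_events(ens2.t, ens2.z[0], pot.period)
    assert classify_motion(msd2, ev2, cfg) == "hopping"
    # huge barrier -> trapped
    pot3 = periodic_potential(synthetic_barrier_profile(U_b=14.0, z_face=0.5))
    ens3 = simulate_ensemble(pot3, cfg)
    msd3 = ensemble_msd(ens3)
    ev3 = detect_events(ens3.t, ens3.z[0], pot3.period)
    assert classify_motion(msd3, ev3, cfg) == "trapped"


def test_effective_friction_models():
    assert effective_friction(1.0, "rouse_coupling", gamma_ref=10.0) == 10.0
    assert effective_friction(2.0, "rouse_coupling", gamma_ref=10.0) == 80.0
    assert effective_friction(2.0, "stokes", gamma_ref=10.0) == 20.0
    with pytest.raises(ValueError):
        effective_friction(1.0, "reptation")


def test_single_trajectory_interface():
    traj = simulate_nle(FlatPotential(), NLEConfig(t_total=100.0, seed=3))
    assert len(traj.t) == len(traj.z)
    assert np.all(np.isfinite(traj.z))
    dt = np.diff(traj.t)
    assert np.allclose(dt, dt[0])
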