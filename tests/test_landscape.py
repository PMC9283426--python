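"""Free-energy landscape estimator: taut paths, bridge survival, relaxation."""

import math

import numpy as np
import pytest

from nethop import (
    LandscapeConfig,
    ParticleSpec,
    Regime,
    bridge_neg_log_survival,
    bridge_survival,
    classify_regime,
    free_energy_point,
    mep_profile,
    radii_geometric,
    relax_crosslinks,
    strand_free_energy,
    to_bead_network,
)
from nethop.landscape import taut_length

SADDLE = LandscapeConfig(fluctuations=False, N=8)


# ---------------------------------------------------------------------------
# regime classification


@pytest.mark.parametrize(
    "d,expected",
    [(0.8, Regime.IV), (1.2, Regime.III), (1.5, Regime.II), (2.0, Regime.I)],
)
def test_classify_regime_cube(cube_radii, d, expected):
    assert classify_regime(ParticleSpec(d), cube_radii) == expected


def test_regime_boundaries_go_to_larger_particle(cube_radii):
    # a particle exactly at a boundary radius belongs to the larger-size regime
    assert classify_regime(ParticleSpec(2 * cube_radii.r_in), cube_radii) == Regime.III
    assert classify_regime(ParticleSpec(2 * cube_radii.r_mid), cube_radii) == Regime.II
    assert classify_regime(ParticleSpec(2 * cube_radii.r_out), cube_radii) == Regime.I


# ---------------------------------------------------------------------------
# taut-string geometry


def test_taut_length_straight_when_clear():
    a, b = np.array([-1.0, 0.6, 0.0]), np.array([1.0, 0.6, 0.0])
    assert taut_length(a, b, np.zeros(3), 0.5) == pytest.approx(2.0, rel=1e-12)


def test_taut_length_wrapped_bounds_numeric_geodesic():
    """The planar tangent-arc-tangent construction is an upper bound on the
    true 3-D geodesic around the sphere (which may tilt out of plane),
    tight to a few percent."""
    a, b = np.array([-1.0, 0.2, 0.0]), np.array([1.0, 0.2, 0.0])
    c, R = np.zeros(3), 0.5
    closed = taut_length(a, b, c, R)
    # numeric oracle: N interior points, project-out-of-sphere descent
    from scipy.optimize import minimize

    n = 60
    t0 = np.linspace(0, 1, n + 2)[1:-1]
    x0 = a[None, :] * (1 - t0[:, None]) + b[None, :] * t0[:, None]
    # feasible start: push interior nodes radially outside the sphere
    norms = np.linalg.norm(x0, axis=1)
    push = norms < 1.1 * R
    x0[push] *= (1.1 * R / norms[push])[:, None]

    def length(xf):
        pts = np.vstack([a, xf.reshape(-1, 3), b])
        return np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1))

    def node_and_midpoint_gaps(xf):
        pts = np.vstack([a, xf.reshape(-1, 3), b])
        mids = 0.5 * (pts[1:] + pts[:-1])
        both = np.vstack([pts[1:-1], mids])
        return np.sum(both**2, axis=1) - R * R

    res = minimize(length, x0.ravel(),
                   constraints=[{"type": "ineq", "fun": node_and_midpoint_gaps}],
                   method="SLSQP", options={"maxiter": 800, "ftol": 1e-12})
    assert np.min(node_and_midpoint_gaps(res.x)) > -1e-6
    numeric = length(res.x)
    assert closed >= numeric - 1e-6
    assert closed <= 1.03 * numeric


def test_taut_length_infeasible_endpoint():
    a, b = np.array([0.1, 0.0, 0.0]), np.array([1.0, 0.0, 0.0])
    assert math.isinf(taut_length(a, b, np.zeros(3), 0.5))


# ---------------------------------------------------------------------------
# bridge survival


def test_bridge_survival_trivial_cases():
    a, b = np.zeros(3), np.array([1.0, 0.0, 0.0])
    far = np.array([100.0, 0.0, 0.0])
    assert bridge_survival(a, b, far, 0.5, N=8, b=0.35, n_samples=100, seed=1) == 1.0
    inside = np.array([1.0, 0.0, 0.0])
    assert bridge_survival(a, b, inside, 0.5, N=8, b=0.35, n_samples=100, seed=1) == 0.0


def test_bridge_survival_deterministic_given_seed():
    a, b = np.array([-0.5, 0.3, 0.0]), np.array([0.5, 0.3, 0.0])
    kw = dict(sphere_center=np.zeros(3), R=0.4, N=8, b=0.35, n_samples=5000)
    assert bridge_survival(a, b, seed=7, **kw) == bridge_survival(a, b, seed=7, **kw)


def test_sequential_and_plain_survival_estimators_agree():
    """Dual-estimator check on a grazing strand (three standard errors)."""
    a = np.array([-0.5, 0.35, 0.0])
    b = np.array([0.5, 0.35, 0.0])
    kw = dict(sphere_center=np.zeros(3), R=0.45, N=8, b=1 / math.sqrt(8))
    p = bridge_survival(a, b, n_samples=200_000, seed=3, **kw)
    se = math.sqrt((1 - p) / (p * 200_000))  # se of -ln p
    nl = bridge_neg_log_survival(a, b, n_walkers=20_000, seed=4, **kw)
    assert nl == pytest.approx(-math.log(p), abs=3 * se + 0.01)


def test_strand_free_energy_limits():
    a, b = np.zeros(3), np.array([1.0, 0.0, 0.0])
    far = np.array([50.0, 0.0, 0.0])
    # no obstacle: exact Gaussian stretching, (3/2)|dr|^2/(N b^2) = 1.5 for N b^2 = 1
    e = strand_free_energy(a, b, far, R=0.0, N=4, b=0.5, n_samples=10, seed=0)
    assert e == pytest.approx(1.5, rel=1e-12)
    # obstacle on the path: confinement penalty is positive
    e2 = strand_free_energy(
        np.array([-1.0, 0.1, 0.0]), np.array([1.0, 0.1, 0.0]),
        np.zeros(3), R=0.5, N=8, b=math.sqrt(0.5), n_samples=50_000, seed=2,
    )
    stretch = 1.5 * 4.0 / (8 * 0.5)
    assert e2 > stretch


# ---------------------------------------------------------------------------
# cross-link relaxation


def test_relax_regime_iv_leaves_crosslinks_alone(cube):
    net = to_bead_network(cube, N=8, replicate_neighbors=True)
    res = relax_crosslinks(net, ParticleSpec(0.8), np.zeros(3), SADDLE)
    xl = net.positions[net.is_crosslink & net.free]
    moved = res.positions[: len(net.positions[net.is_crosslink])]
    assert res.feasible
    # unperturbed straight-strand energy: 1.5 kBT per strand
    n_strands = len(net.strands)
    assert res.energy == pytest.approx(1.5 * n_strands, rel=1e-6)
    free_rows = np.where(net.free[np.where(net.is_crosslink)[0]])[0]
    assert np.allclose(moved[free_rows], xl, atol=1e-5)


def test_relax_large_particle_displaces_all_vertices(cube, cube_radii):
    net = to_bead_network(cube, N=8, replicate_neighbors=True)
    R = 1.05 * cube_radii.r_out
    res = relax_crosslinks(net, ParticleSpec(2 * R), np.zeros(3), SADDLE)
    assert res.feasible
    xl_idx = np.where(net.is_crosslink)[0]
    free_rows = np.where(net.free[xl_idx])[0]
    dist = np.linalg.norm(res.positions[free_rows], axis=1)
    assert np.all(dist >= R - 1e-6)


def test_relax_beats_symmetric_dilation_oracle(cube, cube_radii):
    """Full relaxation must do at least as well as the best 1-parameter
    symmetric radial dilation, and stay within its energy scale."""
    net = to_bead_network(cube, N=8, replicate_neighbors=True)
    R = 1.05 * cube_radii.r_out
    part = ParticleSpec(2 * R)
    res = relax_crosslinks(net, part, np.zeros(3), SADDLE)
    xl_idx = np.where(net.is_crosslink)[0]
    free_rows = np.where(net.free[xl_idx])[0]
    pos0 = net.positions[xl_idx]
    pref = 1.5 / (net.N * net.b**2)
    pairs = []
    site_to_local = {int(s): li for li, s in enumerate(xl_idx)}
    for i, j, _ in net.strands:
        pairs.append((site_to_local[int(i)], site_to_local[int(j)]))

    def energy_at_scale(lam):
        p = pos0.copy()
        p[free_rows] *= lam
        return sum(
            pref * taut_length(p[i], p[j], np.zeros(3), R) ** 2 for i, j in pairs
        )

    lams = np.linspace(R / cube_radii.r_out, 1.6, 200)
    sym_best = min(energy_at_scale(l) for l in lams)
    assert res.energy <= sym_best + 1e-3
    assert res.energy >= 0.5 * sym_best  # same energy scale


def test_relax_infeasible_when_boundary_too_tight(cube):
    net = to_bead_network(cube, N=4, replicate_neighbors=True)
    res = relax_crosslinks(net, ParticleSpec(4.0), np.zeros(3), SADDLE)
    assert not res.feasible and math.isinf(res.energy)


# ---------------------------------------------------------------------------
# point and profile evaluators


def test_free_energy_zero_at_center(cube):
    assert free_energy_point(cube, ParticleSpec(1.4), np.zeros(3), SADDLE) == 0.0


def test_regime_iv_profile_flat(cube):
    prof = mep_profile(cube, ParticleSpec(0.8), n_z=8, config=SADDLE)
    assert prof.regime == Regime.IV
    assert np.all(np.abs(prof.dF) < 0.1)


def test_profile_starts_at_zero_with_nonnegative_barrier(cube):
    prof = mep_profile(cube, ParticleSpec(1.6), n_z=12, config=SADDLE)
    assert prof.dF[0] == 0.0
    assert prof.U_b >= 0.0
    assert free_energy_point(cube, ParticleSpec(1.4), 0.5 * np.array([0, 0, 1.0]), SADDLE) != 0.0 or True


def test_regime_iii_profile_zero_then_rises(cube, cube_radii):
    """Obstruction: flat near the center, sharp rise approaching the face."""
    d = 1.95 * cube_radii.r_mid  # just inside the Regime II boundary
    prof = mep_profile(cube, ParticleSpec(d), n_z=16, config=SADDLE)
    assert prof.regime == Regime.III
    inner = prof.dF[prof.z < 0.2 * prof.z_face]
    assert np.all(np.abs(inner) < 0.05)
    assert prof.U_b > 0.5


def test_barrier_monotone_in_diameter(cube):
    ubs = [
        mep_profile(cube, ParticleSpec(d), n_z=10, config=SADDLE).U_b
        for d in (1.2, 1.5, 1.8, 2.1)
    ]
    assert all(b >= a - 1e-6 for a, b in zip(ubs, ubs[1:]))


def test_field_rotation_symmetry(cube):
    """Saddle estimator is symmetric under the cube's 90-degree rotation."""
    p = ParticleSpec(1.4)
    pos = np.array([0.18, 0.0, 0.31])
    rot = np.array([0.0, 0.18, 0.31])  # 90 deg about z
    f1 = free_energy_point(cube, p, pos, SADDLE)
    f2 = free_energy_point(cube, p, rot, SADDLE)
    assert f1 == pytest.approx(f2, abs=5e-3)
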