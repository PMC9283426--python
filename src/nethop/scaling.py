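"""Regime maps, exponent fits, barrier scans and master-curve collapses.

The size regimes of a cell are bounded by the particle diameters
``2 r_in < 2 r_mid < 2 r_out``; as the topology label g grows the cells
become more spherical, the boundaries approach each other and Regimes II
and III shrink.  Diffusivities collapse onto master curves when both D and
d are normalized at ``2 r_in`` (power-law branch, slope -3) or ``2 r_out``
(exponential branch).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cells import build_cell, radii_geometric
from .landscape import LandscapeConfig, MEPProfile, ParticleSpec, mep_profile

__all__ = [
    "ExponentFit",
    "RegimeDiagram",
    "fit_exponent",
    "barrier_scan",
    "master_curve",
    "regime_diagram",
    "eta_heatmap",
]


@dataclass
class ExponentFit:
    eta: float
    stderr: float
    window: tuple[float, float]
    n_points: int


@dataclass
class RegimeDiagram:
    """Regime boundary diameters per cell (units of a_x)."""

    g_labels: list[int]
    boundary_III_IV: dict[int, float]  # d = 2 r_in
    boundary_II_III: dict[int, float]  # d = 2 r_mid
    boundary_I_II: dict[int, float]    # d = 2 r_out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "g": self.g_labels,
                "d_III_IV": [self.boundary_III_IV[g] for g in self.g_labels],
                "d_II_III": [self.boundary_II_III[g] for g in self.g_labels],
                "d_I_II": [self.boundary_I_II[g] for g in self.g_labels],
            }
        )


def fit_exponent(x, y, window: tuple[float, float] | None = None) -> ExponentFit:
    """Least-squares log-log slope of ``y ~ x^eta`` within ``window`` on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = (x > 0) & (y > 0)
    if window is not None:
        mask &= (x >= window[0]) & (x <= window[1])
    if mask.sum() < 5:
        raise ValueError(f"need at least 5 positive points in the fit window, got {mask.sum()}")
    lx, ly = np.log(x[mask]), np.log(y[mask])
    A = np.vstack([lx, np.ones_like(lx)]).T
    coef, res, *_ = np.linalg.lstsq(A, ly, rcond=None)
    n = mask.sum()
    if n > 2 and len(res):
        s2 = res[0] / (n - 2)
        cov = s2 * np.linalg.inv(A.T @ A)
        stderr = float(np.sqrt(cov[0, 0]))
    else:
        stderr = 0.0
    xm = x[mask]
    return ExponentFit(eta=float(coef[0]), stderr=stderr, window=(float(xm.min()), float(xm.max())), n_points=int(n))


def regime_i_eta(profile: MEPProfile) -> ExponentFit:
    """Regime-I exponent: outer half of the path, z in [z_face/2, z_face]."""
    return fit_exponent(profile.z, profile.dF, window=(profile.z_face / 2.0, profile.z_face))


def regime_ii_eta(profile: MEPProfile) -> ExponentFit:
    """Regime-II small-z exponent: inner window z in (0, z_face/4]."""
    return fit_exponent(profile.z, profile.dF, window=(1e-12, profile.z_face / 4.0))


def barrier_scan(
    g_labels,
    d_grid,
    config: LandscapeConfig | None = None,
    n_z: int = 16,
) -> pd.DataFrame:
    """Barrier U_b(d; g) table with regime-boundary markers.

    Columns: g, d, U_b, regime, feasible, at_2r_mid, at_2r_out.
    Infeasible combinations (particle too large for the pinned boundary)
    carry ``feasible=False`` and ``U_b=inf``.
    """
    config = config or LandscapeConfig(fluctuations=False)
    rows = []
    for g in g_labels:
        cell = build_cell(g)
        radii = radii_geometric(cell)
        for d in np.atleast_1d(d_grid):
            prof = mep_profile(cell, ParticleSpec(float(d)), n_z=n_z, config=config)
            rows.append(
                {
                    "g": g,
                    "d": float(d),
                    "U_b": prof.U_b,
                    "regime": prof.regime.value if prof.regime else None,
                    "feasible": not prof.truncated,
                    "at_2r_mid": math.isclose(d, 2 * radii.r_mid, rel_tol=1e-6),
                    "at_2r_out": math.isclose(d, 2 * radii.r_out, rel_tol=1e-6),
                }
            )
    return pd.DataFrame(rows)


def master_curve(records, norm: str = "r_in"):
    """Collapse (g, d, D) records onto D/D(2 r_norm) versus d/(2 r_norm).

    Returns ``(DataFrame, ExponentFit | None, r_squared | None)``:
    the pooled power-law slope on the ``d <= 2 r_in`` branch for
    ``norm='r_in'``, or the quality (R^2) of a linear ln D ~ d^2 fit on
    the ``d >= 2 r_out`` branch for ``norm='r_out'``.
    """
    if norm not in ("r_in", "r_out"):
        raise ValueError("norm must be 'r_in' or 'r_out'")
    df = pd.DataFrame(records, columns=["g", "d", "D"])
    out = []
    for g, grp in df.groupby("g"):
        radii = radii_geometric(build_cell(int(g)))
        r_norm = radii.r_in if norm == "r_in" else radii.r_out
        d_ref = 2.0 * r_norm
        grp = grp.sort_values("d")
        if np.any(np.isclose(grp["d"], d_ref, rtol=1e-9)):
            D_ref = float(grp.loc[np.isclose(grp["d"], d_ref, rtol=1e-9), "D"].iloc[0])
        else:
            import warnings

            warnings.warn(f"no record at d = 2 {norm} for g={g}; interpolating")
            D_ref = float(np.interp(d_ref, grp["d"], grp["D"]))
        sub = grp.assign(x=grp["d"] / d_ref, y=grp["D"] / D_ref)
        out.append(sub)
    coll = pd.concat(out, ignore_index=True)
    if norm == "r_in":
        branch = coll[coll["x"] <= 1.0 + 1e-9]
        fit = fit_exponent(branch["x"], branch["y"]) if len(branch) >= 5 else None
        return coll, fit, None
    branch = coll[coll["x"] >= 1.0 - 1e-9]
    if len(branch) >= 3 and (branch["y"] > 0).all():
        lnD = np.log(branch["y"].to_numpy())
        d2 = (branch["d"].to_numpy()) ** 2
        A = np.vstack([d2, np.ones_like(d2)]).T
        coef, res, *_ = np.linalg.lstsq(A, lnD, rcond=None)
        ss_tot = np.sum((lnD - lnD.mean()) ** 2)
        r2 = 1.0 - (res[0] / ss_tot if len(res) and ss_tot > 0 else 0.0)
        return coll, None, float(r2)
    return coll, None, None


def regime_diagram(g_labels) -> RegimeDiagram:
    """Regime boundary diameters (2 r_in, 2 r_mid, 2 r_out) per catalog cell."""
    b34, b23, b12 = {}, {}, {}
    for g in g_labels:
        radii = radii_geometric(build_cell(int(g)))
        b34[g] = 2.0 * radii.r_in
        b23[g] = 2.0 * radii.r_mid
        b12[g] = 2.0 * radii.r_out
    return RegimeDiagram(list(g_labels), b34, b23, b12)


def eta_heatmap(profiles: list[MEPProfile]) -> pd.DataFrame:
    """Long-format (d, z, dF) table of a profile family sharing one cell,
    with the cell's regime boundaries attached as attrs."""
    if not profiles:
        raise ValueError("no profiles given")
    g = profiles[0].g_label
    if any(p.g_label != g for p in profiles):
        raise ValueError("profiles must share a cell")
    rows = []
    for p in profiles:
        for z, f in zip(p.z, p.dF):
            rows.append({"d": p.d, "z": float(z), "dF": float(f)})
    df = pd.DataFrame(rows)
    diagram = regime_diagram([g])
    df.attrs["boundary_II_III"] = diagram.boundary_II_III[g]
    df.attrs["boundary_I_II"] = diagram.boundary_I_II[g]
    return df
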