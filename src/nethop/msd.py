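"""Regime-resolved analytic MSD theory for a particle in a network cell.

Before a hopping event (t < t_w) the particle moves in the local free
energy landscape, whose shape depends on the size regime:

* Regime I — V-shaped potential ``rho |z|`` with slope ``rho = U_b/r_in``:
  the MSD is known in the Laplace domain and is inverted numerically
  (fixed-Talbot); it saturates at ``2 D0 t_w - rho^2 t_w^2 (Delta0 - 1)``
  with ``Delta0 = sqrt(1 + 4 D0/(rho^2 t_w))``.
* Regime II — harmonic potential ``omega^2 z^2 / 2`` with
  ``omega = sqrt(2 U_b)/r_in``: classical Brownian harmonic oscillator,
  overdamped for ``gamma > sqrt(8) m omega`` (rate ``beta1``) and
  underdamped otherwise (frequency ``omega1``), both saturating at
  ``k_B T/(m omega^2)``.
* Regime III — free diffusion between reflecting walls at ``+-r_in``:
  ``(r_in^2/6) (1 - exp(-t/tau0))``.

The total MSD composes the short-time form with hopping renewal:
``(t/t_w) <dz^2>`` for ``t >= t_w``.  Natural units ``m = k_B T = 1``
are assumed throughout unless overridden in :class:`RegimeParams`.
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

from .landscape import Regime

__all__ = [
    "RegimeParams",
    "params_from_landscape",
    "invert_laplace_talbot",
    "msd_regime1",
    "msd_regime2",
    "msd_regime3",
    "compose_total_msd",
    "oscillation_mode",
]


@dataclass
class RegimeParams:
    """Parameter bundle mapping a landscape onto the analytic MSD forms."""

    rho: float = 0.0        # V-potential slope, k_B T / a_x
    omega: float = 0.0      # harmonic frequency, tau^-1
    t_w: float = math.inf   # waiting time, tau
    D0: float = 0.1         # bare diffusivity, a_x^2/tau
    r_in: float = 0.5       # a_x
    m: float = 1.0
    gamma: float = 10.0
    kBT: float = 1.0
    tau0: float | None = None  # Regime-III relaxation time; default r_in^2/(12 D0)

    def __post_init__(self) -> None:
        if self.tau0 is None:
            # chosen so the short-time expansion matches free diffusion 2 D0 t
            self.tau0 = self.r_in**2 / (12.0 * self.D0)

    @property
    def omega1(self) -> float:
        """Underdamped frequency sqrt(omega^2 - (gamma/m)^2/8); nan if overdamped."""
        val = self.omega**2 - (self.gamma / self.m) ** 2 / 8.0
        return math.sqrt(val) if val >= 0 else math.nan

    @property
    def beta1(self) -> float:
        """Overdamped rate sqrt((gamma/m)^2 - 8 omega^2); nan if underdamped."""
        val = (self.gamma / self.m) ** 2 - 8.0 * self.omega**2
        return math.sqrt(val) if val >= 0 else math.nan

    @property
    def Delta0(self) -> float:
        return math.sqrt(1.0 + 4.0 * self.D0 / (self.rho**2 * self.t_w))

    @property
    def plateau_regime1(self) -> float:
        """Long-time MSD limit in Regime I."""
        return 2.0 * self.D0 * self.t_w - self.rho**2 * self.t_w**2 * (self.Delta0 - 1.0)

    @property
    def plateau_regime2(self) -> float:
        return self.kBT / (self.m * self.omega**2)


def params_from_landscape(
    U_b: float,
    r_in: float,
    t_w: float,
    D0: float = 0.1,
    m: float = 1.0,
    gamma: float = 10.0,
    kBT: float = 1.0,
    tau0: float | None = None,
) -> RegimeParams:
    """Map a barrier and inradius onto the analytic-theory parameters:
    ``rho = U_b / r_in`` and ``omega = sqrt(2 U_b) / r_in``."""
    if U_b < 0 or r_in <= 0:
        raise ValueError("need U_b >= 0 and r_in > 0")
    return RegimeParams(
        rho=U_b / r_in,
        omega=math.sqrt(2.0 * U_b) / r_in,
        t_w=t_w,
        D0=D0,
        r_in=r_in,
        m=m,
        gamma=gamma,
        kBT=kBT,
        tau0=tau0,
    )


def invert_laplace_talbot(F, t: float, M: int = 32) -> float:
    """Fixed-Talbot numerical inverse Laplace transform at time ``t``.

    ``F`` maps a complex Laplace variable to a complex value.  Uses the
    Abate-Valko fixed-Talbot contour with ``M`` nodes.
    """
    if t <= 0:
        raise ValueError("t must be positive")
    r = 2.0 * M / (5.0 * t)
    total = 0.5 * F(complex(r, 0.0)) * math.exp(r * t)
    for k in range(1, M):
        theta = k * math.pi / M
        cot = math.cos(theta) / math.sin(theta)
        s = r * theta * complex(cot, 1.0)
        sigma = theta + (theta * cot - 1.0) * cot
        total += (cmath.exp(t * s) * F(s) * complex(1.0, sigma)).real
    return (r / M) * total.real if isinstance(total, complex) else (r / M) * total


def _msd1_laplace(s: complex, p: RegimeParams) -> complex:
    root = cmath.sqrt(1.0 + 4.0 * p.D0 * (1.0 / p.t_w + s) / p.rho**2)
    return (8.0 * p.D0**2 / p.rho**2) / (s * (1.0 + root) ** 2)


def msd_regime1(t, params: RegimeParams, M: int = 32):
    """MSD in the V-shaped (Regime I) potential by inverse Laplace transform."""
    if params.rho <= 0:
        raise ValueError("Regime I requires rho > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = np.array([invert_laplace_talbot(lambda s: _msd1_laplace(s, params), ti, M) for ti in t_arr])
    return out if np.ndim(t) else float(out[0])


def msd_regime2(t, params: RegimeParams):
    """MSD of the Brownian harmonic oscillator (Regime II), both branches.

    Overdamped (``gamma > sqrt(8) m omega``)::

        (kBT/m w^2)[1 - e^{-gt/2m}(2 sinh^2(b1 t/4) + (g/m b1) sinh(b1 t/2) + 1)]

    Underdamped (``gamma < sqrt(8) m omega``)::

        (kBT/m w^2)[1 - e^{-gt/2m}(-2 sin^2(w1 t/sqrt 2) + (g/(sqrt 8 m w1)) sin(sqrt 2 w1 t) + 1)]
    """
    if params.omega <= 0:
        raise ValueError("Regime II requires omega > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    g, m, w = params.gamma, params.m, params.omega
    amp = params.kBT / (m * w * w)
    decay = np.exp(-g * t_arr / (2.0 * m))
    disc = (g / m) ** 2 - 8.0 * w * w
    if disc >= 0:
        b1 = math.sqrt(disc)
        lam = g / m
        if b1 < 1e-10 * lam:  # critical point: b1 -> 0 limit of the bracket
            out = amp * (1.0 - decay * (lam * t_arr / 2.0 + 1.0))
        else:
            # e^{-lam t/2} [cosh(b1 t/2) - 1 + (lam/b1) sinh(b1 t/2) + 1]
            # = ((1 + lam/b1) e^{-(lam-b1)t/2} + (1 - lam/b1) e^{-(lam+b1)t/2}) / 2
            term = 0.5 * (
                (1.0 + lam / b1) * np.exp(-(lam - b1) * t_arr / 2.0)
                + (1.0 - lam / b1) * np.exp(-(lam + b1) * t_arr / 2.0)
            )
            out = amp * (1.0 - term)
    else:
        w1 = math.sqrt(-disc) / math.sqrt(8.0)  # omega1 = sqrt(w^2 - (g/m)^2/8)
        bracket = (
            -2.0 * np.sin(w1 * t_arr / math.sqrt(2.0)) ** 2
            + (g / (math.sqrt(8.0) * m * w1)) * np.sin(math.sqrt(2.0) * w1 * t_arr)
            + 1.0
        )
        out = amp * (1.0 - decay * bracket)
    return out if np.ndim(t) else float(out[0])


def msd_regime3(t, params: RegimeParams):
    """MSD between reflecting walls (Regime III): (r_in^2/6)(1 - e^{-t/tau0})."""
    if params.r_in <= 0 or params.tau0 is None or params.tau0 <= 0:
        raise ValueError("Regime III requires r_in > 0 and tau0 > 0")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    out = (params.r_in**2 / 6.0) * (1.0 - np.exp(-t_arr / params.tau0))
    return out if np.ndim(t) else float(out[0])


def compose_total_msd(t, t_w: float, short_time_msd, jump_msd: float | None = None):
    """Total MSD with hopping renewal: ``(t/t_w) <dz^2>`` for t >= t_w.

    ``short_time_msd`` is a callable giving the intra-cell MSD, used for
    ``t < t_w``.  For ``t >= t_w`` the mean number of jumps ``t/t_w``
    multiplies ``<dz^2>``: by default the intra-cell value at ``t_w``
    (which makes the two branches continuous), or ``jump_msd`` — the mean
    squared jump length, i.e. the landscape period squared — which is
    what hopping simulations actually follow at long times (the intra-cell
    plateau underestimates the per-jump displacement).
    """
    if t_w <= 0:
        raise ValueError("t_w must be positive")
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    short = np.asarray(short_time_msd(t_arr), dtype=float)
    if jump_msd is None:
        per_jump = np.asarray(short_time_msd(np.full_like(t_arr, t_w)))
    else:
        per_jump = float(jump_msd)
    out = np.where(t_arr >= t_w, (t_arr / t_w) * per_jump, short)
    return out if np.ndim(t) else float(out[0])


def oscillation_mode(regime: Regime, params: RegimeParams) -> str:
    """Transient oscillation mode of the MSD in each size regime."""
    if regime == Regime.I:
        return "underdamped"  # complex characteristic root s1 of the V potential
    if regime == Regime.II:
        return "underdamped" if params.gamma < math.sqrt(8.0) * params.m * params.omega else "overdamped"
    if regime == Regime.III:
        return "overdamped"
    raise ValueError("Regime IV has no confining landscape and no oscillation mode")
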