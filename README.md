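# nethop

Nanoparticle transport in topologically defined macromolecular network
cells: free-energy landscapes, Wang-Landau sampling, Langevin hopping
dynamics and regime-resolved MSD theory.

## The problem

Gels, mucus and the extracellular matrix are cross-linked polymer
networks, and how a nanoparticle of diameter `d` moves through them
controls drug delivery, infection and filtration. Classical treatments
reduce the network to a single elastic loop; this package instead models
a full **network cell** — a polyhedron whose edges are Gaussian-chain
strands of mesh size `a_x` and whose vertices are cross-links — so that
the *topology* of the cell (labelled by its face count `g`: 4
tetrahedron, 6 cube, 8 octahedron, 12 dodecahedron, 20 icosahedron, 32
truncated icosahedron) shapes the free-energy landscape `ΔF(r)` the
particle experiences.

Three radii classify a particle of radius `R = d/2` against a cell with
`n`-gon faces meeting at dihedral angle `θ`:

```
r_in  = (a_x/2) cot(π/n) tan(θ/2)         (insphere: touches faces)
r_mid = (a_x/2) cot(π/n) sec(θ/2)         (midsphere: touches edges)
r_out = (a_x/2) cot(π/n) √(sec²(θ/2)+tan²(π/n))   (circumsphere: vertices)
```

giving four size regimes — I: `R > r_out` (whole-cell dilation), II:
`r_mid < R < r_out` (strand deformation), III: `r_in < R < r_mid`
(obstruction at the faces), IV: `R < r_in` (free passage) — with
distinct scaling of `ΔF(z)` along the minimum-energy path (MEP) from a
cell center to a face center, and correspondingly Brownian, hopping or
trapped particle dynamics.

## What the package computes

* **cells** — exact polyhedral cells with unit-`a_x` edges, their radii
  by closed form and by direct geometry, MEP frames, and bead-spring
  realizations (N springs per strand, first image shell as boundary).
* **landscape** — `ΔF(r)` of a hard sphere from the partition function
  of the Gaussian network: the cross-link integral at its saddle point
  (constrained minimization with taut-string strand paths) plus optional
  strand-entropy corrections from Gaussian-bridge survival sampling.
* **wanglandau** — flat-histogram Monte Carlo of the bead-spring model
  along the MEP (`βF(z) = −f(z)`, penalty `f₀ = 0.5 k_BT` halving to
  `10⁻⁴`), with 50-run standard errors; the exact cross-check of the
  theory.
* **langevin** — underdamped Langevin dynamics
  `m z̈ = −ΔF′(z) − γż + ξ(t)` (Euler–Maruyama, `Δt = 0.01 τ`,
  `γ/m = 10 τ⁻¹`) on the periodized landscape: diffusion coefficients
  from the velocity autocorrelation, MSDs, van Hove functions,
  jump/waiting decomposition, Brownian/hopping/trapped classification.
* **msd** — closed-form MSD per regime: V-potential `ρ|z|`
  (`ρ = U_b/r_in`, numerically inverse-Laplace-transformed), Brownian
  harmonic oscillator (`ω = √(2U_b)/r_in`, overdamped for
  `γ > √8·mω`), and reflected random walk (`r_in²/6` plateau), composed
  with hopping renewal `⟨Δz²⟩ = (t/t_w)⟨δz²⟩`.
* **scaling** — exponent fits `ΔF ~ z^η`, barrier scans `U_b(d; g)`,
  regime diagrams and master-curve collapses `D/D(2r_in)` vs
  `d/(2r_in)`.

## Worked example

```python
import numpy as np
from nethop import (build_cell, radii_geometric, ParticleSpec,
                    LandscapeConfig, mep_profile, fit_exponent)

cube = build_cell(6)                      # g = 6 cell, a_x = 1
r = radii_geometric(cube)
print(r)            # RadiiTriple(r_in=0.5, r_mid=0.70710678..., r_out=0.86602540...)

prof = mep_profile(cube, ParticleSpec(d=1.4), n_z=16,
                   config=LandscapeConfig(fluctuations=False, N=4))
print(np.round(prof.dF, 2))
# [0.   0.   0.02 0.05 0.1  0.15 0.22 0.3  0.38 0.46 0.54 0.62 0.69 0.74 0.77 0.79]
print(round(prof.U_b, 2), prof.regime)
# 0.79 Regime.III
```

The profile is the free-energy change (in `k_BT`) as a `d/a_x = 1.4`
particle moves from the cube-cell center (`z = 0`, where `ΔF = 0` by
definition) to a face center (`z = r_in = 0.5`): flat near the center,
then rising to the hopping barrier `U_b ≈ 0.8 k_BT` at the face, where
the particle squeezes past the face strands. The same profile sampled by
Wang-Landau MC on the `N = 4` bead-spring cell agrees pointwise to
within `0.3 k_BT`.

The same objects drive the dynamics:

```python
from nethop import periodic_potential, NLEConfig, simulate_ensemble, diffusion_coefficient
pot = periodic_potential(prof)            # even + periodic extension, period 2 r_in
ens = simulate_ensemble(pot, NLEConfig(t_total=1e4, n_replicas=32, seed=1))
D, info = diffusion_coefficient(ens)      # Green-Kubo with MSD cross-check
```

A CLI mirrors the library: `nethop cell --g 6`, `nethop landscape --g 6
--d 1.4`, `nethop wlmc --g 4 --d 1.0 --runs 50`, `nethop nle ...`,
`nethop theory ...`, `nethop scan ...`.

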