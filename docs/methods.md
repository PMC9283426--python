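# Methods

## Model

A network cell is a convex polyhedron with unit-`a_x` edges: strands are
ideal (theta-solvent) Gaussian chains of `N` Kuhn segments with
`a_x = √N·b`, cross-links sit at the vertices, and a hard spherical
nanoparticle of radius `R = d/2` excludes all chain material. The
Helmholtz free energy is `F(r_np) = −k_BT ln Z(r_np)`, with `Z`
integrating over cross-link positions and strand conformations subject
to the exclusion. All energies are in `k_BT`, lengths in `a_x`, times in
`τ`; `m = k_BT = 1`.

The catalog is keyed by the face count `g ∈ {4, 6, 8, 12, 20, 32}`
(tetrahedron … truncated icosahedron). `g` is the label used for cell
topology throughout; note that the cycle rank of the edge graph is
`E − V + 1 = F − 1`, so the label tracks faces, not graph genus. The
vertex functionality `k` is stored but enters no formula.

### Boundary condition

A single cell with free cross-links has a zero mode (the cage would
translate with the particle), so every landscape evaluation appends the
first shell of mirror-image cells across each face and pins the
image-only cross-links. For the cube this reproduces the local cubic
lattice exactly (each vertex recovers its bulk coordination of 6). The
price is a finite environment: the particle becomes infeasible when it
reaches the pinned shell (for the cube at `d ≳ 2.45 a_x`), and barriers
saturate as `d` approaches that scale — see Limitations.

## Landscape estimator (theory route)

The cross-link integral is evaluated at its saddle point: the free
cross-links minimize the summed strand energies under the hard
constraint `|r_k − r_np| ≥ R`. Each strand contributes
`(3/2) L_taut² / (N b²)`, where `L_taut` is the planar
tangent-arc-tangent path around the particle — a smooth, differentiable
upper bound on the true 3-D geodesic (tight to a few percent; the true
geodesic may tilt out of the endpoint-center plane). Minimization is
SLSQP with analytic gradients, restarted until the energy is stationary;
profiles are swept forward and backward along the MEP with warm starts
and the pointwise minimum is kept, which resolves the symmetry-broken
states that appear for particles much larger than the cell.

Strand-level fluctuations can be added (`LandscapeConfig(fluctuations=True)`)
as `(3/2)|Δr|²/(Nb²) − ln P_survive` per strand, with `P_survive`
estimated by sequential Gaussian-bridge sampling with resampling
(resolves `P` far below one part in the walker count; per-strand streams
are derived from one seed so evaluations at different particle positions
share randomness). This term is quantitatively validated only where
stretching dominates; in entropy-dominated states (small cells, large
particles) the fixed-cross-link composition misses the entropy of
cross-link fluctuations, and the Wang-Landau route below is the
reference. The deterministic saddle (`fluctuations=False`) is therefore
the default for scaling analyses.

## Wang-Landau route (simulation reference)

The bead-spring realization discretizes each strand into `N` springs of
energy `(3/2)|Δr|²/b²`; beads and free cross-links move in 3-D, the
particle moves along the MEP axis only. A bias `f(z)` accumulated in
bins over `[0, z_face]` receives `f₀ = 0.5 k_BT` per visit; when every
bin count reaches 0.8 of the mean, the increment halves, terminating
below `10⁻⁴ k_BT`; then `βF(z) = −f(z)`, reported as `F(z) − F(0)`.
Moves are uniform displacements (beads 0.15 `a_x`, particle 0.08 `a_x`)
with Metropolis acceptance on spring energy + bias and hard-sphere
rejection. The printed configurational-integral prefactor `exp(−βz)` is
treated as bias bookkeeping, not a physical field. The engine is
validated against equipartition (3/2 `k_BT` per spring), Widom insertion
(absolute `F`), bidirectional thermodynamic perturbation, and bin-count
invariance.

The per-strand discretization `N` is a study condition: confinement
entropy grows with `N` (for the cube at `d = 1.9`, `U_b ≈ 3.4 / 9.2 / 14
k_BT` at `N = 4 / 16 / 32`), converging from below toward the continuum.
`N = 4` is used for the Monte-Carlo fidelity checks (small, fast,
matched between theory and MC); `N = 16` is the default for landscapes
that drive dynamics, as the largest discretization whose Wang-Landau
profiles converge in minutes on one CPU.

## Langevin dynamics

The half-path profile is extended by even reflection about `z = 0` and
`z = z_face` (period `2 z_face`, minima at cell centers, barrier `U_b`
at face centers) and interpolated with a periodic cubic spline; the
integrator reads the force from a 4096-point lookup table.
Euler–Maruyama with `Δt = 0.01 τ` and `γ/m = 10 τ⁻¹` at `d = a_x`; at
this step the discrete velocity process reproduces `D₀ = k_BT/γ` exactly
under trapezoidal Green–Kubo integration. The friction grows with
particle size as `γ ∝ d³/a_x²` (Rouse-coupling model: drag dominated by
local strand dynamics, giving `D₀ ∝ (d/a_x)⁻³`); a Stokes `γ ∝ d`
variant is provided. `D` comes from the replica-averaged velocity
autocorrelation integrated to an automatic cutoff (five consecutive lags
indistinguishable from zero), cross-checked against half the long-time
MSD slope.

Jump events: the committed cell index changes only when the trajectory
reaches the core of a new cell (`|z − center| < 0.25·period`), which
suppresses barrier-top recrossings. Motion classification partitions by
the Brownian band of local MSD log-slopes (computed after the ballistic
time `10 m/γ`, excluding the poorly averaged final 5% of lags, 3-point
smoothed): all slopes in `[0.8, 1.2]` → Brownian; a dip below the band
plus events → hopping; a plateau (slope < 0.1) with no events → trapped;
otherwise mixed.

## Analytic MSD theory

Mapping from a landscape: `ρ = U_b/r_in` (Regime I) and
`ω = √(2U_b)/r_in` (Regime II), in natural units. Regime I uses the
Laplace-domain MSD inverted by fixed-Talbot (Abate–Valkó, 32 nodes; the
engine self-tests against closed-form pairs to 10⁻⁶ before use); its
`t → ∞` value equals `2D₀t_w − ρ²t_w²(Δ₀−1)` with
`Δ₀ = √(1+4D₀/(ρ²t_w))` — algebraically identical to the `s → 0` limit,
both reducing to `(ρ²t_w²/2)(Δ₀−1)²`. Regime II is the Brownian
harmonic oscillator with branches at `γ = √8·mω` (the overdamped branch
is evaluated in an exponential form stable at large `t`); Regime III is
`(r_in²/6)(1 − e^{−t/τ₀})` with `τ₀ = r_in²/(12 D₀)` by default, chosen
so the short-time expansion matches free diffusion `2D₀t` (`τ₀` is
exposed as an override; note the plateau `r_in²/6` is half the textbook
value `r_in²/3` for a walker started at the center between reflecting
walls at `±r_in` — the printed form is reproduced as stated). `t_w` is
always measured from simulation, never predicted.

Hopping renewal: `⟨Δz²(t)⟩ = (t/t_w)·⟨δz²⟩` for `t ≥ t_w`. With `⟨δz²⟩`
the mean squared jump length (≈ period²) this reproduces simulated
hopping diffusion exactly (`2D = period²/t_w`); with the intra-cell
plateau it is continuous at `t_w` but underestimates the long-time
diffusivity by `period²/plateau`. `compose_total_msd` defaults to the
continuous form and accepts the jump variant explicitly.

## Design choices and numerical details

* Regime classification ties go to the larger-particle regime
  (deterministic).
* Fit windows: Regime-I exponent over `z ∈ [z_face/2, z_face]`;
  Regime-II small-z exponent over `z ∈ (0, z_face/4]`.
* For the truncated icosahedron the closed-form radii apply per face
  class; the geometric route (min face-plane / min edge / max vertex
  distance) is authoritative.
* Neighbor cells are mirror images even for non-tiling polyhedra (a
  local environment, not a global tessellation); only the first shell is
  used.
* All randomness flows from explicit seeds through `SeedSequence`
  spawning; every stochastic routine is bit-reproducible given its seed.
* Exports: OFF / legacy-ASCII VTK for meshes, XYZ + JSON adjacency for
  bead networks, CSV with unit-bearing headers for curves.

## What the tests do and do not show

The synthetic study conditions are the catalog cells themselves — there
is no external data. Problem sizes in the tests and the acceptance
script are desk-scale: Langevin ensembles of 16–32 replicas at
`t_total = 10⁴–10⁵ τ` (production-scale would be `10⁷ τ`), Wang-Landau
at 16–32 bins with 6–50 runs, landscapes at 10–32 path points. Passing
tests demonstrate internal consistency of theory, sampler and dynamics
on regular, unentangled, quenched networks with a hard spherical probe;
they say nothing about irregular or entangled networks, soft or
anisotropic particles, hydrodynamic memory, or network motion coupled to
the particle during transport.

## Known limitations

* The pinned first image shell caps the accessible particle size
  (`d ≲ 2.45 a_x` for the cube) and saturates `U_b(d)` as that scale is
  approached, so the quadratic barrier growth expected from bulk loop
  elasticity at `d > 2 r_out` is not recovered in this environment.
* The saddle estimator yields smooth profiles with a quadratic core at
  the cell center (any symmetric equilibrium model has `dF′(0) = 0`);
  the outer-half Regime-I exponent measures ≈ 1.4–1.5 rather than the
  V-potential value 1, and the exact Wang-Landau free energy of the same
  model confirms ≈ 1.5 — the V-shape is an idealization adopted only in
  the analytic MSD theory.
* Entropy-dominated barriers grow with the strand discretization `N`
  and have not converged at `N = 16`; at `d = 1.90` in the cube this
  leaves the particle in the rare-hopping rather than fully trapped
  regime over desk-scale windows.
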