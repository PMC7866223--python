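# Methods

## Physical model

The solver treats the 2D transverse-magnetic (TM) problem: the electric
field has a single out-of-plane component E(x, y) obeying the Helmholtz
equation (∇² + k²(r)) E = −source, with the complex squared wavenumber

    k² = ω² μ₀ (ε₀ ε_r − j σ/ω)    [m⁻²]

under the engineering time convention e^{+jωt}. Passive media therefore
have Im(k²) ≤ 0, outgoing waves carry Hankel functions of the second kind,
and the free-space Green's function is G(d) = H₀⁽²⁾(k_b d)/4j, which
satisfies (∇² + k_b²) G = −δ. k² is the reconstruction variable: it folds
permittivity and conductivity into one complex unknown per node, and the
Jacobian's m² units follow from differentiating with respect to it.
Conversion to (ε_r, σ) images is the fixed scaling
ε_r = Re k²/(ω²μ₀ε₀), σ = −Im k²/(ωμ₀), applied at reporting time.

Antennas are ideal 2D line currents of amplitude |J| (default 1): the
incident field is E_inc(r) = −(ωμ₀|J|/4) H₀⁽²⁾(k_b|r − r_s|) = −jωμ₀|J| G.
No antenna hardware is modeled; receivers are point samples of the total
field.

## Geometry

The domain is a side × side square grid of n × n cells centered on the
origin (default 25 cm / 64 cells, h = 3.90625 mm). The imaging zone is the
step-wise circle of cells whose **centers** lie within the zone radius of
the grid center; the unknowns sit on the distinct corner nodes of those
cells, ordered row-major. The shipped default radius is 69.8 mm: the
cell-count of this selection rule is piecewise constant in the radius, and
the plateau [69.72, 69.93) mm reproduces the reference configuration of
1012 cells and 1085 nodes (effective equal-area diameter 14.0 cm) exactly;
69.8 mm sits in the middle of that plateau. Each node τ carries the area
A_τ = h² × (number of incident in-zone cells); interior nodes have
A_τ = 4h², so A_τ/M = h² with M = 4 vertices per cell. The zone satisfies
the Euler relation |nodes| = |cells| + B/2 + 1 (B = boundary edge count),
asserted in tests for every generated zone.

Antennas are equally spaced on a circle (default 16 on 15.2 cm) with
antenna #1 at the bottom (angle −90°) and subsequent antennas clockwise.
One sweep measures every ordered (s, r) pair with r ≠ s — 240 complex
transmission values for 16 antennas — ordered s-major.

## Forward solver

Writing k² = k_b² + χ with the contrast χ supported on the zone turns the
scattering problem into the Lippmann–Schwinger volume integral equation,
collocated at the in-zone nodes with each node owning an h × h square:

    E_n = E_inc,n + Σ_m C_nm χ_m E_m,
    C_nm = h² G(p_n, p_m)   (n ≠ m),
    C_nn = −(jπa/(2k_b)) H₁⁽²⁾(k_b a) − 1/k_b²,  a = h/√π,

the self term being the closed-form integral of G over the equal-area
circle (it agrees with adaptive quadrature over the actual square cell to
well under 1% for sub-wavelength cells; the code warns when |k_b|h > 0.6).
Antenna fields are filled by the same midpoint rule,
E(r) = E_inc(r) + Σ_m h² G(r, p_m) χ_m E_m.

The dense system (I − C diag χ) E = E_inc is solved by LU; the matrix is
independent of the transmitter, so one factorization serves all n_s
right-hand sides per iteration. A matrix-free GMRES path using the same
coefficients is provided and agrees with the LU path to ≤ 1e−8 relative.
With zero contrast the identity E = E_inc holds exactly; the full
measurement matrix is reciprocal (m(s,r) = m(r,s)) to ≤ 1e−10 relative.

### Accuracy

Against the analytic cylindrical-harmonic series for a line source and a
homogeneous dielectric cylinder (4 cm diameter, ε_r 16.9/σ 1.15 in the
20.9/1.35 bath at 1500 MHz, contrast discretized as the exact cell average
of the disk indicator), the scattered field at the antennas converges at
second order: ≈ 3.5% relative L2 at h ≈ λ_b/10 (the 64-cell reference grid,
λ_b = 2π/Re k_b = 41 mm) and ≈ 0.9% at h ≈ λ_b/20. The dominant term is the
midpoint quadrature of the radiation integral, whose integrand oscillates at
spatial rates up to 2k_b (transmit plus observation phase), i.e. about 5
samples per period at h = λ_b/10 — a ((2k_b h)²/24 ≈ 5%) second-order error.
This is an inherent property of the nodal midpoint discretization, which is
exactly the discretization that makes the collapsed Jacobian identity exact;
a higher-order radiation quadrature would decouple the discrete model from
the adjoint formula. Users needing < 2% scattered-field accuracy should
refine the grid (the inversion itself is far less sensitive: it compares
model to model through the calibration).

## Jacobian

The nodal-adjoint identity expresses the derivative of measurement (s, r)
with respect to k²_τ as a weighted product of the two forward fields; on
the shared grid with interpolatory nodal basis functions the dual-mesh
quadrature collapses to

    J[(s,r), τ] = −(1/(jωμ₀|J_r|)) (A_τ/M) E_s(p_τ) E_r(p_τ).

This is the *exact* derivative of the discrete forward model at interior
nodes (A_τ/M = h²): verified against central finite differences of the
received field (relative error ≤ 1e−3 on sampled interior nodes, typically
≈ 1e−10, with second-order convergence in the step). At zone-boundary nodes
the implementation uses the true per-node area A_τ (1–3 cells) rather than
the uniform constant, which keeps the general quadrature identity exact
there; the discrete-model derivative at those few rim nodes is h², so the
adjoint value differs from the finite difference by the area ratio — the
finite-difference oracle is therefore checked at interior nodes. The
general double-summation form (explicit sum over elements and vertices) is
implemented as a verification path and equals the collapsed rows to machine
precision, and rows are bitwise invariant under transmit/receive exchange
(field products are formed in a canonical operand order because complex
multiplication is not bitwise commutative under FMA).

Building the full matrix from a sweep's field solutions performs zero
additional forward solves and exactly n_s·n_r row products; both counters
are instrumented and asserted in tests.

The log transform divides row (s, r) by the received field E(s, r) (chain
rule of the complex logarithm): real parts become ∂ln|E|/∂k², imaginary
parts phase sensitivities. No unwrapping enters the Jacobian; unwrapping is
a measurement-side operation. Source amplitude cancels between the Jacobian
and the received field, so log-domain rows are amplitude-invariant.

## Reconstruction

Measurements enter as γ = ln|E| + jφ with φ unwrapped along each
transmitter's receiver sequence (ascending receiver index, 2π-jump
correction). Measured phantom data are calibrated as

    γ_cal = [γ_meas,inhomog − γ_meas,homog] + γ_model,homog,

re-basing the measured log-domain perturbation onto the model's own
homogeneous-tank prediction so that antenna/system factors common to both
measured conditions cancel.

Gauss–Newton iteration from the homogeneous bath starting map: per
iteration one forward sweep (n_s solves, one LU), residual
r = γ_cal − γ_model, the collapsed Jacobian from the sweep's fields,
log transform, and the Levenberg–Marquardt step

    (JᴴJ + λ s I) Δk² = Jᴴ r,  s = mean diag(JᴴJ),

with λ relative (default λ₀ = 0.1) decaying geometrically (default 0.9 per
iteration) — mild damping early, nearly pure Gauss–Newton later. Updated
maps are projected onto the physical set ε_r ≥ 1, σ ≥ 0. Only zone nodes
are ever modified. The error trace e_i = ‖r_i‖₂/‖r_1‖₂ is normalized to the
first iteration; iteration stops when |e_i − e_{i−1}| < 10⁻³ (configurable),
on max_iterations, or aborts with a diagnostic if e_i grows three
consecutive iterations. Arithmetic is fully complex (Hermitian normal
equations).

## Synthetic data generator

The generator emulates a circular-array phantom experiment: a lossy
glycerin–water bath, one or more homogeneous circular inclusions, each
antenna transmitting in turn. Defaults are the reference experiment's
conditions: 1500 MHz; bath ε_r = 20.9, σ = 1.35 S/m; a single 4 cm diameter
inclusion with ε_r = 16.9, σ = 1.15 S/m placed at 2/3 of the zone radius
along the bisector of antennas #6 and #7 (the reference setup states only
"in front of antennas #6 and #7"; 2/3 radius puts the inclusion fully
inside the zone with a one-wavelength clearance from the antennas);
measurement noise 1% i.i.d. complex Gaussian, relative to each
measurement's magnitude.

Both the phantom and bare-tank conditions are simulated on a grid refined
by fine_factor (default 2, i.e. 128 cells) with the same zone radius and
antennas, then noised with a fixed seed (byte-identical output per seed).
Refinement rather than a different solver family avoids the inverse crime
while keeping the package self-contained. Node membership in an inclusion
is decided by the node coordinate, so property transitions are staircase
like the zone itself.

What the generator does **not** emulate: antenna mutual coupling and
near-field behavior, cable/switch drift and other systematic errors that
real calibration removes, dispersion across frequency, and anthropomorphic
tissue heterogeneity. Passing recovery tests on this generator therefore
demonstrates correctness of the solver/Jacobian/inversion chain under the
stated noise model, not clinical image quality.

Recovery is scored by `recovery_metrics`: mean ε_r/σ over the true
inclusion footprint, and the centroid of the half-maximum anomaly region
(the top half of the permittivity-anomaly mass — the standard blob
localization choice, insensitive to remote low-level artifacts). Under the
default scenario (seed 1) the reconstruction stops by the 10⁻³ rule at
iteration 6 with a monotone error trace, mean footprint ε_r ≈ 17.4 against
a truth of 16.9, and centroid error ≈ 0.1 cells.

## Numerical choices and degenerate inputs

- Wavenumber branch: Re k ≥ 0, Im k ≤ 0 (decaying outgoing waves).
- Problem sizes: the reference zone (1085 unknowns) takes a dense 1085²
  complex LU per iteration — fractions of a second; data synthesis on the
  refined 128-cell grid (~4200 unknowns) is the most expensive step at
  under a minute.
- Zero received field in a measurement row is rejected (degenerate null of
  the log transform), as are zero-magnitude measurements, zones touching
  the domain boundary, inclusions escaping the zone, antennas inside the
  zone, evaluation points on a source, and λ = 0 normal equations that turn
  out singular.
- A zero initial residual (data generated by the starting map itself) stops
  the iteration immediately with the background image.
- Tie-breaks: zone membership uses ≤ on the center distance; plateau-valued
  radii make the set robust to roundoff at the shipped default.

## Limitations

- 2D TM scalar physics only; no 3D vector extension.
- The open-domain integral formulation has no exterior boundary model —
  appropriate for a large lossy tank, not for resonant enclosures.
- Scattered-field accuracy at h = λ_b/10 is ~3.5% (see above); refine for
  quantitative scattering studies.
- Phase unwrapping is 1D per transmitter and can mis-branch for very high
  contrast objects whose inter-receiver phase steps exceed π.
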