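# Methods

## Model and assumptions

The package treats epi-off CXL as a one-dimensional photobleaching problem:
a uniform UVA beam enters the stromal surface (z = 0) and is attenuated by
three components — unreacted riboflavin (extinction ε₁ per % per cm), its
photolysis product (ε₂), and the riboflavin-independent stromal background
(Q per cm). The local photolysis rate is proportional to the local
intensity, so concentration obeys the exact depletion law
C = C₀F(z)·exp(−aE) with the accumulated dose E(z,t) and the rate constant
a = 83.6·λ·φ·ε₁. The pre-soak profile is the linear ramp
F(z) = 1 − 0.5·z/D with half-maximum at the diffusion depth D, clamped at
zero beyond 2D; its running mean G(z) = (1/z)∫₀ᶻF (equal to 1 − 0.25·z/D on
the ramp, D/z beyond it) appears in the two Beer–Lambert limit coefficients
Aⱼ = 2.3[Q + εⱼC₀G(z)].

Assumptions inherited from the model: no riboflavin re-diffusion or
replenishment during the exposure, no oxygen or temperature dependence,
continuous-wave illumination, laterally uniform beam (no 2-D effects). The
epithelium-intact (epi-on) case is the same model with the surface intensity
reduced by exp(−A_epi·d_epi).

Crosslinking efficacy is the monomer-to-polymer conversion
Ceff = 1 − exp(−S) with S = ∫₀ᵗ R dt′. The photoinitiation rate is
implemented in its bimolecular-termination form **R = √(K·a·C·I)**. The
linear form R = a·K·C·I appears in parts of the source literature, but it
makes steady-state efficacy independent of intensity, contradicting the
model's own consequences (steady efficacy ∝ √(C₀/I₀), the I₀^(−1/2)
exposure-time law, and the exact solution below); the square-root form
reproduces all three and is the package's single reconstruction of
substance. With it, the surface steady state has the closed value
S(0,∞) = √(4KC₀/(aI₀)).

## Parameters, units, defaults

| symbol | meaning | unit | default | note |
|---|---|---|---|---|
| ε₁ | riboflavin extinction | (%·cm)⁻¹ | 204 | measured value from the RF literature |
| ε₂ | photoproduct extinction | (%·cm)⁻¹ | 50 | measured range is 80–120; 50 is the scenario value used throughout, both exposed as config |
| Q | stromal background absorption | cm⁻¹ | 13.9 | |
| φ | quantum yield | — | 0.5 | treated as free in 0.3–0.5 |
| λ | UV wavelength | cm | 3.65e−5 | 365 nm UVA |
| K | chain growth/termination ratio | (%·s)⁻¹ | 1 | not measured; scales S uniformly, all orderings/ratios are K-invariant |
| C₀ | surface RF concentration | weight % | 0.1 | |
| D | diffusion depth (HWHM) | cm | 0.05 | 500 µm |
| I₀ | surface intensity | mW/cm² | 10 | clinical range 3–45 |
| M (N) | depletion level defining T* | — | 4 | T* when C reaches e⁻⁴ |

Internally depth is cm, concentration weight-%, intensity mW/cm², time s,
dose mJ/cm²; then a·I is s⁻¹ and a·E dimensionless, as the depletion law
requires. At the defaults a = 0.6225·φ cm²/mJ; this normalisation is fixed
by the worked surface example (T₀ = 4/(a·I₀) ≈ 1.3 s at 10 mW/cm², a
13 mJ/cm² surface dose, coefficient 6.43 s·mW/cm² in T₀ = k/(I₀φ)).

## Numerical scheme

Per time step: (1) predictor — Euler advance of E with the current I;
(2) C from E by the exact exponential (the stiffness of dC/dt never enters);
(3) I from C by cumulative trapezoidal quadrature of the attenuation
integrand in z; (4) corrector — trapezoid-in-time E using the predicted I;
(5) S advanced by trapezoid on R. The trapezoid in z is exact at t = 0
(piecewise-linear integrand), so the initial column matches I₀e^(−A₁z) to
machine precision; the fully-depleted column converges to I₀e^(−A₂z)
limited only by the residual-depletion tolerance.

Grid defaults: dz = 1 µm, z_max = 500 µm, and dt from the per-step
depletion contract a·I₀·dt = 0.05 (an accuracy contract — the exponential
update is unconditionally stable; violating grids are refused with the
required dt). Steady-state ("t = ∞") requests run until
max_z exp(−aE) < 10⁻³, doubling the exposure as needed, with an explicit
not-converged flag at a configurable cap. A convergence checker re-solves
at (dz/2, dt/2) and reports the max Ceff change normalised by the profile
maximum; all built-in presets pass at < 0.5 % (typically ~2×10⁻⁵).

Validation is two-sided. For Q = 0, ε₂ = 0 and a uniform riboflavin column
(F ≡ 1) the coupled system has the exact (Wegscheider) solution

    S(z,t) = √(4KC₀/(aI₀)) · √(E2/(E2−1)) · arctan(G1),
    G1 = √(E2−1)·(1−Ē) / (1 + (E2−1)·Ē),

with E2 = exp(2.3ε₁C₀·z), Ē = exp(−½aI₀t); the z → 0 limit
√(4KC₀/(aI₀))·(1−Ē) coincides with the mean-intensity approximation at the
surface, tying the exact and approximate layers together. The arctangent
argument was re-derived from scratch for this package (substituting
x = e^(βt/2) reduces the time integral of R to ∫dx/(x² + E2 − 1)); note the
radical applies to the numerator factor only — a variant with √(E2−1) in
the denominator is off by ~50 % against the solver at moderate depth. The
default grid agrees with the exact solution to ≤ 6×10⁻⁵ relative over
z ≤ 500 µm, t ≤ 30 s.

## Analytic layer and its validity domains

The closed forms replace the dynamic intensity by the mean of its initial
and steady Beer–Lambert limits, H(z) = ½[e^(−A₁z) + e^(−A₂z)]:

- **Dose**: E(z) ≈ E₀e^(−A₂z) − g with g = ½(I₂−I₁)·T, T = 12/(a·I₀).
  The correction g carries dose units (a normalisation of the source form,
  which divided by E₀ and would leave g dimensionless); with it the
  approximation tracks the solver to ~6 % at 400 µm on the standard
  transient scenario, comfortably inside the expected 10–25 % correction
  band. Not valid for t below the crossover T.
- **Concentration**: C ≈ C₀F·exp(−a·E_approx), i.e. the exact depletion law
  applied to the approximate dose (the exponent is −aE₀e^(−A₂z) + a·g;
  a stray factor of z on the correction term in the source's printed form
  would shrink it ~25-fold and is not used). Because a·E ≈ 5 in the
  depleted regime, the ~6 % dose error is exponentially amplified:
  pointwise relative error in C can exceed 100 % where C is nearly
  exhausted, while the error *on the concentration scale* C₀F stays ~1 %.
  Tests assert the latter; users needing depleted-regime concentrations
  should use the solver.
- **Crosslink time**: T*(z) ≈ T₀[e^(A₂z) + 1.5(1 − e^(−(A₁−A₂)z))], exact
  at the surface; the fitted transient term leaves up to ~20 % mismatch in
  the 100–300 µm band (tests bound it at 25 %), converging again at depth.
- **Efficacy**: S ≈ P·W with W = √(4KC₀F/(aHI₀)) and
  P = 1 − exp(−½·a·t·H·I₀). Its exact inverse
  t = −(2/X)·ln(1 − s/W), X = a·I₀·H, s = −ln(1−Ceff) is the exposure-time
  planner; targets above the ceiling 1 − e^(−W) raise a dedicated error
  carrying the ceiling. The small-demand expansion gives the I₀^(−1/2) law.
- **Steady-state criterion**: an exposure counts as steady at depth z once
  the residual exponential e^(−½atH I₀) < 0.133 (at 10 mW/cm², φ = 0.5
  that is t > 1.30 s at the surface). Scenario outputs label each condition
  steady/transient by this criterion at the deepest analysed z.

## Scenario presets and design choices

Eight presets cover the canonical conditions: transient profiles at 10 and
30 mW/cm² (matched doses 0.03–0.1 J/cm²), the high-concentration variant
(0.2 %), matched-dose 0.1 J/cm² intensity ladders (5/10/20/30 mW/cm²), and
efficacy-vs-intensity sweeps at 250 and 400 µm. Intensity sweeps are
log-spaced over 3–45 mW/cm² (25 points) to span slow and accelerated
protocols. Ties in argmax depth break to the smallest depth. The
matched-dose ladder runs are transient at the deepest depths by the
criterion above (their label says so); the strict intensity ordering of
their profiles holds regardless, as the approximation predicts (at fixed
dose, P is intensity-independent and W ∝ I₀^(−1/2)).

Problem sizes used in tests and the acceptance script: the default
501-point depth grid, exposures ≤ 60 s, and one grid-halving per preset —
a full suite run is well under a minute of compute plus the sweep tests.

## Known limitations

- No oxygen kinetics: the model cannot distinguish type-I/type-II
  photochemistry or pulsed-light oxygen replenishment effects.
- K is unmeasured, so absolute Ceff values are conditional on K = 1; only
  orderings, depths, times and ratios should be compared to observations.
- The linear-ramp soak profile is an analytic convenience; measured
  profiles would require the solver path only (all closed forms assume F).
- Corneal thinning is represented only as a D-shift between two static
  runs, not as a moving boundary during the exposure.
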