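# Methods

This note documents the models, numerical choices and limitations behind
`braincal`: what each stage computes, which constants matter, what the
synthetic data generator does and does not emulate, and where the design
was genuinely open.

## Constitutive model

The brain parenchyma is an incompressible one-term Ogden solid embedded in
Fung's quasi-linear viscoelasticity (QLV): the stress response separates
into a normalized relaxation function and an instantaneous elastic stress,
R(ε,t) = g(t)·Tᵉ(ε). The closed forms used:

- uniaxial nominal stress T(λ) = μ(λ^(α−1) − λ^(−α/2−1)) with
  λ₂ = λ₃ = λ^(−1/2);
- simple shear τ(γ) = μ(λ₁^α − λ₁^(−α))/√(γ²+4) with
  λ₁ = (γ + √(γ²+4))/2;
- infinitesimal shear modulus μ₀ = ½μα (the α-independent initial slope);
- reduced relaxation g(t) = g_∞ + Σᵢ gᵢ e^(−t/τᵢ), g_∞ + Σgᵢ = 1.

Compression is represented as λ = 1 − |engineering strain| on the same
uniaxial formula, so tension and compression share one code path and
compressive stresses are negative.

**Units.** Moduli in kPa, times in ms, densities in kg/mm³ (solver
convention kg-mm-ms, in which stress is GPa; the phantom converts with
1 kPa = 10⁻⁶ GPa). Defaults: ρ = 1.123×10⁻⁶ kg/mm³, ν = 0.499999.

**Modulus reference convention.** Textbook QLV treats Tᵉ as the
instantaneous response, so the long-term modulus is g_∞μ₀. Reported brain
stiffnesses here are quasi-static, so material cards carry a `reference`
flag (default `quasi_static`) under which the relaxation function is
rescaled by 1/g_∞: the long-term shear modulus then equals μ₀ exactly and
the instantaneous modulus is μ₀/g_∞. `instantaneous` preserves the literal
textbook equation. Which convention the original solver cards used is not
decidable from the published account; both are exposed and the calibration
pipeline is internally consistent under either, since reference data and
model are generated with the same flag.

**Prony fitting.** tan δ(f) = ĝ''/ĝ' of the normalized spectrum is
independent of μ, which is what makes it suitable for fitting damping
alone. Time constants are fixed to the decade grid (10, 1, 0.1, 0.01) ms —
the printed spectrum strongly suggests fixed decades, and freezing τ
removes the non-convex part of the search — and only the coefficients gᵢ
are optimized, subject to gᵢ ≥ 0 and g_∞ + Σgᵢ = 1. The residual
loss − tanδ·storage is linear in g, so a bounded linear least-squares
solve provides the starting point (exact when the data come from the model
class) and SLSQP polishes the true squared-tan δ objective. The table's
time-constant column is printed with units of ms although the symbol
defined in the text is an inverse time; the values are interpreted as τᵢ
in ms, the only reading under which the units make sense.

**Hereditary integral.** QLV stress histories use the standard recursive
exponential (internal-variable) update per Prony term with piecewise-linear
elastic stress within each step. The update is exact for piecewise-linear
Tᵉ(t), unconditionally stable and O(n); step-halving changes smooth-ramp
outputs by < 0.5 %. Single-element virtual experiments (tension,
compression, simple shear at 0.5 / 5 / 30 s⁻¹ to 50 % engineering strain)
integrate a constant-rate ramp on an internal grid of ≥ 4000 steps and
sample ≥ 100 points.

## Heterogeneity

The MRE stiffness distribution is truncated to the half-open percentile
band (15, 98] — the lower tail is CSF-contaminated, the upper tail carries
inversion edge artifacts — and every brain voxel is divided by the median
of the retained values. Percentiles use linear interpolation between order
statistics (the most common convention; the source does not specify).
Binning is equal-width over the retained normalized range with midpoint
centres: this reproduces the ≈ 0.111 spacing of the published 10-group
ladder (0.53 … 1.53), which equal-count binning would not. Values exactly
on a bin edge go to the upper bin; the retained maximum goes to bin n;
excluded-low/-high voxels are assigned to bins 1 and n. Centres are kept at
full precision internally and rounded only for display — the published
table's γ = 1.20/1.53 rows are only consistent with unrounded internal
centres.

Per-group cards use μᵢ = 2γᵢμ₀,med/α, which keeps every group's
infinitesimal modulus at γᵢμ₀,med for any α; at α = 2 this reduces to the
linear stage-1 relation μᵢ = γᵢμ_med.

## Objective rating

The per-axis score is
score = w_corr(w_shape·R_shape + w_size·R_size + w_phase·R_phase) +
w_corridor·R_corridor with constants w_corr = w_corridor = 0.5,
w_shape = 0.5, w_size = w_phase = 0.25, maximum cross-correlation shift
δ_max = 0.12 of the evaluation window, corridor half-widths a₀ = 0.05 and
b₀ = 0.5 of the peak absolute reference, and an evaluation window spanning
the samples where |ref| ≥ 0.03 of its peak. These are package constants in
the spirit of the CORA defaults; score parity with any particular release
of the original tool is not claimed, and all constants are configurable.

R_shape is the (clipped) maximum normalized cross-correlation over shifts,
R_phase = 1 − |δ*|/(δ_max·T), R_size the min/max ratio of signal energies
∫y²dt, and R_corridor the per-sample corridor score (1 inside the inner
corridor, 0 outside the outer, quadratic in between) averaged over the
window. The integer-shift correlation maximum is refined by parabolic
interpolation through its neighbours: without the sub-sample refinement the
phase and shape ratings are quantized at the sampling resolution, which
puts ~10⁻³-size steps into the calibration objective and lets the
golden-section search terminate on quantization plateaus rather than on
the physics.

cCORA weights axis scores by peak absolute reference magnitude per axis
(an RMS alternative is behind a flag); a zero-energy axis gets weight 0
and is skipped. wcCORA weights receiver cCORA scores by the recomputed
maximum resultant reference displacement; the joint objective is the plain
mean across subjects.

## Calibration

Stage 1 calibrates μ₀,med with α = 2 on the axial 20 rad/s, 60 ms case
(grid 0.25…2.6 kPa, termination width 0.1 kPa); stage 2 calibrates α on
the coronal 40 rad/s, 30 ms case (grid 2, 6, 10, termination 0.2),
rebuilding cards through the μ₀-preserving relation at every evaluation.
Simulations run 200 ms. The bracket is the pair of grid points adjacent to
the grid argmax; a boundary argmax raises an explicit bracket error rather
than silently extending. Golden-section iterations shrink the interval by
φ per step with exactly one new forward evaluation after the first
(interior-point reuse is implemented by caching objective values keyed on
the parameter rounded to 10⁻⁹). Termination is checked after each interval
update, and the returned value is the best *evaluated* parameter — every
candidate already has a known objective, so no extra simulation is spent
on a midpoint. Ties f(x₁) = f(x₂) deterministically take the first branch.
On the stage-2 interval [2, 10] with tolerance 0.2 this yields 8 interval
reductions and 12 total evaluations including the three bracketing runs.

## The phantom (what the synthetic data are, and are not)

The phantom is *not* a continuum FE head model. It is a deliberately small
lumped-parameter surrogate whose role is to provide a forward model with
the same interfaces, parameter dependencies and statistical structure the
calibration assumes, fast enough that staged recovery runs in minutes:

- ~150 interior point masses on a jittered lattice inside a rigid
  spherical shell of radius 70 mm, Delaunay connectivity (sliver edges
  pruned), mass from tributary volume;
- spring force law = the package's own Ogden-QLV simple-shear response on
  relative spring elongation, with per-spring μ scaled by the node-pair
  mean relative stiffness γ taken from a (synthetic) MRE label volume;
- spring cross-sections set by the affine lattice-continuum estimate for
  central-force networks, μ_eff = (1/15V)Σk_eL_e², matched exactly to the
  card modulus (no empirical stiffness factor);
- each boundary node is anchored to its radial shell projection *and* to
  the two nearest neighbouring anchor points. The oblique anchors matter:
  with radial anchors only, rigid rotation of the interior relative to the
  shell is a near-zero-stiffness pendulum mode (its restoring force is
  second-order in the angle) which dominates the response at every
  stiffness and breaks the rigid-limit invariant. With them, scaling μ₀ by
  10³ reduces peak relative displacement by ~10³;
- rotational pulses are half-sine angular-velocity waveforms
  ω(t) = peak·sin(πt/duration) about an anatomical axis (axes × {20, 40}
  rad/s × {30, 60} ms gives the 12-case matrix); the equations of motion
  are integrated in the shell-fixed rotating frame with Euler, centrifugal
  and Coriolis accelerations, so receiver outputs are skull-frame relative
  displacements as in sonomicrometry;
- semi-implicit (symplectic) Euler at dt = 0.05 ms, far below the computed
  stability bound for the stiffest card; a small fixed mass damping
  (0.005 ms⁻¹) removes numerical drift while all material damping flows
  through the Prony terms, keeping the calibration sensitive to the
  intended parameters. The integrator has a numba-compiled kernel and a
  numpy reference implementation; a test pins their agreement.

At the calibrated parameters the default phantom produces peak relative
displacements of roughly 10 mm (coronal 40 rad/s, 30 ms) and 3 mm (axial
20 rad/s, 60 ms) — the scale and severity contrast of the cadaveric
dataset. Receiver counts and
placements per specimen are not published; 12 receivers at random interior
nodes are used per subject, and subjects differ by lattice seed and by
their own synthetic MRE volume.

The synthetic MRE generator draws a Gaussian random field, smooths it
(σ = 2 voxels), exponentiates with the log-variance solving the lognormal
moment relation sd/median = e^(σ²/2)√(e^(σ²)−1), and rescales so the
sample median inside a spherical brain mask matches 2.53 kPa exactly; the
target sd is 0.99 kPa. It emulates the template's marginal statistics and
smoothness, not its anatomy: there is no tissue structure, no CSF rim, no
left-right symmetry.

Experiment bundles record per-subject, per-case receiver signals at 0.5 ms
sampling (~2 kHz, the order of sonomicrometry acquisition), with optional
white Gaussian noise whose standard deviation is a stated fraction of the
case's peak resultant displacement, and full provenance (true parameters,
seeds) from which the bundle regenerates bit-identically.

**What recovery on the phantom shows — and what it cannot.** Zero-noise
staged recovery returns the generating parameters within the stage
termination tolerances (μ₀,med to 10⁻⁴ kPa, α to 1.3×10⁻³), which
validates the rating, bracketing, reuse accounting and the staged design
itself, including the near-decoupling that motivates it: the low-severity
case operates springs at small strain where α is nearly invisible, the
higher-severity case at strains where it is not. Under 5 %-of-peak noise,
μ₀,med recovers with a systematic −3 % bias (noise inflates reference
signal energy and the size rating then prefers a slightly softer model) —
well within twice the stage tolerance. α is the weakly identified
direction: its total signature in the severe-case waveforms is ~0.5 % of
peak displacement per α-unit, an order of magnitude below that noise, so
the noisy objective is a shallow plateau roughly ±1 wide in α and the
recovered value wanders accordingly (errors up to ~1.3 across seeds). This
is an information limit of the surrogate at these conditions, not of the
search: the original FE calibration operated at 30–50 % tissue strain,
where the objective's α-range is two orders of magnitude larger. Passing
zero-noise recovery therefore demonstrates correctness of the machinery;
it does not certify α identifiability under heavy measurement noise at
desk scale, and none of the phantom results say anything about absolute
biofidelity against real brains.

## Strain metrics

Displacement volumes are differentiated by central differences inside the
brain mask, one-sided at mask edges; voxels lacking a usable neighbour
along any axis are excluded from all metrics. F = I + ∇u, and the maximum
principal strain (MPS) is the largest eigenvalue of the Green–Lagrange
tensor E = ½(FᵀF − I) — the standard choice in the tagged-MRI brain-strain
literature, under which rigid rotations are exactly strain-free; the
alternative definition (largest principal stretch − 1) is behind a flag,
and the two differ only at large strain. MPS-95 is the 95th percentile
with linear interpolation (same convention as the binning percentiles);
the exceedance metric is the voxel fraction strictly above 2 % strain.
Regional summaries take an integer label volume; the phantom's synthetic
three-region parcellation (peripheral / core / inferior, standing in for
gray matter, white matter and cerebellum) partitions the mask exactly and
exists purely to exercise the regional code path.

## Known limitations

- The phantom is a central-force spring network: no volumetric response,
  no CSF layer, no membranes, no contact, no anatomy; its α-sensitivity
  at the published loading conditions is far below the real FE model's.
- The tan δ source compilation behind the published spectrum is not
  tabulated; the fitted spectrum is taken as given and the fitter is
  validated by round-trip recovery instead.
- Rating constants are self-consistent package defaults, not a certified
  reproduction of any specific CORA release.
- Single-axis rotational pulses only; the machinery accepts one axis per
  case, not general 6-DOF kinematics.
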