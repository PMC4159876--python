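# Methods

## Model and procedure

The package analyses steady-state donor-quenching FRET data in five
chained stages.

**Overlap integral.** The donor emission spectrum `F_D(λ)` (arbitrary
units) and acceptor extinction spectrum `ε_A(λ)` (M⁻¹·cm⁻¹) are linearly
interpolated onto a common grid spanning the union of their sampled
supports, with zero outside each spectrum's support, and

    J = ∫ F_D ε_A λ⁴ dλ / ∫ F_D dλ

is evaluated by trapezoidal quadrature. The normalizing denominator makes
J independent of any positive rescaling of `F_D` (tested as a property),
so whether the emission spectrum is peak- or area-normalized is
mathematically irrelevant; both normalizations are available for display.
J is carried in M⁻¹·cm⁻¹·nm⁴ — the unit convention of the 0.211
prefactor — with explicit ×10⁻²⁸ conversion to M⁻¹·cm³ where that
convention is wanted.

**Förster radius.** `R₀ = 0.211 [κ² η⁻⁴ Φ_D J]^(1/6)` Å. The orientation
factor κ² defaults to 2/3 (donor and acceptor rotating isotropically
within the donor lifetime), the refractive index η to 1.4 (biomolecules
in aqueous solution). Φ_D, the donor quantum yield without acceptor, can
be supplied directly or computed relative to a standard (fluorescein
disodium, Φ = 0.92 in 0.1 N NaOH, is the built-in default standard) with
absorbance and refractive-index corrections. With κ² = 2/3, η = 1.4,
Φ_D = 0.90 and J = 1.6 × 10⁻¹³ M⁻¹·cm³ this yields R₀ ≈ 53.0 Å. A
second textbook form, `R₀⁶ = 8.79 × 10⁻⁵ κ² η⁻⁴ Φ_D J` (Å⁶), serves as
an independent cross-check in the tests; the two published constants are
themselves mutually consistent only to ≈0.07% on R₀ (0.211⁶ = 8.82 × 10⁻⁵
≠ 8.79 × 10⁻⁵), which sets the tolerance of that check.

**Efficiency and distance.** Single-point efficiencies come from donor
intensities with and without acceptor, `E = 1 − F_AD/F_D`. Because
sub-saturating acceptor occupies only a fraction θ of donor sites, the
observed efficiency is E·θ; the limiting (fully occupied) efficiency is
obtained by ordinary least squares on the transformed points
`(1/[acceptor], 1/E_obs)` — the y-intercept is 1/E at infinite acceptor.
An intercept ≤ 1 would imply E ≥ 1 and is rejected as an error rather
than propagated. The unweighted transformed-coordinate fit matches the
classical plotted procedure; a variance-weighted option (weights `E⁴`,
the inverse delta-method variance of 1/E under homoscedastic noise on E)
is provided but not default. Distance follows from
`r = R₀ (1/E − 1)^(1/6)`; the uncertainty on r is first-order
(delta-method) propagation from the standard errors of E and R₀ and is
labelled as such in reports.

**Inner-filter correction.** An absorbing ligand attenuates both the
excitation beam and the emitted light;
`F_corr = F_obs · 10^((A_exc·l_exc + A_em·l_em)/2)` with per-1-cm
absorbances scaled by the cell pathlengths (defaults: 1 cm excitation,
0.2 cm emission). Absorbances not measured directly are computed from
Beer–Lambert with the ligand extinction coefficients (defaults
8624 M⁻¹·cm⁻¹ at 494 nm and 20,983 M⁻¹·cm⁻¹ at 520 nm, the values for a
rhodamine-labeled ligand at the donor excitation/emission wavelengths).

**Binding fit.** The corrected titration is inverted into the quench
signal `S = (F₀ − F_corr)/F₀` and fitted by Levenberg–Marquardt least
squares (lmfit) with a single class of sites. Two models are
implemented. The default `quadratic_depletion` solves the site-occupancy
mass balance exactly: with receptor R, total ligand L, stoichiometry n
and `b = nR + L + K_d`, `S = F_max (b − √(b² − 4nRL))/(2nR)`. The
free≈total hyperbola `S = F_max L/(K_d + L)` is retained for comparison.
The quadratic is the default because the regime of interest has
K_d (≈1 µM) below the receptor concentration (5 µM), where ligand
depletion is far from negligible — on depletion-generated data the
hyperbola visibly overestimates K_d, and pipeline reports include both
fits so the model ambiguity stays visible. The fit acts on the quench
signal (the inverted, normalized curve), not on raw corrected intensity.

## Fitting details

* Initialization is multistart: F_max starts at the maximum observed
  signal; K_d starts at {0.1, 1, 10}× the half-saturation ligand
  concentration. The best converged start (lowest χ²) is kept; saturation
  fits have shallow, correlated (K_d, F_max) valleys and a single start
  can stall.
* n (sites per receptor, interpreted against the receptor-carrier
  concentration without resolving sites-per-dimer ambiguity) is fixed to
  1 by default and can be fitted instead.
* Uncertainties are asymptotic standard errors from the local curvature
  of the objective; an optional seeded residual bootstrap (95% percentile
  interval on K_d, 500 resamples recommended) is available.
* K_d is box-constrained to [10⁻⁶, 10⁶] µM; a fit ending on a bound is
  flagged and warned about, as is a titration whose positive ligand
  concentrations do not bracket the fitted K_d.
* Observed efficiencies or signals slightly outside their physical range
  (from noise) are clipped with a warning rather than rejected, so one
  bad point does not discard a titration.

## Synthetic data

The generators are pure functions of their spec including the seed. They
emulate:

* smooth single-band Gaussian spectra (donor emission centered at 520 nm;
  acceptor extinction centered at 556 nm with peak 41,955 M⁻¹·cm⁻¹) —
  these exercise the integrator but make no claim to reproduce any
  instrument-measured J, since real fluorophore lineshapes are asymmetric
  with vibronic structure;
* quenching titrations: the noiseless quench signal follows the
  depletion-quadratic model, corrected intensities are de-corrected
  through the inverse inner-filter factor with Beer–Lambert absorbances,
  and additive Gaussian noise (optionally multiplicative) is applied to
  the observed intensities. Defaults are the study conditions the package
  was built around: 5 µM receptor, true K_d 1.0 µM, n = 1, 12 ligand
  concentrations from 0 to 20 µM (dense below K_d), plateau quench
  fraction 0.47 (the limiting efficiency — at saturation every donor site
  is quenched with that probability), baseline 100 a.u., noise 3% of the
  plateau;
* FRET dilution series: `F_AD/F_D = 1 − E·θ(L)` with hyperbolic occupancy
  by default, chosen because 1/θ is then exactly affine in 1/L and the
  double-reciprocal extrapolation recovers E exactly in the noiseless
  limit; depletion-quadratic occupancy is available and introduces the
  slight transformed-plot curvature real data would show.

Passing round-trip tests on these generators therefore validates the
estimators and their numerics, not the photophysics of any particular
dye pair: real data add lineshape asymmetry, correlated drifts,
photobleaching and pipetting error that the generators deliberately omit.

## Numerical choices

* Common-grid spacing for J defaults to 0.5 nm; agreement with a
  0.001 nm brute-force quadrature is within 0.1% for smooth Gaussian
  bands (tested). Sharp-edged (discontinuous) bands are limited by
  edge-straddling trapezoids to ~step/width relative error.
* Spectrum loading clamps negative baseline readings to zero (logged),
  averages duplicate wavelengths, and sorts rows; the quadrature is
  undefined for negative intensities.
* The quadratic model clips its discriminant at zero to guard round-off
  for L near the equivalence point; agreement with a bisection
  mass-balance oracle is 1e-9 relative (tested).
* Efficiency/distance conversions round-trip to 1e-10 relative error;
  degenerate inputs (E outside (0,1), non-positive distances, all-equal
  concentrations, zero donor integral, disjoint spectral supports) raise
  descriptive errors rather than returning NaN.

## Problem sizes

The test suite and acceptance script run entirely on synthetic data at
desk scale: titrations of 12 points, parameter-recovery studies of 500
seeded replicates at 3% noise (median recovered K_d within 15% of truth)
and 1000 replicates at 1% noise for the efficiency extrapolation (mean
within 2%). These sizes were chosen to estimate medians and means
stably while keeping the whole suite in seconds.

## Known limitations

* Steady-state only: no lifetime (time-resolved) FRET, no acceptor
  photobleaching correction, and κ² is a scalar — orientation
  distributions are out of scope.
* Single class of sites: no cooperativity (Hill), no multi-phase
  accumulation of ligand on the lattice, no kinetic modeling of assembly
  time courses.
* The inner-filter correction is the standard mean-absorbance
  approximation, valid for moderate absorbances (≲0.3 per effective
  path).
* Uncertainty on the distance assumes independent errors on E and R₀ and
  first-order propagation; replicate-based uncertainty is the user's
  responsibility.
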