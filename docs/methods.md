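# Methods

## The kinetic model

Proteolysis of micellar β-casein by trypsin is described as a linear chain
of first-order steps, S → X → Y → N, with an optional aggregation branch
Y → Z. S is the intact micelle fraction, X the micelle with hydrolyzed
peptide bonds, Y the nanoparticle reassembled from hydrolyzed fragments,
N the soluble peptide products, Z large (>100 nm) aggregates. All species
are fractions of the initial micellar substrate, so S₀ = 1 and
S+X+Y+N+Z = 1 for all t; absolute concentrations are outside the model's
scope.

Assumptions:

- the active-enzyme concentration is constant over a run (no trypsin
  autolysis), so enzymatic steps are pseudo-first-order;
- the first and third stages are enzymatic: their effective rates are
  k₁E₀ and k₃E₀, proportional to the trypsin concentration E₀ (mg/L);
- the second stage — rearrangement of the hydrolyzed micelle into new
  nanoparticles — is a property of the substrate assembly and does not
  depend on E₀. This mixed scaling is the substantive claim: if all
  three rates scaled with E₀, the peak time of Y would be exactly
  proportional to 1/E₀ (a hyperbola), which light-scattering peak times
  contradict;
- bond-level heterogeneity is deliberately collapsed into the two
  enzymatic constants; per-bond hydrolysis kinetics are a non-goal;
- aggregation is off by default (k_a = 0, Z ≡ 0), appropriate for short
  reaction times. Whether k_a should scale with E₀ is unresolved; the
  `ka_enzyme_proportional` flag (default True) records the choice, and
  the branch is reachable only through the numerical integrator.

With a = k₁E₀, b = k₂, c = k₃E₀ pairwise distinct, the chain has the
standard Bateman closed form (see README for the formulas); N = 1−S−X−Y
makes conservation exact by construction. The peak time of Y solves
a(c−b)e^(−at) − b(c−a)e^(−bt) − c(a−b)e^(−ct) = 0. Note t = 0 solves
this identically (X and Y both start empty, so dY/dt(0) = 0); the
physical root is the interior one.

Reference constants, used as defaults throughout: k₁E₀ = 0.0066 s⁻¹,
k₂ = 0.0015 s⁻¹, k₃E₀ = 0.0002 s⁻¹ at E₀ = 0.25 mg/L. Constructors
accept either per-(mg/L) coefficients (k₁, k₃) or effective products
(k₁E₀, k₃E₀) plus the reference E₀, and normalize internally.

### Numerical choices

- **Degenerate rates.** The closed-form denominators vanish when any two
  effective rates coincide. If a pair differs by less than 1e−10
  relative, `species_closed_form` silently delegates to the integrator;
  `y_concentration` and `tmax_from_constants` raise instead, since their
  contracts are tied to the distinct-rate formulas. Tests check the
  confluent limit X(t) = a·t·e^(−at) when a = b exactly.
- **Integrator.** `ode_oracle` uses DOP853 (8th-order Runge–Kutta) at
  rtol = 1e−12, atol = 1e−14. At these tolerances closed form and
  integrator agree to better than 1e−8 max-abs over 100 random rate sets
  spanning [1e−5, 1e−1] s⁻¹ — the tightest agreement the roundoff floor
  of the three-exponential formula supports at the long time spans
  involved (up to 5·10⁵ s).
- **Peak-time solver.** The t_max expression is scanned on 400 log-spaced
  points over [1e−3/max(rates), 10/min(rates)]; the first sign change is
  polished with Brent's method (xtol 1e−12). The lower scan edge avoids
  the spurious t = 0 root. Y is unimodal for positive distinct rates, so
  exactly one interior sign change exists.
- **k₂ fitting.** 1-D bounded minimization (scipy `minimize_scalar`,
  bounds [1e−6, 1] s⁻¹, xatol 1e−12) of the sum of squared peak-time
  residuals, with k₁ and k₃ held fixed. A single noiseless observation
  inverts exactly; candidate k₂ values that make the root search fail are
  assigned infinite cost rather than aborting the fit.
- **Lag time.** Defined here as the first time N(t) reaches a threshold
  (default 0.05), linearly interpolated between grid points; `inf` with a
  warning if the grid ends first. The threshold choice is the package's
  own — lag is a qualitative notion and any fixed small threshold yields
  the same ordering across enzyme levels, which is what the model
  predicts (lag grows as E₀ falls).
- **Structure-recovery peak.** The S+X/2+Y curve declines, then passes a
  local maximum as nanoparticles transiently accumulate.
  `interior_local_max_time` finds the first discrete downturn after the
  first rise that follows the initial decline; it returns None for
  monotone decay (very high enzyme). On the 1 s-resolution grids used in
  tests the discrete peak is within one grid step of the continuous one.

### Secondary-structure prediction

Two retention hypotheses map species fractions to overall regular
(β-sheet + α-helix) structure content, both normalized to 1 at t = 0:
S+Y assumes structure survives only in intact micelles and new
nanoparticles; S+X/2+Y additionally credits hydrolyzed micelles with half
their structure. The second tracks measured amide-I time courses more
closely — it reproduces the early partial recovery of β-sheet signal at
low enzyme — and is the default coupling in the synthetic generator.

## FTIR processing chain

The chain mirrors standard difference-spectroscopy practice for reaction
monitoring in the amide window, in this fixed order: (1) subtract the
enzyme-solution spectrum; (2) subtract the straight line through the
spectrum's values at 1725 and 1375 cm⁻¹ and keep only that window;
(3) scale to equal (signed trapezoidal) area over the window; (4) subtract
the first spectrum of the series (t = 1 min convention); (5) read band
intensities at 1633 (β-sheet), 1650 (α-helix), 1593 and 1405 cm⁻¹ (free
carboxylates, the product signal). Δabsorbance is (t) − (1 min), so
structure loss is negative and product growth positive.

Choices where practice varies:

- **Normalization target** 1 AU·cm⁻¹; any common constant gives identical
  difference-spectrum shapes up to scale.
- **Signed, not absolute, area**: a baseline-corrected amide window is
  non-negative in practice; non-positive area raises instead of silently
  flipping sign.
- **Band read-off** by linear interpolation at the nominal wavenumber, so
  results are independent of whether the 4 cm⁻¹ grid happens to hit the
  band center.
- **No implicit resampling**: series operations demand identical grids;
  `regrid` (linear) must be called explicitly.
- Anchors are read by the same linear interpolation when they fall off
  the grid; corrected spectra are exactly zero at both anchors.

## AFM particle statistics

Dried particles flatten on mica, so each is a (height H, diameter D)
pair; H > D warns. Summaries are arithmetic mean ± sample SD. Height and
diameter histograms use fixed bins (defaults 0.2 nm and 5 nm) anchored at
the data minimum; modes are local maxima of the 3-bin moving average of
counts, with zero padding so edge bins can host a mode, and a floor of 5%
of the tallest smoothed bin so isolated tail counts do not register as
modes. This keeps detection fully auditable (bin width, window, floor
determine the result) and invariant to uniform count scaling.

Since the geometry behind reported mean particle volumes is
underdetermined, two flattened-particle volume models are provided:
spherical cap V = (πH/6)(3(D/2)² + H²) (default) and half-ellipsoid
V = (2/3)π(D/2)²H; they coincide at H = D/2. Reported mean volumes
(3500 and 2200 nm³ for heat- and inhibitor-stopped samples) are treated
as inputs; the sphere-equivalent radius conversion r = (3V/4π)^(1/3) is
reproduced exactly (9.4 and 8.1 nm).

## Synthetic data

The generator produces every input the analysis consumes, with ground
truth attached, under one seeded numpy Generator (same seed + config ⇒
bitwise-identical output).

- **Peak-time tables**: t_max from the transcendental condition at each
  E₀ in {0.125, 0.25, 0.5, 1} mg/L (the k₂-fitting grid), perturbed by
  multiplicative lognormal noise (σ = 0.1 by default, median 1),
  emulating the 1–2 min read-off resolution of scattering kinetics.
- **FTIR series**: Gaussian bands (σ = 12 cm⁻¹, a typical amide-I
  component width; synthetic, not fitted to any instrument) at
  1633/1650/1593/1405 cm⁻¹ on a descending 1800–1300 cm⁻¹ grid at
  4 cm⁻¹. Structure-band amplitudes follow S+X/2+Y evaluated on the
  supplied trajectory plus a non-reacting residual offset (keeping the
  window strictly positive so area normalization is well-posed);
  product-band amplitudes follow N(t). A linear baseline drift, a broad
  low-amplitude enzyme Gaussian (center 1550 cm⁻¹, σ 120 cm⁻¹ — present
  so reference subtraction is exercised nontrivially) and white noise
  (σ = 0.002 AU) are added. Acquisition times run 1–90 min.
  Because equal-area normalization rescales each spectrum and neighboring
  bands overlap (1633 and 1650 cm⁻¹ are 1.4σ apart), the raw amplitude
  schedules are not directly observable; the truth record therefore also
  contains `normalized_traces`, the analytically replayed post-chain
  expectation, which the pipeline reproduces exactly in the noiseless
  limit and to RMSE ≪ noise σ otherwise.
- **Particle ensembles**: heights from a Gaussian mixture (defaults
  0.4·N(0.8, 0.2) + 0.6·N(3.8, 0.6) nm, the bimodal heat-stopped
  pattern; a single component at 1 nm mimics the inhibitor-stopped one),
  diameters from N(58, 12) nm; negatives are resampled, not clipped, so
  densities stay smooth near zero.

What the generator does *not* emulate: Voigt/instrument line shapes,
atmospheric (water vapor, CO₂) interference, D₂O-exchange band shifts,
detector drift beyond a linear baseline, AFM tip broadening, or any
correlation between particle height and diameter. Passing tests
therefore demonstrate correctness of the algorithms and their mutual
consistency on data matching the model's assumptions — not robustness to
every artifact of real spectra or topographs.

## Problem sizes

Defaults were chosen so each analysis resolves its quantity comfortably:
trajectories on 2001-point grids over 2·10⁴ s (about 12 times the
reference t_max); lag/peak orderings on 30001-point grids over 3·10⁴ s;
the noisy-recovery study uses 200 replicate fits at 4 enzyme levels;
FTIR series use 12 acquisition times over 90 min; particle ensembles
n = 1000. The whole test suite and the acceptance script each run in
well under a minute.

## Known limitations

- The closed form requires pairwise-distinct effective rates; exactly
  coincident rates silently use the integrator, so results there carry
  integrator (1e−12 relative) rather than closed-form accuracy.
- k₂ fitting assumes k₁ and k₃ known exactly; errors in those constants
  propagate into k₂ and are not quantified here.
- The published k₂ = 0.0015 s⁻¹ was fitted to peak-time observations
  that are not tabulated anywhere we can read them from; recovery is
  therefore demonstrated against synthetic observations generated at the
  published constants, not against the original data.
- Mode detection depends on bin width; the defaults resolve the
  0.8/3.8 nm structure at n ≈ 1000 but very small ensembles may need
  wider bins.
- The FTIR chain does no curve fitting or second-derivative band
  decomposition; band traces are raw difference intensities at nominal
  positions.
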