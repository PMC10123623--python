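# Methods

## The problem

Laurdan is an environment-sensitive fluorescent probe that inserts into
lipid bilayers near the glycerol backbone.  When the local environment —
hydration water and polar lipid moieties — can reorient around the probe's
enlarged excited-state dipole within the fluorescence lifetime ("dipolar
relaxation"), emitted photons lose energy and the emission shifts to longer
wavelengths.  The steady-state emission spectrum of Laurdan in a membrane is
therefore well approximated by a two-state superposition: a short-wavelength
band from probes in a nonrelaxing (ordered/dehydrated) environment and a
long-wavelength band from probes in a readily relaxing (fluid/hydrated)
environment.  This package quantifies that balance two ways along a
condition axis (relative humidity of the atmosphere above a solid-supported
bilayer, or cholesterol molar fraction):

1. **Generalized polarization**, GP = (I₄₄₀ − I₄₉₀)/(I₄₄₀ + I₄₉₀), a
   ratiometric summary statistic;
2. **Two-band log-normal decomposition**, giving the area fractions of the
   relaxed and nonrelaxed populations.

## The band model

Each band is an asymmetric log-normal (Siano–Metzler) peak in the
wavenumber domain, parameterized by the peak intensity I_m, the peak
position ν_m, and the two half-intensity positions ν_max > ν_m > ν_min:

    I(ν) = I_m · exp[ −(ln 2 / ln²ρ) · ln²( (a − ν)/(a − ν_m) ) ]

with asymmetry ρ = (ν_m − ν_min)/(ν_max − ν_m), FWHM H = ν_max − ν_min, and
limiting wavenumber a = ν_m + Hρ/(ρ² − 1), beyond which the band is exactly
zero.  For ρ > 1 the band cuts off sharply above the peak and tails toward
low wavenumber (long wavelength), the usual shape of solvatochromic
emission.  ρ = 1 is the Gaussian limit and is implemented as an explicit
branch (|ρ − 1| < 1e-8) to avoid the removable singularity in a; a
continuity test pins the two branches to within 1e-5·I_m of each other.
The conventions are pinned by exact identities — I(ν_m) = I_m and
I(ν_max) = I(ν_min) = I_m/2 — enforced in the test suite to 1e-9.

The band area has the closed form
area = I_m·(a − ν_m)·ln ρ·√(π/ln 2)·exp(ln²ρ/(4 ln 2)) (ρ ≠ 1), continuous
at the Gaussian limit I_m·(H/2)·√(π/ln 2); it is cross-checked against
adaptive quadrature to 1e-8 relative.  Population fractions are analytic
band areas relative to the total fitted area, so they sum to 100% exactly.

## Fitting

Fits minimize the sum of squared intensity residuals in the wavenumber
domain (intensities as measured; no Jacobian reweighting — the model
describes the recorded counts, which is the field's standard practice).  Each band is internally reparameterized as
(I_m, ν_m, H, ρ) with box constraints, so the asymmetry cap ρ ≤ 1.5 is
guaranteed by construction rather than by post-hoc rejection.  Default
bounds (overridable):

| parameter | default | rationale |
|---|---|---|
| ν_m (long band) | 1e7/510 … 1e7/455 cm⁻¹ | brackets reported relaxed-band peaks (475–482 nm) |
| ν_m (short band) | 1e7/450 … 1e7/410 cm⁻¹ | brackets reported nonrelaxed-band peaks (427–430 nm) |
| H | 800 … 4000 cm⁻¹ | physically plausible emission bandwidths |
| ρ | 0.5 … 1.5 | asymmetry cap and its reciprocal |
| I_m | ≥ 0 | nonnegative intensities |

The optimizer is bounded trust-region least squares (lmfit/SciPy `trf`)
with Jacobian-based variable scaling, iteration budget 2000 evaluations
per start, and 1e-10 cost tolerances.  Non-convergence is flagged on the
result object, never silently discarded.

**Multistart pre-search.**  The two-band problem on a finite window is
nearly degenerate: distinct parameter sets reproduce the same spectrum to
~1e-5 relative, and the cost surface has spurious local minima separated
from the global one by genuine barriers.  A single-start fit can stall a
few hundred cm⁻¹ from the true peak positions even on noiseless data.
`fit_individual` therefore seeds the local optimizer from a deterministic
coarse grid over the six shape parameters (10 positions × 7 widths × 5
asymmetries per band); because the model is linear in the two peak
intensities, each of the ~110 000 shape pairs gets closed-form optimal
amplitudes in a fully vectorized pass, and the six lowest-residual
candidates (plus the data-driven heuristic guess) are polished.  On
noiseless in-family spectra this recovers all eight parameters to better
than 1e-3 relative.

**Global fit.**  For a condition series, individual fits of the
spot-averaged spectrum of every condition provide starting values (their
parameter means, per the standard protocol); the joint fit then shares the
two ν_m values across all conditions while I_m, H, ρ stay
condition-specific, concatenating all residuals unweighted.  Sharing the
peak positions is what makes them well determined (see Limitations).

Degenerate fits (band separation < 200 cm⁻¹) are flagged; constant spectra
are rejected; R² = 1 − SS_res/SS_tot is reported per spectrum.

## GP

I₄₄₀ and I₄₉₀ are means over a window of grid samples (default five
points, ≈2 nm at 0.4 nm spacing) centered on the grid point nearest 440
and 490 nm; an even window takes its extra sample on the
shorter-wavelength side, making the definition deterministic.  GP is
computed per spot on raw spectra (it is scale-invariant, so normalization
is irrelevant), then summarized per condition as mean ± sample SD over
replicates (default minimum 10 spots).

## Preprocessing

FFT smoothing (zeroing components above a cutoff fraction of Nyquist,
default 0.1) and max-normalization are presentation aids and are *not*
applied before GP or fitting by default.  The smoother clips the rare
negative undershoot at steep edges to keep intensities valid, so exact
linearity holds only where the filtered signal stays nonnegative.
Replicate aggregation is the unweighted pointwise mean over spots (default
minimum 5), which is the prescribed input to the individual fits.

## Synthetic generator

The generator emulates exactly the statistical structure the analysis
assumes: two fixed band templates, area-normalized and mixed with a
condition-dependent weight `fraction_long` ∈ [0, 1], scaled to a nominal
peak of 1000 counts, with additive Gaussian detector noise (σ = 1% of the
condition's peak by default) and per-spot multiplicative brightness jitter
(σ = 5%) — magnitudes chosen so replicate GP spreads are a few hundredths,
comparable to typical spot-to-spot uncertainties; they are synthetic
stand-ins, not values fitted to data.  Negative noisy samples are clipped
to zero.  A single seeded NumPy generator drives all randomness, so equal
seeds give bit-identical sets; the truth record stores every generating
parameter.

Preset condition axes: dehydration (bulk immersion encoded as RH = 100,
then 95…10, 0% RH), cholesterol (x = 0…0.6), and a phase-separated-L_d
variant.  Fraction trajectories interpolate linearly between endpoint
values down to the plateau onset; intermediate experimental values exist
only as published figure curves and are deliberately not digitized.

**Calibration** (`scripts/calibrate_presets.py`, constants committed in
`laurdanspec.synthetic`): peak positions (475/427 nm dehydration,
482/430 nm cholesterol) and the dehydration fraction endpoints (0.79 bulk,
0.18 at ≤20% RH) are fixed benchmark values; asymmetries ρ = 1.3/1.2 were
fixed a priori as typical red-tailed emission shapes; the two FWHMs were
then solved (H_long = 3799.895, H_short = 2607.069 cm⁻¹) so the noise-free
pipeline yields GP = 0.62 at 0% RH and GP = −0.08 at bulk (any clearly
negative fluid-phase value would do; −0.08 is typical), and the
cholesterol endpoint fraction (0.35591 at x = 0.6) so GP there equals
0.38.  This is a one-time documented computation, not a runtime search.

What the generator does *not* emulate: baseline drifts, cosmic rays,
wavelength-dependent detector response, vibronic structure, three-state
mixtures, liquid-ordered-phase spectra, or any photophysical kinetics.
Passing round-trip tests therefore demonstrates internal consistency of
the pipeline under its own model assumptions, not robustness to every
artifact of real acquisitions.

## Numerical choices and degenerate inputs

- Wavelength↔wavenumber conversion uses ν = 1e7/λ; the Jacobian factor
  λ²/1e7 is available but off by default (fits operate on measured
  intensities).
- Shared grids must match exactly; resampling (linear interpolation, no
  extrapolation) must be requested explicitly so acquisition mismatches
  cannot hide.
- Grid coverage check in the generator: the grid must contain both bands'
  half-intensity support.  (Requiring coverage down to 1% of peak would
  reject every realistic configuration: the relaxed band's 1% support
  extends beyond 700 nm, far outside the standard 400–600 nm window.)
- Quadrature for band areas integrates over ±50 FWHM intersected with the
  band support; the tail decays superpolynomially, so this bounds all mass.
- lmfit's internal bound transform can overshoot a box constraint by one
  ulp; returned asymmetries are clamped to the 1.5 cap so the constraint is
  exact.
- Problem sizes: the default grid has 501 points; test ensembles use 20
  noiseless random-parameter spectra (fit-quality floor), 1000 random
  spectra (GP bounds), and 11 conditions × 10 spots (constraint
  enforcement and recovery).

## Known limitations

- **Per-spectrum identifiability.**  With realistic band widths the two
  bands overlap strongly, and an unconstrained 8-parameter fit of a single
  spectrum has a nearly flat likelihood valley: at 1% additive noise,
  fitted peak positions scatter by several hundred cm⁻¹ and area fractions
  by ~10 percentage points even when the optimizer is seeded at the true
  parameters.  Individual-fit parameters of noisy single spectra should be
  treated as descriptive.  The global fit resolves this — sharing the two
  peak positions across a condition series pins them to a few cm⁻¹ — and
  is the intended route to quantitative population trajectories.
- The two-band model is exactly the generator's model; model mismatch
  (e.g. a third population, L_o-phase contributions) is out of scope.
- GP window placement snaps to the nearest grid point; on grids much
  coarser than ~2 nm the "five-point" window no longer approximates the
  nominal ±1 nm region.
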