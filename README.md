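# laurdanspec

Analysis of steady-state **Laurdan** emission spectra from lipid membranes:
generalized polarization (GP), two-band log-normal spectral decomposition
with individual and global fitting, and population-fraction trajectories
along a condition axis (membrane hydration as relative humidity, or
cholesterol molar fraction).  Written for membrane biophysicists who record
spot-resolved emission spectra of solid-supported bilayers and want a
reproducible, tested pipeline from raw spectral tables to condition
trajectories — plus a calibrated synthetic generator so every stage can be
exercised and validated without experimental data.

## The statistics at the core

**Generalized polarization** summarizes the balance between nonrelaxed
(blue) and relaxed (red) emission:

    GP = (I₄₄₀ − I₄₉₀) / (I₄₄₀ + I₄₉₀)

with I₄₄₀, I₄₉₀ averaged over five grid points (≈2 nm) around 440 and
490 nm, computed per spot and reported per condition as mean ± SD.

**Two-band decomposition** models each spectrum in the wavenumber domain as
the sum of two asymmetric log-normal (Siano–Metzler) bands,

    I(ν) = I_m · exp[ −(ln 2/ln²ρ) · ln²((a − ν)/(a − ν_m)) ],

where ν_m is the peak position, ρ = (ν_m − ν_min)/(ν_max − ν_m) the
asymmetry (capped at 1.5), H = ν_max − ν_min the FWHM, and
a = ν_m + Hρ/(ρ² − 1) the limiting wavenumber.  Constrained least squares
fits each spectrum individually; a **global fit** then shares the two peak
positions across all conditions of a series.  The relaxed/nonrelaxed
population fractions are the analytic band areas as percentages of the
total fitted area.

## Worked example

```python
import laurdanspec as ls

# synthetic dehydration series (noise off): bulk immersion -> 0% RH
cfg = ls.make_config("dehydration", spots=1, noise=False, seed=1)
spectra, truth = ls.generate(cfg)

bulk, dry = spectra.select(100.0)[0], spectra.select(0.0)[0]
print(f"GP(bulk) = {ls.gp(bulk).gp:+.3f}")
print(f"GP(0% RH) = {ls.gp(dry).gp:+.3f}")

fit = ls.fit_individual(bulk)
print(f"bulk: R^2 = {fit.r2:.6f}, relaxed fraction = {fit.fraction_long:.1f}%")

gfit = ls.fit_global(spectra)
print(f"global fit: relaxed band peak = {gfit.peak_long_nm:.1f} nm, "
      f"nonrelaxed = {gfit.peak_short_nm:.1f} nm")
```

prints

```
GP(bulk) = -0.080
GP(0% RH) = +0.620
bulk: R^2 = 1.000000, relaxed fraction = 79.0%
global fit: relaxed band peak = 475.0 nm, nonrelaxed = 427.0 nm
```

A fully hydrated fluid bilayer shows negative GP and ~79% of the emission
in the relaxed (long-wavelength) band; full dehydration drives GP to 0.62
with the relaxed population collapsing to 18%, while the two band positions
stay fixed — the spectra interconvert between two populations rather than
shifting continuously.

The same analysis runs from the shell on long-format CSV tables
(`condition_kind, condition_value, spot, wavelength_nm, intensity`):

```sh
laurdan simulate --preset dehydration --spots 10 --seed 42 -o spectra.csv
laurdan gp spectra.csv -o gp_trajectory.csv
laurdan decompose spectra.csv --global -o decomposition.json
laurdan run config.yaml            # full pipeline -> report bundle
laurdan compare reportA/ reportB/  # per-condition trajectory differences
```

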