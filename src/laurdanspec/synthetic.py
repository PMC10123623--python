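"""Synthetic Laurdan spectrum-set generator.

Emulates the two-state statistical structure the analysis assumes: every
spectrum is a superposition of two fixed asymmetric log-normal bands — a
long-wavelength (relaxed) and a short-wavelength (nonrelaxed) component —
whose *area fractions* interconvert along a condition axis while the band
shapes stay put.  Bands are area-normalized before mixing, so the mixing
weight ``fraction_long`` is exactly the long band's true area fraction and
decomposition can be validated against it.  Replicate ("spot") noise is
additive Gaussian detector noise plus a multiplicative per-spot brightness
jitter.

Three calibrated presets ship as fixed constants:

* ``dehydration`` — a single-lipid fluid bilayer dried from bulk immersion
  (condition value 100, labelled "bulk") through 95..10% relative humidity
  down to 0% RH.  Band peaks 475 / 427 nm; the relaxed fraction falls
  linearly from 0.79 at bulk to 0.18 at 20% RH and plateaus below.
* ``cholesterol`` — a fully hydrated binary bilayer with cholesterol molar
  fraction 0..0.6.  Band peaks 482 / 430 nm; the relaxed fraction declines
  more shallowly, from 0.79 to ~0.356.
* ``phase_separated_ld`` — the liquid-disordered phase of a phase-separated
  ternary membrane under dehydration: decline from bulk to 50% RH, plateau
  between 50 and 20% RH, then a small further decline.

The band widths/asymmetries and the cholesterol endpoint fraction were fixed
by a one-time calibration (see ``scripts/calibrate_presets.py``) so that the
noise-free pipeline reproduces the benchmark endpoint values: bulk GP < 0,
GP = 0.62 at 0% RH, GP = 0.38 at x_chol = 0.6, relaxed fraction 79% (bulk)
and 18% (0% RH).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bandshape import LogNormalBand
from .spectra_io import Spectrum, SpectrumSet

__all__ = [
    "GeneratorConfig",
    "BandTemplate",
    "PRESETS",
    "fraction_trajectory",
    "make_config",
    "generate",
    "calibrate_presets",
]

# ---------------------------------------------------------------------------
# calibrated constants (outputs of scripts/calibrate_presets.py, committed)

#: band FWHM (cm^-1) solved so the dehydration endpoints give GP = 0.62 at
#: 0% RH and GP = -0.08 at bulk on the default grid
H_LONG = 3799.895
H_SHORT = 2607.069
#: band asymmetries (low-wavenumber tail), fixed before calibration
RHO_LONG = 1.3
RHO_SHORT = 1.2
#: relaxed-fraction endpoint of the cholesterol preset at x_chol = 0.6,
#: solved so the noise-free pipeline gives GP = 0.38 there
F_CHOL_END = 0.35591

#: condition value used for bulk-water immersion on the RH axis
BULK_RH = 100.0
#: RH below which the dehydration band fractions plateau
PLATEAU_RH = 20.0


@dataclass(frozen=True)
class BandTemplate:
    """Shape of one generator band (peak intensity is set by mixing)."""

    peak_nm: float
    fwhm: float
    rho: float

    @property
    def nu_m(self) -> float:
        return 1e7 / self.peak_nm

    def band(self, i_max: float = 1.0) -> LogNormalBand:
        return LogNormalBand.from_shape(i_max, self.nu_m, self.fwhm, self.rho)

    def to_dict(self) -> dict:
        return {"peak_nm": self.peak_nm, "fwhm": self.fwhm, "rho": self.rho}


_PRESET_TEMPLATES = {
    "dehydration": (
        BandTemplate(475.0, H_LONG, RHO_LONG),
        BandTemplate(427.0, H_SHORT, RHO_SHORT),
    ),
    "cholesterol": (
        BandTemplate(482.0, H_LONG, RHO_LONG),
        BandTemplate(430.0, H_SHORT, RHO_SHORT),
    ),
    # L_d phase of a phase-separated membrane contains cholesterol, so it
    # shares the cholesterol-series band positions
    "phase_separated_ld": (
        BandTemplate(482.0, H_LONG, RHO_LONG),
        BandTemplate(430.0, H_SHORT, RHO_SHORT),
    ),
}

_PRESET_AXES = {
    "dehydration": ("hydration", [BULK_RH, 95.0, 80.0, 70.0, 60.0, 50.0,
                                  40.0, 30.0, 20.0, 10.0, 0.0]),
    "cholesterol": ("cholesterol", [0.0, 0.1, 0.2, 0.25, 0.3, 0.4, 0.5, 0.6]),
    "phase_separated_ld": ("hydration", [BULK_RH, 95.0, 80.0, 70.0, 60.0,
                                         50.0, 40.0, 30.0, 20.0, 10.0, 0.0]),
}

PRESETS = tuple(_PRESET_TEMPLATES)


def fraction_trajectory(preset: str, condition: float) -> float:
    """Relaxed-population (long-band) area fraction at one condition value.

    dehydration: linear from 0.79 at bulk (RH 100) to 0.18 at 20% RH,
    constant below.  cholesterol: linear from 0.79 at x = 0 to the
    calibrated endpoint at x = 0.6.  phase_separated_ld: linear decline
    0.75 -> 0.50 from bulk to 50% RH, plateau to 20% RH, then a small
    further decline to 0.45 at 0% RH.
    """
    if preset == "dehydration":
        if not 0.0 <= condition <= BULK_RH:
            raise ValueError(f"RH {condition} outside [0, {BULK_RH}]")
        if condition <= PLATEAU_RH:
            return 0.18
        return 0.18 + (0.79 - 0.18) * (condition - PLATEAU_RH) / (BULK_RH - PLATEAU_RH)
    if preset == "cholesterol":
        if not 0.0 <= condition <= 0.6:
            raise ValueError(f"x_chol {condition} outside [0, 0.6]")
        return 0.79 + (F_CHOL_END - 0.79) * condition / 0.6
    if preset == "phase_separated_ld":
        if not 0.0 <= condition <= BULK_RH:
            raise ValueError(f"RH {condition} outside [0, {BULK_RH}]")
        if condition >= 50.0:
            return 0.50 + (0.75 - 0.50) * (condition - 50.0) / (BULK_RH - 50.0)
        if condition >= PLATEAU_RH:
            return 0.50
        return 0.45 + (0.50 - 0.45) * condition / PLATEAU_RH
    raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")


@dataclass
class GeneratorConfig:
    """Everything needed to generate one synthetic spectrum set.

    ``noise_additive`` is the additive Gaussian sigma as a fraction of the
    condition's noise-free peak intensity (default 1%); ``noise_brightness``
    is the per-spot multiplicative brightness jitter sigma (default 5%) —
    magnitudes chosen so replicate GP spreads are comparable to the few-
    hundredths uncertainties typical of spot-to-spot spectral measurements.
    """

    preset: str = "custom"
    axis_kind: str = "custom"
    conditions: list = field(default_factory=list)
    band_long: BandTemplate = None
    band_short: BandTemplate = None
    fraction_long: dict = field(default_factory=dict)  # condition -> [0, 1]
    grid_nm: tuple = (400.0, 600.0, 0.4)               # start, stop, step
    spots: int = 10
    noise_additive: float = 0.01
    noise_brightness: float = 0.05
    peak_counts: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        if self.band_long is not None and self.band_short is not None:
            if self.band_short.nu_m <= self.band_long.nu_m:
                raise ValueError("band_short must peak at higher wavenumber")
        for c, f in self.fraction_long.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction_long[{c}] = {f} outside [0, 1]")

    def grid(self) -> np.ndarray:
        start, stop, step = self.grid_nm
        return np.arange(start, stop + step / 2, step)

    def truth(self) -> dict:
        """JSON-serializable record of every generating parameter."""
        return {
            "preset": self.preset,
            "axis_kind": self.axis_kind,
            "conditions": list(self.conditions),
            "fraction_long": {str(c): self.fraction_long[c] for c in self.conditions},
            "band_long": self.band_long.to_dict(),
            "band_short": self.band_short.to_dict(),
            "grid_nm": list(self.grid_nm),
            "spots": self.spots,
            "noise_additive": self.noise_additive,
            "noise_brightness": self.noise_brightness,
            "peak_counts": self.peak_counts,
            "seed": self.seed,
        }


def make_config(
    preset: str,
    spots: int = 10,
    noise: bool = True,
    seed: int = 0,
    conditions: list | None = None,
    grid_nm: tuple = (400.0, 600.0, 0.4),
) -> GeneratorConfig:
    """Build a :class:`GeneratorConfig` for one of the shipped presets."""
    if preset not in _PRESET_TEMPLATES:
        raise ValueError(f"unknown preset {preset!r}; choose from {PRESETS}")
    long_t, short_t = _PRESET_TEMPLATES[preset]
    axis_kind, default_conditions = _PRESET_AXES[preset]
    conditions = list(conditions) if conditions is not None else list(default_conditions)
    return GeneratorConfig(
        preset=preset,
        axis_kind=axis_kind,
        conditions=conditions,
        band_long=long_t,
        band_short=short_t,
        fraction_long={c: fraction_trajectory(preset, c) for c in conditions},
        grid_nm=grid_nm,
        spots=spots,
        noise_additive=0.01 if noise else 0.0,
        noise_brightness=0.05 if noise else 0.0,
        seed=seed,
    )


def _mixture(config: GeneratorConfig, fraction_long: float, nu: np.ndarray) -> np.ndarray:
    bl = config.band_long.band()
    bs = config.band_short.band()
    return (
        fraction_long * bl.evaluate(nu) / bl.area()
        + (1.0 - fraction_long) * bs.evaluate(nu) / bs.area()
    )


def generate(config: GeneratorConfig) -> tuple:
    """Generate a :class:`SpectrumSet` and its truth record.

    Per condition and spot: spectrum = brightness x [f * band_long +
    (1 - f) * band_short] (area-normalized bands) scaled to
    ``peak_counts`` at the noise-free maximum, plus additive Gaussian noise;
    negative noisy samples are clipped to zero.  A single seeded random
    stream drives all noise, so equal seeds give bit-identical output.
    """
    if config.band_long is None or config.band_short is None:
        raise ValueError("config must define both band templates")
    grid = config.grid()
    nu = 1e7 / grid
    # the grid must cover both bands' half-intensity support
    for name, t in (("band_long", config.band_long), ("band_short", config.band_short)):
        b = t.band()
        lo_nm, hi_nm = 1e7 / b.nu_max, 1e7 / b.nu_min
        if grid[0] > lo_nm or grid[-1] < hi_nm:
            raise ValueError(
                f"grid [{grid[0]}, {grid[-1]}] nm does not cover the "
                f"half-intensity support of {name} [{lo_nm:.1f}, {hi_nm:.1f}] nm"
            )
    rng = np.random.default_rng(config.seed)
    spectra = []
    for cond in config.conditions:
        f = config.fraction_long[cond]
        base = _mixture(config, f, nu)
        base = base * (config.peak_counts / base.max())
        for k in range(config.spots):
            brightness = 1.0
            if config.noise_brightness > 0:
                brightness = max(0.2, 1.0 + rng.normal(0.0, config.noise_brightness))
            iy = brightness * base
            if config.noise_additive > 0:
                iy = iy + rng.normal(0.0, config.noise_additive * config.peak_counts,
                                     size=iy.size)
            meta = {"seed": config.seed, "preset": config.preset}
            if cond == BULK_RH and config.axis_kind == "hydration":
                meta["label"] = "bulk"
            spectra.append(
                Spectrum(
                    wavelengths=grid,
                    intensities=np.clip(iy, 0.0, None),
                    condition_kind=config.axis_kind,
                    condition_value=float(cond),
                    spot_id=f"spot{k + 1:02d}",
                    meta=meta,
                )
            )
    return SpectrumSet(spectra, axis_kind=config.axis_kind,
                       conditions=list(config.conditions)), config.truth()


def calibrate_presets() -> dict:
    """Return the shipped calibration constants for every preset.

    These are fixed package data produced by a one-time documented
    computation (``scripts/calibrate_presets.py``), not a runtime search.
    """
    out = {}
    for preset, (long_t, short_t) in _PRESET_TEMPLATES.items():
        axis_kind, conditions = _PRESET_AXES[preset]
        out[preset] = {
            "band_long": long_t.to_dict(),
            "band_short": short_t.to_dict(),
            "axis_kind": axis_kind,
            "conditions": list(conditions),
            "fraction_long": {str(c): fraction_trajectory(preset, c)
                              for c in conditions},
        }
    return out
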