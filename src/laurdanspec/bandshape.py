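"""Asymmetric log-normal emission band model (Siano–Metzler form).

One band is parameterized by four primary quantities, all of which are the
free parameters during fitting:

* ``i_max`` — peak intensity (counts),
* ``nu_m`` — wavenumber of the intensity maximum (cm^-1),
* ``nu_max`` / ``nu_min`` — upper / lower half-intensity wavenumbers (cm^-1).

Derived quantities: asymmetry ``rho = (nu_m - nu_min)/(nu_max - nu_m)``,
full width at half maximum ``H = nu_max - nu_min``, and the limiting
wavenumber ``a = nu_m + H*rho/(rho^2 - 1)`` (rho != 1) beyond which the band
is exactly zero.  For rho > 1 the band has a sharp cutoff above the peak and
a tail toward low wavenumber (long wavelength), the usual shape of
solvatochromic emission bands.  rho = 1 is the Gaussian limit, handled as an
explicit branch to avoid the removable singularity in ``a``.

The intensity profile for rho != 1 is

    I(nu) = i_max * exp( -(ln 2 / ln^2 rho) * ln^2( (a - nu)/(a - nu_m) ) )

on the side of ``a`` containing the peak, and 0 beyond.  This convention
satisfies I(nu_m) = i_max and I(nu_max) = I(nu_min) = i_max/2 exactly, which
pins the functional form; those identities are enforced by tests.

The band area has the closed form (substitution u = ln((a-nu)/(a-nu_m)))

    area = i_max * (a - nu_m) * ln(rho) * sqrt(pi/ln 2) * exp(ln^2 rho / (4 ln 2))

for rho != 1, continuous at the Gaussian limit i_max * (H/2) * sqrt(pi/ln 2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad

from .spectra_io import Spectrum

__all__ = ["LogNormalBand", "TwoBandModel", "model_spectrum"]

_LN2 = np.log(2.0)
#: |rho - 1| below this uses the Gaussian branch
_GAUSS_EPS = 1e-8


@dataclass(frozen=True)
class LogNormalBand:
    """One asymmetric log-normal emission band (wavenumber domain)."""

    i_max: float
    nu_m: float
    nu_max: float
    nu_min: float

    def __post_init__(self):
        if not (self.nu_min < self.nu_m < self.nu_max):
            raise ValueError(
                f"band ordering violated: need nu_min < nu_m < nu_max, got "
                f"{self.nu_min}, {self.nu_m}, {self.nu_max}"
            )
        if self.i_max <= 0:
            raise ValueError(f"i_max must be positive, got {self.i_max}")

    @classmethod
    def from_shape(cls, i_max: float, nu_m: float, fwhm: float, rho: float) -> "LogNormalBand":
        """Build from (peak, position, FWHM H, asymmetry rho).

        Inverse relations: nu_max = nu_m + H/(1+rho), nu_min = nu_m - H*rho/(1+rho).
        """
        if fwhm <= 0 or rho <= 0:
            raise ValueError(f"need fwhm > 0 and rho > 0, got {fwhm}, {rho}")
        return cls(
            i_max=i_max,
            nu_m=nu_m,
            nu_max=nu_m + fwhm / (1.0 + rho),
            nu_min=nu_m - fwhm * rho / (1.0 + rho),
        )

    @property
    def rho(self) -> float:
        """Asymmetry (nu_m - nu_min)/(nu_max - nu_m); 1 is Gaussian."""
        return (self.nu_m - self.nu_min) / (self.nu_max - self.nu_m)

    @property
    def fwhm(self) -> float:
        """Full width at half maximum H = nu_max - nu_min (cm^-1)."""
        return self.nu_max - self.nu_min

    @property
    def limit(self) -> float:
        """Limiting wavenumber a; the band is zero at and beyond it (rho != 1)."""
        rho = self.rho
        if abs(rho - 1.0) < _GAUSS_EPS:
            raise ValueError("Gaussian band (rho = 1) has no finite limiting wavenumber")
        return self.nu_m + self.fwhm * rho / (rho**2 - 1.0)

    def evaluate(self, nu) -> np.ndarray:
        """Band intensity at wavenumber(s) ``nu`` (cm^-1); vectorized."""
        nu = np.asarray(nu, dtype=float)
        rho = self.rho
        if abs(rho - 1.0) < _GAUSS_EPS:
            return self.i_max * np.exp(-4.0 * _LN2 * (nu - self.nu_m) ** 2 / self.fwhm**2)
        a = self.limit
        arg = (a - nu) / (a - self.nu_m)
        out = np.zeros(nu.shape, dtype=float)
        ok = arg > 0
        out[ok] = self.i_max * np.exp(
            -(_LN2 / np.log(rho) ** 2) * np.log(arg[ok]) ** 2
        )
        return out

    def area(self, method: str = "analytic") -> float:
        """Integral of the band over its full support (counts * cm^-1)."""
        rho = self.rho
        if method == "analytic":
            if abs(rho - 1.0) < _GAUSS_EPS:
                return self.i_max * self.fwhm * 0.5 * np.sqrt(np.pi / _LN2)
            a = self.limit
            return float(
                self.i_max
                * (a - self.nu_m)
                * np.log(rho)
                * np.sqrt(np.pi / _LN2)
                * np.exp(np.log(rho) ** 2 / (4.0 * _LN2))
            )
        if method == "quadrature":
            # the tail decays superpolynomially: +/-50 FWHM bounds all mass
            span = 50.0 * self.fwhm
            lo, hi = self.nu_m - span, self.nu_m + span
            if abs(rho - 1.0) >= _GAUSS_EPS:
                if rho > 1.0:
                    hi = min(hi, self.limit)
                else:
                    lo = max(lo, self.limit)
            val, _ = quad(
                lambda x: float(self.evaluate(x)), lo, hi,
                points=[self.nu_min, self.nu_m, self.nu_max], limit=200,
            )
            return val
        raise ValueError(f"unknown area method {method!r}")

    def to_dict(self) -> dict:
        return {
            "i_max": self.i_max,
            "nu_m": self.nu_m,
            "nu_max": self.nu_max,
            "nu_min": self.nu_min,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LogNormalBand":
        return cls(**{k: float(d[k]) for k in ("i_max", "nu_m", "nu_max", "nu_min")})


@dataclass(frozen=True)
class TwoBandModel:
    """Two-state emission model: a short-wavelength (nonrelaxed, higher
    nu_m) band plus a long-wavelength (relaxed, lower nu_m) band."""

    band_short: LogNormalBand
    band_long: LogNormalBand

    def __post_init__(self):
        if not self.band_short.nu_m > self.band_long.nu_m:
            raise ValueError(
                f"band_short.nu_m ({self.band_short.nu_m}) must exceed "
                f"band_long.nu_m ({self.band_long.nu_m}); relabel the bands"
            )

    def evaluate(self, nu) -> np.ndarray:
        return self.band_short.evaluate(nu) + self.band_long.evaluate(nu)

    def to_dict(self) -> dict:
        return {
            "band_short": self.band_short.to_dict(),
            "band_long": self.band_long.to_dict(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TwoBandModel":
        return cls(
            band_short=LogNormalBand.from_dict(d["band_short"]),
            band_long=LogNormalBand.from_dict(d["band_long"]),
        )


def model_spectrum(
    model: TwoBandModel,
    grid_nm: np.ndarray,
    condition_kind: str = "custom",
    condition_value: float = 0.0,
    spot_id: str = "model",
) -> Spectrum:
    """Evaluate the two-band model on a wavelength grid (nm).

    Intensities are the band sums at nu = 1e7/lambda; no Jacobian factor is
    applied (the model describes measured intensities).
    """
    grid_nm = np.asarray(grid_nm, dtype=float)
    nu = 1e7 / grid_nm
    return Spectrum(
        wavelengths=grid_nm,
        intensities=model.evaluate(nu),
        condition_kind=condition_kind,
        condition_value=condition_value,
        spot_id=spot_id,
    )
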