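"""Smoothing, normalization, and replicate aggregation.

FFT low-pass smoothing and max-normalization are presentation steps; band
fitting and GP operate on raw (spot-averaged) spectra unless explicitly
configured otherwise.
"""

from __future__ import annotations

import numpy as np

from .spectra_io import Spectrum, SpectrumSet, SpectraValidationError

__all__ = ["fft_smooth", "normalize_max", "average_spots"]

#: default low-pass cutoff as a fraction of the Nyquist frequency
DEFAULT_CUTOFF_FRACTION = 0.1
#: default minimum replicate count for averaged fitting inputs
DEFAULT_MIN_SPOTS = 5


def _require_uniform_grid(spectrum: Spectrum) -> float:
    d = np.diff(spectrum.wavelengths)
    if d.size == 0:
        raise SpectraValidationError("spectrum too short")
    if not np.allclose(d, d[0], rtol=1e-6, atol=0):
        raise SpectraValidationError(
            "fft_smooth requires a uniform wavelength grid; resample the "
            "spectrum onto a uniform reference grid first"
        )
    return float(d[0])


def fft_smooth(spectrum: Spectrum, cutoff_fraction: float = DEFAULT_CUTOFF_FRACTION) -> Spectrum:
    """Low-pass FFT filter: zero frequency components above
    ``cutoff_fraction`` x Nyquist and inverse-transform.

    Requires a uniform grid of at least 8 points.  The operation is linear
    in the intensities and leaves a constant spectrum unchanged (the DC
    component always passes).
    """
    if not 0 < cutoff_fraction <= 1:
        raise ValueError(f"cutoff_fraction must be in (0, 1], got {cutoff_fraction}")
    if spectrum.n_points < 8:
        raise SpectraValidationError("fft_smooth needs at least 8 points")
    _require_uniform_grid(spectrum)
    spec = np.fft.rfft(spectrum.intensities)
    freqs = np.fft.rfftfreq(spectrum.n_points)  # cycles/sample; Nyquist = 0.5
    spec[freqs > cutoff_fraction * 0.5] = 0.0
    smoothed = np.fft.irfft(spec, n=spectrum.n_points)
    # the filter can undershoot near steep edges; clip tiny negatives
    return spectrum.with_intensities(np.clip(smoothed, 0.0, None))


def normalize_max(spectrum: Spectrum) -> Spectrum:
    """Divide intensities by their maximum so the new peak equals 1."""
    m = spectrum.intensities.max() if spectrum.n_points else 0.0
    if m <= 0:
        raise SpectraValidationError("cannot normalize an all-zero spectrum")
    return spectrum.with_intensities(spectrum.intensities / m)


def average_spots(
    spectrum_set: SpectrumSet,
    condition_value: float,
    min_spots: int = DEFAULT_MIN_SPOTS,
) -> Spectrum:
    """Unweighted pointwise mean of all spot replicates at one condition.

    The result is tagged with the condition and ``spot_id='mean'``.  Fewer
    than ``min_spots`` replicates is an error (replicate averaging is what
    stabilizes the fitting inputs).
    """
    spots = spectrum_set.select(condition_value)
    if len(spots) < min_spots:
        raise SpectraValidationError(
            f"condition {condition_value}: {len(spots)} < {min_spots} replicates"
        )
    mean = np.mean([s.intensities for s in spots], axis=0)
    ref = spots[0]
    return Spectrum(
        wavelengths=ref.wavelengths,
        intensities=mean,
        condition_kind=ref.condition_kind,
        condition_value=ref.condition_value,
        spot_id="mean",
        meta={"n_spots": len(spots)},
    )
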