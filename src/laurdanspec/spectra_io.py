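"""Spectral containers and long-format table I/O.

A :class:`Spectrum` is one steady-state emission spectrum on a strictly
increasing wavelength grid (nm) with condition and replicate ("spot")
metadata.  A :class:`SpectrumSet` is an ordered collection of spectra sharing
one grid, indexed by (condition, spot).  The canonical on-disk form is a
long-format delimited table with columns

    condition_kind, condition_value, spot, wavelength_nm, intensity

(UTF-8, '.' decimal separator; comma-delimited by default, tab via the
``dialect`` argument).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "Spectrum",
    "SpectrumSet",
    "SpectraFormatError",
    "SpectraValidationError",
    "read_spectra",
    "write_spectra",
    "to_wavenumber",
    "to_wavelength",
    "resample",
]

#: columns of the canonical long format, in order
COLUMNS = ("condition_kind", "condition_value", "spot", "wavelength_nm", "intensity")

_DELIMS = {"csv": ",", "tsv": "\t"}


class SpectraFormatError(ValueError):
    """Input table does not conform to the long spectral format."""


class SpectraValidationError(ValueError):
    """Spectral data violate an invariant (grid order, sign, duplication)."""


@dataclass(frozen=True)
class Spectrum:
    """One emission spectrum with condition/replicate metadata.

    Parameters
    ----------
    wavelengths : array
        Strictly increasing grid, all positive.  Nanometres for measured
        spectra; the same container carries a wavenumber axis (cm^-1) after
        :func:`to_wavenumber`, flagged in ``meta['axis']``.
    intensities : array
        Nonnegative emission intensities (counts, arbitrary units), same
        length as ``wavelengths``.
    condition_kind : str
        Condition axis label, e.g. ``"hydration"`` (RH in %) or
        ``"cholesterol"`` (molar fraction).
    condition_value : float
        Numeric condition value on that axis.
    spot_id : str
        Replicate identifier.
    meta : mapping
        Free-form annotations.
    """

    wavelengths: np.ndarray
    intensities: np.ndarray
    condition_kind: str = "custom"
    condition_value: float = 0.0
    spot_id: str = "spot"
    meta: Mapping = field(default_factory=dict)

    def __post_init__(self):
        wl = np.asarray(self.wavelengths, dtype=float)
        iy = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "wavelengths", wl)
        object.__setattr__(self, "intensities", iy)
        if wl.ndim != 1 or iy.shape != wl.shape:
            raise SpectraValidationError(
                f"wavelengths and intensities must be 1-D of equal length, "
                f"got {wl.shape} and {iy.shape}"
            )
        if wl.size and (np.any(wl <= 0) or np.any(np.diff(wl) <= 0)):
            raise SpectraValidationError(
                f"wavelength grid must be strictly increasing and positive "
                f"(condition={self.condition_kind}={self.condition_value}, "
                f"spot={self.spot_id})"
            )
        if np.any(iy < 0):
            j = int(np.argmax(iy < 0))
            raise SpectraValidationError(
                f"negative intensity {iy[j]} at wavelength {wl[j]} "
                f"(condition={self.condition_kind}={self.condition_value}, "
                f"spot={self.spot_id})"
            )

    @property
    def n_points(self) -> int:
        return self.wavelengths.size

    def with_intensities(self, intensities: np.ndarray) -> "Spectrum":
        """Copy of this spectrum with replaced intensities (same grid)."""
        return replace(self, intensities=np.asarray(intensities, dtype=float))

    @property
    def condition(self) -> tuple:
        return (self.condition_kind, self.condition_value)


@dataclass
class SpectrumSet:
    """Ordered collection of spectra on one shared grid.

    ``axis_kind`` names the condition axis; ``conditions`` lists its values
    in axis order (derived from members if not given).  Every
    (condition_value, spot_id) pair must be unique and every member must sit
    on the exact same wavelength grid — use :func:`resample` explicitly if
    grids differ.
    """

    spectra: list
    axis_kind: str = "custom"
    conditions: list = None

    def __post_init__(self):
        self.spectra = list(self.spectra)
        if self.spectra:
            grid = self.spectra[0].wavelengths
            for s in self.spectra:
                if s.wavelengths.shape != grid.shape or not np.array_equal(
                    s.wavelengths, grid
                ):
                    raise SpectraValidationError(
                        f"all spectra must share one wavelength grid exactly; "
                        f"spectrum (condition={s.condition_value}, spot={s.spot_id}) "
                        f"differs — resample explicitly first"
                    )
        seen = set()
        for s in self.spectra:
            key = (s.condition_value, s.spot_id)
            if key in seen:
                raise SpectraValidationError(
                    f"duplicate (condition, spot) pair {key}"
                )
            seen.add(key)
        if self.conditions is None:
            ordered = []
            for s in self.spectra:
                if s.condition_value not in ordered:
                    ordered.append(s.condition_value)
            self.conditions = ordered

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self) -> Iterator[Spectrum]:
        return iter(self.spectra)

    @property
    def grid(self) -> np.ndarray:
        if not self.spectra:
            raise SpectraValidationError("empty SpectrumSet has no grid")
        return self.spectra[0].wavelengths

    def select(self, condition_value: float) -> list:
        """All spectra (spots) measured at one condition value."""
        return [s for s in self.spectra if s.condition_value == condition_value]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.spectra:
            rows.append(
                pd.DataFrame(
                    {
                        "condition_kind": s.condition_kind,
                        "condition_value": s.condition_value,
                        "spot": s.spot_id,
                        "wavelength_nm": s.wavelengths,
                        "intensity": s.intensities,
                    }
                )
            )
        if not rows:
            return pd.DataFrame(columns=list(COLUMNS))
        return pd.concat(rows, ignore_index=True)


def read_spectra(path, dialect: str = "csv") -> SpectrumSet:
    """Read a long-format spectral table into a validated :class:`SpectrumSet`.

    Rows are grouped into spectra by (condition_value, spot); the shared-grid
    and sign invariants are enforced.  Raises :class:`SpectraFormatError` on
    missing columns, :class:`SpectraValidationError` on invalid data.
    """
    path = Path(path)
    if dialect not in _DELIMS:
        raise SpectraFormatError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = pd.read_csv(path, sep=_DELIMS[dialect])
    missing = [c for c in COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(
            f"{path}: missing required column(s) {missing}; expected {list(COLUMNS)}"
        )
    neg = df[df["intensity"] < 0]
    if len(neg):
        r = neg.iloc[0]
        raise SpectraValidationError(
            f"{path}: negative intensity {r['intensity']} at "
            f"condition={r['condition_kind']}={r['condition_value']}, "
            f"spot={r['spot']}, wavelength={r['wavelength_nm']} nm"
        )
    spectra = []
    axis_kind = "custom"
    for (cond, spot), grp in df.groupby(["condition_value", "spot"], sort=False):
        grp = grp.sort_values("wavelength_nm", kind="stable")
        kind = str(grp["condition_kind"].iloc[0])
        axis_kind = kind
        wl = grp["wavelength_nm"].to_numpy(dtype=float)
        if np.any(np.diff(wl) <= 0):
            raise SpectraValidationError(
                f"{path}: non-monotone or duplicated wavelengths within "
                f"spectrum (condition={cond}, spot={spot})"
            )
        spectra.append(
            Spectrum(
                wavelengths=wl,
                intensities=grp["intensity"].to_numpy(dtype=float),
                condition_kind=kind,
                condition_value=float(cond),
                spot_id=str(spot),
            )
        )
    return SpectrumSet(spectra, axis_kind=axis_kind)


def write_spectra(spectrum_set: SpectrumSet, path, dialect: str = "csv") -> None:
    """Write a :class:`SpectrumSet` to the canonical long format.

    Values round-trip through :func:`read_spectra` at full precision.  An
    empty set produces a header-only file.
    """
    if dialect not in _DELIMS:
        raise SpectraFormatError(f"unknown dialect {dialect!r}; use 'csv' or 'tsv'")
    df = spectrum_set.to_frame()
    # repr-precision floats so read_spectra recovers bit-identical values
    df.to_csv(path, sep=_DELIMS[dialect], index=False, float_format="%.17g")


def to_wavenumber(spectrum: Spectrum, jacobian: bool = False) -> Spectrum:
    """Convert a wavelength-axis spectrum (nm) to a wavenumber axis (cm^-1).

    nu = 1e7 / lambda; the axis is re-sorted ascending.  With ``jacobian``
    on, intensities are multiplied by lambda^2/1e7 so the integrated signal
    is conserved; off (default) intensities are carried over unchanged — the
    band model is fitted to intensities as measured.
    """
    wl = spectrum.wavelengths
    if np.any(wl <= 0):
        raise SpectraValidationError("wavelengths must be positive for conversion")
    nu = 1e7 / wl[::-1]
    iy = spectrum.intensities[::-1].copy()
    if jacobian:
        iy = iy * (wl[::-1] ** 2) / 1e7
    meta = dict(spectrum.meta)
    meta["axis"] = "wavenumber_cm1"
    return replace(spectrum, wavelengths=nu, intensities=iy, meta=meta)


def to_wavelength(spectrum: Spectrum, jacobian: bool = False) -> Spectrum:
    """Inverse of :func:`to_wavenumber` (the map nu <-> 1e7/x is an involution)."""
    nu = spectrum.wavelengths
    if np.any(nu <= 0):
        raise SpectraValidationError("wavenumbers must be positive for conversion")
    wl = 1e7 / nu[::-1]
    iy = spectrum.intensities[::-1].copy()
    if jacobian:
        iy = iy * (nu[::-1] ** 2) / 1e7
    meta = dict(spectrum.meta)
    meta["axis"] = "wavelength_nm"
    return replace(spectrum, wavelengths=wl, intensities=iy, meta=meta)


def resample(spectrum: Spectrum, reference_grid: np.ndarray) -> Spectrum:
    """Linear interpolation of a spectrum onto a reference grid.

    Provided for explicit use when grids differ; the containers never
    resample silently.  The reference grid must lie within the spectrum's
    span (no extrapolation).
    """
    ref = np.asarray(reference_grid, dtype=float)
    wl = spectrum.wavelengths
    if ref[0] < wl[0] or ref[-1] > wl[-1]:
        raise SpectraValidationError(
            f"reference grid [{ref[0]}, {ref[-1]}] extends beyond spectrum "
            f"span [{wl[0]}, {wl[-1]}]; refusing to extrapolate"
        )
    iy = np.interp(ref, wl, spectrum.intensities)
    return replace(spectrum, wavelengths=ref, intensities=iy)
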