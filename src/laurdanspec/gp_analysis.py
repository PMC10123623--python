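"""Laurdan generalized polarization (GP).

GP = (I440 - I490) / (I440 + I490), where I440 and I490 are intensities
averaged over a small window of grid samples (default five points, ~2 nm at
~0.4 nm spacing) centred on the grid point nearest 440 and 490 nm.  GP is
dimensionless, scale-invariant, and bounded in [-1, 1] for nonnegative
spectra.  It is computed on raw (unsmoothed, unnormalized) spectra;
normalization is irrelevant by scale invariance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .spectra_io import Spectrum, SpectrumSet, SpectraValidationError

__all__ = ["GPResult", "GPTrajectory", "gp", "gp_trajectory"]

DEFAULT_LAMBDA_BLUE = 440.0
DEFAULT_LAMBDA_RED = 490.0
DEFAULT_WINDOW_POINTS = 5
#: minimum replicates per condition for a trajectory point
DEFAULT_MIN_SPOTS = 10


class UndefinedGPError(ZeroDivisionError):
    """Both intensity windows are zero; GP is undefined."""


@dataclass(frozen=True)
class GPResult:
    """GP value with the window-averaged intensities that produced it."""

    gp: float
    i440: float
    i490: float
    window_points: int


def _window_mean(spectrum: Spectrum, target_nm: float, window_points: int) -> float:
    wl = spectrum.wavelengths
    center = int(np.argmin(np.abs(wl - target_nm)))
    # even windows put the extra sample on the shorter-wavelength side
    lo = center - window_points // 2
    hi = lo + window_points
    if lo < 0 or hi > wl.size:
        raise SpectraValidationError(
            f"{window_points}-point window around {target_nm} nm extends "
            f"beyond the grid [{wl[0]}, {wl[-1]}] nm"
        )
    return float(spectrum.intensities[lo:hi].mean())


def gp(
    spectrum: Spectrum,
    lambda_blue: float = DEFAULT_LAMBDA_BLUE,
    lambda_red: float = DEFAULT_LAMBDA_RED,
    window_points: int = DEFAULT_WINDOW_POINTS,
) -> GPResult:
    """Generalized polarization of one spectrum."""
    i_blue = _window_mean(spectrum, lambda_blue, window_points)
    i_red = _window_mean(spectrum, lambda_red, window_points)
    total = i_blue + i_red
    if total == 0:
        raise UndefinedGPError(
            f"GP undefined: both windows ({lambda_blue} and {lambda_red} nm) "
            f"average to zero"
        )
    return GPResult(
        gp=(i_blue - i_red) / total,
        i440=i_blue,
        i490=i_red,
        window_points=window_points,
    )


@dataclass
class GPTrajectory:
    """Per-condition GP statistics along the condition axis.

    ``table`` has one row per condition: condition, mean_gp, sd_gp, n_spots.
    Uncertainties are sample standard deviations over spot replicates
    (0 for a single replicate).
    """

    axis_kind: str
    table: pd.DataFrame

    def mean_at(self, condition_value: float) -> float:
        row = self.table[self.table["condition"] == condition_value]
        if row.empty:
            raise KeyError(f"no condition {condition_value} in trajectory")
        return float(row["mean_gp"].iloc[0])


def gp_trajectory(
    spectrum_set: SpectrumSet,
    min_spots: int = DEFAULT_MIN_SPOTS,
    lambda_blue: float = DEFAULT_LAMBDA_BLUE,
    lambda_red: float = DEFAULT_LAMBDA_RED,
    window_points: int = DEFAULT_WINDOW_POINTS,
) -> GPTrajectory:
    """Per-spot GP then mean +/- SD per condition, in axis order."""
    rows = []
    for cond in spectrum_set.conditions:
        spots = spectrum_set.select(cond)
        if len(spots) < min_spots:
            raise SpectraValidationError(
                f"condition {cond}: {len(spots)} < {min_spots} replicates for GP"
            )
        values = np.array(
            [gp(s, lambda_blue, lambda_red, window_points).gp for s in spots]
        )
        sd = float(np.std(values, ddof=1)) if values.size > 1 else 0.0
        rows.append(
            {
                "condition": cond,
                "mean_gp": float(values.mean()),
                "sd_gp": sd,
                "n_spots": values.size,
            }
        )
    return GPTrajectory(axis_kind=spectrum_set.axis_kind, table=pd.DataFrame(rows))
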