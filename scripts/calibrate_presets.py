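#!/usr/bin/env python
"""One-time derivation of the synthetic-preset calibration constants.

Solves for the band widths and the cholesterol endpoint fraction committed
in ``laurdanspec.synthetic`` (H_LONG, H_SHORT, F_CHOL_END).  Peak positions
(475/427 nm dehydration, 482/430 nm cholesterol), fraction endpoints
(0.79 bulk, 0.18 at <=20% RH) and asymmetries (1.3/1.2) are fixed inputs;
the two widths are solved so the noise-free dehydration endpoints give
GP(0% RH) = 0.62 and GP(bulk) = -0.08, and the cholesterol endpoint
fraction so GP(x_chol = 0.6) = 0.38.  Run from the repository root:

    python scripts/calibrate_presets.py
"""

import numpy as np
from scipy.optimize import brentq, fsolve

from laurdanspec.bandshape import LogNormalBand
from laurdanspec.gp_analysis import gp
from laurdanspec.spectra_io import Spectrum

GRID = np.arange(400.0, 600.0 + 1e-9, 0.4)
NU = 1e7 / GRID
RHO_LONG, RHO_SHORT = 1.3, 1.2


def mixture_gp(fraction_long, peak_long_nm, peak_short_nm, h_long, h_short):
    bl = LogNormalBand.from_shape(1.0, 1e7 / peak_long_nm, h_long, RHO_LONG)
    bs = LogNormalBand.from_shape(1.0, 1e7 / peak_short_nm, h_short, RHO_SHORT)
    iy = (fraction_long * bl.evaluate(NU) / bl.area()
          + (1 - fraction_long) * bs.evaluate(NU) / bs.area())
    return gp(Spectrum(GRID, iy)).gp


def main():
    def endpoints(widths):
        h_long, h_short = widths
        return [
            mixture_gp(0.18, 475.0, 427.0, h_long, h_short) - 0.62,  # 0% RH
            mixture_gp(0.79, 475.0, 427.0, h_long, h_short) + 0.08,  # bulk
        ]

    (h_long, h_short), info, ier, msg = fsolve(endpoints, [3400.0, 3000.0],
                                               full_output=True)
    assert ier == 1, msg
    print(f"H_LONG = {h_long:.3f}")
    print(f"H_SHORT = {h_short:.3f}")

    f_chol = brentq(
        lambda f: mixture_gp(f, 482.0, 430.0, h_long, h_short) - 0.38, 0.0, 1.0
    )
    print(f"F_CHOL_END = {f_chol:.5f}")

    print("check GP(0% RH) =", mixture_gp(0.18, 475.0, 427.0, h_long, h_short))
    print("check GP(bulk)  =", mixture_gp(0.79, 475.0, 427.0, h_long, h_short))
    print("check GP(x=0.6) =", mixture_gp(f_chol, 482.0, 430.0, h_long, h_short))


if __name__ == "__main__":
    main()
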