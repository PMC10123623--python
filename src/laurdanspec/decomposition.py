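"""Constrained two-band spectral decomposition.

Each Laurdan emission spectrum is fitted, in the wavenumber domain, to a sum
of two asymmetric log-normal bands: a short-wavelength (nonrelaxed) and a
long-wavelength (relaxed) component.  Fits are bounded least squares: peak
positions are confined to physically meaningful windows, widths to a
plausible range, and the asymmetry rho = (nu_m - nu_min)/(nu_max - nu_m) is
capped at 1.5 by construction — each band is reparameterized as
(i_max, nu_m, H, rho) with rho bounded, so no returned band can violate the
cap.  A global fit couples all conditions of a series through two shared
peak positions (one per band) while every other parameter stays
condition-specific; population fractions are band areas (computed
analytically in wavenumber space) relative to the total fitted area.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np
import pandas as pd

from .bandshape import LogNormalBand, TwoBandModel
from .spectra_io import Spectrum, SpectrumSet, to_wavenumber

__all__ = [
    "FitBounds",
    "TwoBandFit",
    "GlobalFit",
    "FitError",
    "initial_guess",
    "fit_individual",
    "fit_global",
    "population_fractions",
    "r_squared",
]

#: optimizer iteration budget (function evaluations)
MAX_NFEV = 2000
#: cost-change convergence tolerance passed to the trust-region solver
FIT_TOL = 1e-10
#: bands closer than this in nu_m (cm^-1) are flagged degenerate
DEGENERATE_SEPARATION = 200.0


class FitError(RuntimeError):
    """A fit prerequisite failed (degenerate input, failed stage)."""


@dataclass(frozen=True)
class FitBounds:
    """Parameter boxes for the constrained fit (wavenumbers in cm^-1).

    Defaults bracket all peak positions reported for Laurdan in fluid and
    dehydrated bilayers (long band 455-510 nm, short band 410-450 nm), admit
    FWHM between 800 and 4000 cm^-1, and cap the asymmetry at 1.5 with a
    lower bound of 0.5 (its reciprocal shape).
    """

    nu_m_long: tuple = (1e7 / 510.0, 1e7 / 455.0)
    nu_m_short: tuple = (1e7 / 450.0, 1e7 / 410.0)
    fwhm: tuple = (800.0, 4000.0)
    rho: tuple = (0.5, 1.5)
    i_max: tuple = (0.0, np.inf)

    def __post_init__(self):
        for name in ("nu_m_long", "nu_m_short", "fwhm", "rho", "i_max"):
            lo, hi = getattr(self, name)
            if not lo < hi:
                raise ValueError(f"bounds for {name} must satisfy lower < upper")
        if self.rho[1] > 1.5:
            raise ValueError("asymmetry cap above 1.5 exceeds the imposed constraint")

    def contains(self, model: TwoBandModel) -> bool:
        bl, bs = model.band_long, model.band_short
        return (
            self.nu_m_long[0] <= bl.nu_m <= self.nu_m_long[1]
            and self.nu_m_short[0] <= bs.nu_m <= self.nu_m_short[1]
            and all(self.fwhm[0] <= b.fwhm <= self.fwhm[1] for b in (bl, bs))
            and all(self.rho[0] <= b.rho <= self.rho[1] for b in (bl, bs))
        )


@dataclass
class TwoBandFit:
    """Result of one constrained two-band fit."""

    model: TwoBandModel
    r2: float
    residual_norm: float
    converged: bool
    within_bounds: bool
    bound_hits: list = field(default_factory=list)
    degenerate: bool = False
    fraction_long: float = 0.0
    fraction_short: float = 0.0
    n_eval: int = 0

    def __post_init__(self):
        area_long = self.model.band_long.area()
        area_short = self.model.band_short.area()
        total = area_long + area_short
        if total <= 0:
            raise FitError("zero total band area; fractions undefined")
        self.fraction_long = 100.0 * area_long / total
        self.fraction_short = 100.0 * area_short / total


@dataclass
class GlobalFit:
    """Joint fit of a condition series with shared band peak positions."""

    nu_m_long: float
    nu_m_short: float
    conditions: list
    models: dict          # condition value -> TwoBandModel (shared nu_m)
    r2: dict              # condition value -> per-condition R^2
    converged: bool
    axis_kind: str = "custom"
    individual_r2: dict = field(default_factory=dict)  # prerequisite fits

    @property
    def peak_long_nm(self) -> float:
        return 1e7 / self.nu_m_long

    @property
    def peak_short_nm(self) -> float:
        return 1e7 / self.nu_m_short

    def fractions(self) -> pd.DataFrame:
        return population_fractions(self)


def r_squared(observed: Spectrum, model: Spectrum) -> float:
    """Coefficient of determination 1 - SS_res/SS_tot on a shared grid."""
    if not np.array_equal(observed.wavelengths, model.wavelengths):
        raise ValueError("observed and model spectra must share a grid")
    obs, mod = observed.intensities, model.intensities
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0:
        raise FitError("constant observed spectrum: R^2 undefined (SS_tot = 0)")
    return 1.0 - float(np.sum((obs - mod) ** 2)) / ss_tot


def initial_guess(spectrum: Spectrum, bounds: FitBounds | None = None) -> TwoBandModel:
    """Deterministic starting model for an individual fit.

    Peak positions start at 1e7/480 and 1e7/430 cm^-1 (the canonical relaxed
    and nonrelaxed emission maxima), widths from the overall spectral width,
    asymmetries at the Gaussian value 1, and peak intensities from the data
    near each peak.  The guess always satisfies the given bounds.
    """
    bounds = bounds or FitBounds()
    wl = spectrum.wavelengths
    if wl[0] > 425.0 or wl[-1] < 500.0:
        raise FitError(
            f"spectrum [{wl[0]}, {wl[-1]}] nm does not cover both emission "
            f"peak windows (~430 and ~480 nm)"
        )
    iy = spectrum.intensities
    # overall FWHM in wavenumber from the half-maximum crossing span
    above = wl[iy >= 0.5 * iy.max()]
    width = 1e7 / above.min() - 1e7 / above.max() if above.size > 1 else 0.0
    h0 = float(np.clip(0.85 * width, bounds.fwhm[0], bounds.fwhm[1]))

    def peak_height(target_nm):
        i = int(np.argmin(np.abs(wl - target_nm)))
        return max(float(iy[i]), 1e-3 * float(iy.max()), 1e-12)

    num_long = float(np.clip(1e7 / 480.0, *bounds.nu_m_long))
    num_short = float(np.clip(1e7 / 430.0, *bounds.nu_m_short))
    rho0 = float(np.clip(1.0, *bounds.rho))
    return TwoBandModel(
        band_long=LogNormalBand.from_shape(peak_height(480.0), num_long, h0, rho0),
        band_short=LogNormalBand.from_shape(peak_height(430.0), num_short, h0, rho0),
    )


def _add_band_params(params, prefix, band, bounds, nu_window):
    params.add(f"{prefix}_imax", value=band.i_max, min=bounds.i_max[0] + 1e-12,
               max=bounds.i_max[1])
    params.add(f"{prefix}_num", value=float(np.clip(band.nu_m, *nu_window)),
               min=nu_window[0], max=nu_window[1])
    params.add(f"{prefix}_fwhm", value=float(np.clip(band.fwhm, *bounds.fwhm)),
               min=bounds.fwhm[0], max=bounds.fwhm[1])
    params.add(f"{prefix}_rho", value=float(np.clip(band.rho, *bounds.rho)),
               min=bounds.rho[0], max=bounds.rho[1])


def _band_from_params(params, prefix) -> LogNormalBand:
    # lmfit's internal bound transform can overshoot the box by ~1 ulp;
    # clamp so the asymmetry cap is a hard guarantee on returned bands
    rho = min(params[f"{prefix}_rho"].value, 1.5)
    return LogNormalBand.from_shape(
        i_max=max(params[f"{prefix}_imax"].value, 1e-300),
        nu_m=params[f"{prefix}_num"].value,
        fwhm=params[f"{prefix}_fwhm"].value,
        rho=rho,
    )


def _model_from_params(params, long_prefix="l", short_prefix="s") -> TwoBandModel:
    bl = _band_from_params(params, long_prefix)
    bs = _band_from_params(params, short_prefix)
    if bs.nu_m <= bl.nu_m:  # relabel if the optimizer swapped the bands
        bl, bs = bs, bl
    return TwoBandModel(band_long=bl, band_short=bs)


def _bound_hits(params, tol_frac=1e-4) -> list:
    hits = []
    for name, p in params.items():
        if not p.vary or not np.isfinite(p.min) or not np.isfinite(p.max):
            # one-sided box: only check the finite edge
            if p.vary and np.isfinite(p.min) and abs(p.value - p.min) < 1e-12:
                hits.append(name)
            continue
        span = p.max - p.min
        if min(p.value - p.min, p.max - p.value) < tol_frac * span:
            hits.append(name)
    return hits


# cache of candidate band matrices keyed by (bounds, wavenumber grid)
_CANDIDATE_CACHE: dict = {}
#: number of pre-search candidates refined by the local optimizer
N_STARTS = 6


def _candidate_shapes(bounds: FitBounds, nu_window, n_num=10, n_h=7, n_rho=5):
    nums = np.linspace(nu_window[0], nu_window[1], n_num)
    hs = np.linspace(bounds.fwhm[0], bounds.fwhm[1], n_h)
    rhos = np.linspace(bounds.rho[0], bounds.rho[1], n_rho)
    return [(nm, h, r) for nm in nums for h in hs for r in rhos]


def _candidate_matrix(bounds, nu_window, nu):
    key = (tuple(nu_window), tuple(bounds.fwhm), tuple(bounds.rho), nu.tobytes())
    if key not in _CANDIDATE_CACHE:
        shapes = _candidate_shapes(bounds, nu_window)
        mat = np.array(
            [LogNormalBand.from_shape(1.0, nm, h, r).evaluate(nu)
             for nm, h, r in shapes]
        )
        _CANDIDATE_CACHE[key] = (shapes, mat)
    return _CANDIDATE_CACHE[key]


def _grid_starts(nu, obs, bounds: FitBounds, k: int = N_STARTS) -> list:
    """Coarse global pre-search for starting models.

    The two-band model is linear in the peak intensities once the six shape
    parameters are fixed, so every pair of candidate shapes admits a
    closed-form optimal amplitude pair; the k pairs with the lowest residual
    seed the local optimizer.  This sidesteps the spurious local minima the
    nearly-degenerate two-band problem exhibits on a finite window.
    """
    shapes_l, L = _candidate_matrix(bounds, bounds.nu_m_long, nu)
    shapes_s, S = _candidate_matrix(bounds, bounds.nu_m_short, nu)
    ll = np.einsum("ij,ij->i", L, L)[:, None]
    ss = np.einsum("ij,ij->i", S, S)[None, :]
    lo = (L @ obs)[:, None]
    so = (S @ obs)[None, :]
    cross = L @ S.T
    oo = float(obs @ obs)
    det = ll * ss - cross**2
    bad = det <= 0
    det = np.where(bad, 1.0, det)
    a = (lo * ss - so * cross) / det
    b = (so * ll - lo * cross) / det
    # pairs where an amplitude goes negative fall back to single-band fits
    a1 = np.clip(lo / ll, 0.0, None)
    b1 = np.clip(so / ss, 0.0, None)
    invalid = bad | (a < 0) | (b < 0)
    sse = oo - 2 * a * lo - 2 * b * so + a**2 * ll + b**2 * ss + 2 * a * b * cross
    sse_single = np.minimum(
        oo - 2 * a1 * lo + a1**2 * ll, oo - 2 * b1 * so + b1**2 * ss
    )
    sse = np.where(invalid, sse_single, sse)
    floor = 1e-6 * float(obs.max())
    starts = []
    for idx in np.argsort(sse, axis=None)[:k]:
        i, j = np.unravel_index(idx, sse.shape)
        ai = float(a1[i, 0] if invalid[i, j] else a[i, j])
        bi = float(b1[0, j] if invalid[i, j] else b[i, j])
        starts.append(
            TwoBandModel(
                band_long=LogNormalBand.from_shape(max(ai, floor), *shapes_l[i]),
                band_short=LogNormalBand.from_shape(max(bi, floor), *shapes_s[j]),
            )
        )
    return starts


def _polish(nu, obs, init: TwoBandModel, bounds: FitBounds):
    params = lmfit.Parameters()
    _add_band_params(params, "l", init.band_long, bounds, bounds.nu_m_long)
    _add_band_params(params, "s", init.band_short, bounds, bounds.nu_m_short)

    def residual(p):
        return _model_from_params(p).evaluate(nu) - obs

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lmfit.minimize(
            residual, params, method="least_squares", x_scale="jac",
            max_nfev=MAX_NFEV, ftol=FIT_TOL, xtol=FIT_TOL, gtol=FIT_TOL,
        )


def fit_individual(
    spectrum: Spectrum,
    init: TwoBandModel | None = None,
    bounds: FitBounds | None = None,
    multistart: bool = True,
) -> TwoBandFit:
    """Bounded least-squares two-band fit of a single spectrum.

    The residual is the difference between model and measured intensity on
    the wavenumber axis (no Jacobian reweighting).  The local optimizer is
    seeded from a coarse shape-grid pre-search (plus the data-driven
    :func:`initial_guess`, plus ``init`` if given) and the lowest-cost
    refined solution is returned; set ``multistart=False`` to refine only
    from ``init``/``initial_guess``.  Non-convergence within the iteration
    budget is flagged on the result, never masked.
    """
    bounds = bounds or FitBounds()
    wn = to_wavenumber(spectrum)
    nu, obs = wn.wavelengths, wn.intensities
    if np.all(obs == obs[0]):
        raise FitError("degenerate (constant) spectrum cannot be fitted")

    starts = []
    if init is not None:
        starts.append(init)
    if multistart:
        try:
            starts.append(initial_guess(spectrum, bounds))
        except FitError:
            pass
        starts.extend(_grid_starts(nu, obs, bounds))
    if not starts:
        starts.append(initial_guess(spectrum, bounds))

    result = None
    for start in starts:
        candidate = _polish(nu, obs, start, bounds)
        if result is None or candidate.chisqr < result.chisqr:
            result = candidate
    model = _model_from_params(result.params)
    modeled = model.evaluate(nu)
    r2 = 1.0 - float(np.sum((obs - modeled) ** 2)) / float(
        np.sum((obs - obs.mean()) ** 2)
    )
    hits = _bound_hits(result.params)
    fit = TwoBandFit(
        model=model,
        r2=r2,
        residual_norm=float(np.linalg.norm(obs - modeled)),
        converged=bool(result.success),
        within_bounds=not hits,
        bound_hits=hits,
        degenerate=abs(model.band_short.nu_m - model.band_long.nu_m)
        < DEGENERATE_SEPARATION,
        n_eval=int(result.nfev),
    )
    if not fit.converged:
        warnings.warn(
            f"two-band fit did not converge within {MAX_NFEV} evaluations "
            f"(condition={spectrum.condition_value}, spot={spectrum.spot_id})",
            stacklevel=2,
        )
    return fit


def fit_global(
    spectrum_set: SpectrumSet,
    bounds: FitBounds | None = None,
) -> GlobalFit:
    """Joint fit of one spectrum per condition with shared peak positions.

    Individual fits are run first; their averaged parameters seed the global
    problem, in which the two nu_m values are shared across conditions and
    every other band parameter stays free per condition.  Residuals of all
    conditions are concatenated unweighted.
    """
    bounds = bounds or FitBounds()
    conditions = list(spectrum_set.conditions)
    if not conditions:
        raise FitError("empty spectrum set")
    per_cond = {}
    for cond in conditions:
        spots = spectrum_set.select(cond)
        if len(spots) != 1:
            raise FitError(
                f"global fit expects one (averaged) spectrum per condition; "
                f"condition {cond} has {len(spots)} — average spots first"
            )
        per_cond[cond] = spots[0]

    indiv, failed = {}, []
    for cond, spec in per_cond.items():
        try:
            f = fit_individual(spec, bounds=bounds)
        except FitError:
            failed.append(cond)
            continue
        if not f.converged:
            failed.append(cond)
        indiv[cond] = f
    if failed:
        raise FitError(f"individual prerequisite fits failed for conditions {failed}")

    # starting values: averaged individual-fit parameters; shared nu_m per band
    params = lmfit.Parameters()
    mean_num_long = float(np.mean([f.model.band_long.nu_m for f in indiv.values()]))
    mean_num_short = float(np.mean([f.model.band_short.nu_m for f in indiv.values()]))
    params.add("num_long", value=float(np.clip(mean_num_long, *bounds.nu_m_long)),
               min=bounds.nu_m_long[0], max=bounds.nu_m_long[1])
    params.add("num_short", value=float(np.clip(mean_num_short, *bounds.nu_m_short)),
               min=bounds.nu_m_short[0], max=bounds.nu_m_short[1])
    for i, cond in enumerate(conditions):
        for prefix, band in (
            ("l", indiv[cond].model.band_long),
            ("s", indiv[cond].model.band_short),
        ):
            params.add(f"{prefix}{i}_imax", value=band.i_max,
                       min=1e-12, max=bounds.i_max[1])
            params.add(f"{prefix}{i}_fwhm",
                       value=float(np.clip(band.fwhm, *bounds.fwhm)),
                       min=bounds.fwhm[0], max=bounds.fwhm[1])
            params.add(f"{prefix}{i}_rho",
                       value=float(np.clip(band.rho, *bounds.rho)),
                       min=bounds.rho[0], max=bounds.rho[1])

    wn = {c: to_wavenumber(per_cond[c]) for c in conditions}

    def cond_model(p, i):
        bl = LogNormalBand.from_shape(
            max(p[f"l{i}_imax"].value, 1e-300), p["num_long"].value,
            p[f"l{i}_fwhm"].value, min(p[f"l{i}_rho"].value, 1.5))
        bs = LogNormalBand.from_shape(
            max(p[f"s{i}_imax"].value, 1e-300), p["num_short"].value,
            p[f"s{i}_fwhm"].value, min(p[f"s{i}_rho"].value, 1.5))
        return TwoBandModel(band_long=bl, band_short=bs)

    def residual(p):
        return np.concatenate([
            cond_model(p, i).evaluate(wn[c].wavelengths) - wn[c].intensities
            for i, c in enumerate(conditions)
        ])

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        result = lmfit.minimize(
            residual, params, method="least_squares", x_scale="jac",
            max_nfev=10 * MAX_NFEV, ftol=FIT_TOL, xtol=FIT_TOL, gtol=FIT_TOL,
        )

    models, r2 = {}, {}
    for i, cond in enumerate(conditions):
        m = cond_model(result.params, i)
        obs = wn[cond].intensities
        mod = m.evaluate(wn[cond].wavelengths)
        models[cond] = m
        r2[cond] = 1.0 - float(np.sum((obs - mod) ** 2)) / float(
            np.sum((obs - obs.mean()) ** 2)
        )
    return GlobalFit(
        nu_m_long=float(result.params["num_long"].value),
        nu_m_short=float(result.params["num_short"].value),
        conditions=conditions,
        models=models,
        r2=r2,
        converged=bool(result.success),
        axis_kind=spectrum_set.axis_kind,
        individual_r2={c: indiv[c].r2 for c in conditions},
    )


def population_fractions(fit) -> "dict | pd.DataFrame":
    """Band-area population fractions in percent of the total fitted area.

    For a :class:`TwoBandFit`: dict with ``fraction_long``/``fraction_short``.
    For a :class:`GlobalFit`: DataFrame with one row per condition.
    Fractions are computed from analytic band areas and sum to 100 exactly.
    """
    if isinstance(fit, TwoBandFit):
        return {
            "fraction_long": fit.fraction_long,
            "fraction_short": fit.fraction_short,
        }
    if isinstance(fit, GlobalFit):
        rows = []
        for cond in fit.conditions:
            m = fit.models[cond]
            al, ash = m.band_long.area(), m.band_short.area()
            total = al + ash
            if total <= 0:
                raise FitError(f"zero total band area at condition {cond}")
            rows.append(
                {
                    "condition": cond,
                    "fraction_long": 100.0 * al / total,
                    "fraction_short": 100.0 * ash / total,
                    "r2": fit.r2[cond],
                }
            )
        return pd.DataFrame(rows)
    raise TypeError(f"expected TwoBandFit or GlobalFit, got {type(fit).__name__}")
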