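"""Stopped-flow association kinetics of FG-Nup / receptor binding.

Under pseudo-first-order conditions (receptor in large excess over the
labelled Nup) an anisotropy transient relaxes as a sum of exponentials with
observed rates k_obs,i = k_on,i * c + k_off,i.  A biexponential describes the
measured transients: a major ultrafast phase and a minor fast phase, each
with its own linear k_obs-versus-concentration law whose slope is the
association rate constant.  Endpoint anisotropies across the concentration
ladder trace the apparent binding isotherm (K_d,app), and the ionic-strength
dependence of k_on extrapolates, through a Debye-Hueckel-like screening
model, to the basal rate at infinite electrostatic shielding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np
from scipy.optimize import least_squares

from .constants import (
    ROOM_TEMPERATURE_K,
    WATER_VISCOSITY_MPAS,
    debye_kappa_nm,
    diffusion_limited_k,
    stokes_einstein_d,
    stokes_radius_nm,
)

__all__ = [
    "AnisotropyTrace",
    "BiexpFitResult",
    "RateLaw",
    "IonicSeries",
    "DebyeHuckelFit",
    "SmoluchowskiRate",
    "fit_biexp",
    "fit_kobs_line",
    "fit_endpoint_kd",
    "fit_debye_huckel",
    "smoluchowski_kon",
    "analyze_flow_campaign",
]


@dataclass
class AnisotropyTrace:
    """A stopped-flow anisotropy transient at one receptor concentration."""

    times_s: np.ndarray
    anisotropy: np.ndarray
    ntr_conc_m: float
    label: str = ""

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.anisotropy = np.asarray(self.anisotropy, dtype=float)
        if len(self.times_s) != len(self.anisotropy):
            raise ValueError("length mismatch")
        if len(self.times_s) < 50:
            raise ValueError("trace must have >= 50 points")
        if np.any(np.diff(self.times_s) <= 0):
            raise ValueError("times must be strictly increasing")


@dataclass
class BiexpFitResult:
    """Two-component description of one transient; faster phase first."""

    k_obs_ultrafast: float
    k_obs_fast: float
    amp_ultrafast: float
    amp_fast: float
    r_inf: float
    rss: float
    n_components_selected: int

    @property
    def amp_fraction_ultrafast(self) -> float:
        tot = self.amp_ultrafast + self.amp_fast
        return self.amp_ultrafast / tot if tot > 0 else np.nan


@dataclass
class RateLaw:
    """k_obs = k_on * c + intercept for one kinetic phase."""

    k_on: float
    k_on_se: float
    intercept: float
    phase: str


@dataclass
class IonicSeries:
    """Association rates measured across an ionic-strength ladder."""

    ionic_strengths_m: np.ndarray
    k_on_values: np.ndarray
    k_on_errs: np.ndarray | None = None
    ground_truth: "object | None" = None

    def __post_init__(self) -> None:
        self.ionic_strengths_m = np.asarray(self.ionic_strengths_m, dtype=float)
        self.k_on_values = np.asarray(self.k_on_values, dtype=float)
        if len(self.ionic_strengths_m) != len(self.k_on_values):
            raise ValueError("length mismatch")
        if np.any(self.ionic_strengths_m <= 0) or np.any(self.k_on_values <= 0):
            raise ValueError("ionic strengths and rates must be positive")


@dataclass
class DebyeHuckelFit:
    """Screened-electrostatics fit, ln k(I) = ln k_basal + E/(1 + kappa a)."""

    k_basal: float
    k_basal_ci: tuple[float, float]
    elec_energy_kt: float
    a_contact_nm: float


@dataclass
class SmoluchowskiRate:
    k_on: float  # M^-1 s^-1
    order_of_magnitude: int  # floor(log10 k)


def _exp_basis(t: np.ndarray, ks: np.ndarray) -> np.ndarray:
    # columns: [1, -exp(-k1 t), -exp(-k2 t), ...]
    return np.column_stack([np.ones_like(t)] + [-np.exp(-k * t) for k in ks])


def _fit_n_exp(t: np.ndarray, r: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray, float]:
    """Fit r(t) = r_inf - sum_i A_i exp(-k_i t) with n components.

    Rates are found by log-spaced grid search with variable projection
    (amplitudes solved linearly at each candidate), then refined jointly by
    Levenberg-Marquardt.  Returns (rates desc, amplitudes, rss).
    """
    span = t[-1] - t[0]
    kmin = 0.3 / span
    kmax = 2.0 / max(np.min(np.diff(t)), 1e-12)
    grid = np.geomspace(kmin, kmax, 25)

    best = None
    if n == 1:
        candidates = [(k,) for k in grid]
    else:
        candidates = [
            (k1, k2) for i, k1 in enumerate(grid) for k2 in grid[: max(i - 2, 0)]
        ]
    for ks in candidates:
        ks = np.asarray(ks, dtype=float)
        basis = _exp_basis(t, ks)
        coef, res, *_ = np.linalg.lstsq(basis, r, rcond=None)
        rss = float(res[0]) if res.size else float(np.sum((r - basis @ coef) ** 2))
        if best is None or rss < best[0]:
            best = (rss, ks, coef)

    _, ks0, coef0 = best

    def resid(theta):
        ks = np.exp(theta[:n])
        basis = _exp_basis(t, ks)
        coef, *_ = np.linalg.lstsq(basis, r, rcond=None)
        return r - basis @ coef

    sol = least_squares(resid, np.log(ks0), method="lm", xtol=1e-14, ftol=1e-14)
    ks = np.exp(sol.x)
    basis = _exp_basis(t, ks)
    coef, *_ = np.linalg.lstsq(basis, r, rcond=None)
    rss = float(np.sum((r - basis @ coef) ** 2))
    order = np.argsort(ks)[::-1]
    return ks[order], coef[1:][order], rss  # coef[0] is r_inf


def fit_biexp(trace: AnisotropyTrace, k_ratio_warn: float = 3.0) -> BiexpFitResult:
    """Fit a biexponential association transient and select the model order.

    r(t) = r_inf - A1 exp(-k1 t) - A2 exp(-k2 t); the one-component model is
    preferred when it has the lower Bayesian information criterion, in which
    case the single phase is reported in the ultrafast slot with zero minor
    amplitude.  Phases are always ordered fast-first; a rate separation below
    ``k_ratio_warn`` triggers a poorly-separated-phases warning.
    """
    t = trace.times_s
    r = trace.anisotropy
    n_pts = len(t)

    ks1, amps1, rss1 = _fit_n_exp(t, r, 1)
    ks2, amps2, rss2 = _fit_n_exp(t, r, 2)

    def bic(rss: float, n_par: int) -> float:
        return n_pts * np.log(max(rss, 1e-300) / n_pts) + n_par * np.log(n_pts)

    use_two = bic(rss2, 5) < bic(rss1, 3)
    if use_two and (np.any(amps2 < 0) or ks2[1] <= 0):
        use_two = False  # rank-deficient / unphysical second component

    if not use_two:
        basis = _exp_basis(t, ks1)
        coef, *_ = np.linalg.lstsq(basis, r, rcond=None)
        return BiexpFitResult(
            k_obs_ultrafast=float(ks1[0]),
            k_obs_fast=float(ks1[0]),
            amp_ultrafast=float(amps1[0]),
            amp_fast=0.0,
            r_inf=float(coef[0]),
            rss=rss1,
            n_components_selected=1,
        )

    if ks2[0] / ks2[1] < k_ratio_warn:
        warnings.warn("poorly separated phases (k1/k2 < 3)", stacklevel=2)
    basis = _exp_basis(t, ks2)
    coef, *_ = np.linalg.lstsq(basis, r, rcond=None)
    return BiexpFitResult(
        k_obs_ultrafast=float(ks2[0]),
        k_obs_fast=float(ks2[1]),
        amp_ultrafast=float(amps2[0]),
        amp_fast=float(amps2[1]),
        r_inf=float(coef[0]),
        rss=rss2,
        n_components_selected=2,
    )


def fit_kobs_line(kobs, concs, phase: str = "ultrafast", errs=None) -> RateLaw:
    """Weighted linear regression of observed rates on receptor concentration.

    Slope = k_on, intercept = apparent k_off (reported, not over-interpreted).
    Raises when the fitted slope is non-positive (no concentration dependence).
    """
    kobs = np.asarray(kobs, dtype=float)
    c = np.asarray(concs, dtype=float)
    if len(kobs) != len(c):
        raise ValueError("length mismatch")
    if len(c) < 4:
        raise ValueError("need >= 4 concentrations")
    w = np.ones_like(kobs) if errs is None else 1.0 / np.maximum(np.asarray(errs), 1e-300) ** 2
    sw = np.sqrt(w)
    a = np.column_stack([np.ones_like(c), c])
    coef, *_ = np.linalg.lstsq(a * sw[:, None], kobs * sw, rcond=None)
    intercept, slope = coef
    if slope <= 0:
        raise ValueError(f"no concentration dependence of k_obs ({phase} phase)")
    resid = kobs - (intercept + slope * c)
    dof = max(len(c) - 2, 1)
    cov = np.linalg.inv((a * w[:, None]).T @ a) * float(np.sum(w * resid**2) / dof)
    return RateLaw(float(slope), float(np.sqrt(cov[1, 1])), float(intercept), phase)


@dataclass
class EndpointKdFit:
    kd_app_m: float
    r_bound: float
    r_free: float
    kd_se_m: float
    ill_conditioned: bool


def fit_endpoint_kd(r_end, concs) -> EndpointKdFit:
    """Hyperbolic isotherm fit to endpoint anisotropies across the ladder.

    r_end(c) = r_free + (r_bound - r_free) c / (K_d,app + c).  Flagged
    ill-conditioned when the ladder never samples below ~3x K_d,app (the
    transition is unresolved and the Kd unbounded from below).
    """
    r_end = np.asarray(r_end, dtype=float)
    c = np.asarray(concs, dtype=float)
    if len(c) < 4:
        raise ValueError("need >= 4 concentrations")

    def model(x, kd, r_free, r_bound):
        return r_free + (r_bound - r_free) * x / (kd + x)

    m = lmfit.Model(model, independent_vars=["x"])
    params = m.make_params(
        kd=dict(value=float(np.median(c[c > 0])) if np.any(c > 0) else 1e-9, min=1e-15),
        r_free=dict(value=float(r_end.min())),
        r_bound=dict(value=float(r_end.max())),
    )
    res = m.fit(r_end, params, x=c)
    if not res.success:
        raise RuntimeError(f"endpoint fit failed: {res.message}")
    kd = float(res.params["kd"].value)
    kd_se = float(res.params["kd"].stderr or np.nan)
    ill = bool(np.min(c[c > 0]) > 3.0 * kd) if np.any(c > 0) else True
    if ill:
        warnings.warn(
            "all concentrations well above fitted K_d,app; isotherm ill-conditioned",
            stacklevel=2,
        )
    return EndpointKdFit(
        kd, float(res.params["r_bound"].value), float(res.params["r_free"].value), kd_se, ill
    )


def fit_debye_huckel(series: IonicSeries, a_contact_nm: float = 0.6) -> DebyeHuckelFit:
    """Extrapolate k_on to infinite ionic strength (basal rate).

    ln k(I) = ln k_basal + E / (1 + kappa(I) a), kappa = 3.29 sqrt(I) nm^-1.
    With ``a_contact_nm`` fixed the model is linear in (ln k_basal, E) and is
    solved by (weighted) least squares; the basal-rate confidence interval is
    the 95% normal interval on the intercept.
    """
    ii = series.ionic_strengths_m
    if len(ii) < 5 or ii.max() / ii.min() < 10.0:
        raise ValueError("need >= 5 ionic strengths spanning >= one decade")
    x = 1.0 / (1.0 + debye_kappa_nm(ii) * a_contact_nm)
    y = np.log(series.k_on_values)
    order = np.argsort(ii)
    dlnk = np.diff(y[order])
    # a screened-attraction series decreases with I; flag series that rise
    # more often than they fall, or show a jump far beyond the local scatter
    if np.sum(dlnk > 0) > len(dlnk) / 2 or (
        np.any(dlnk > 0)
        and np.max(dlnk) > 5.0 * np.median(np.abs(dlnk))
    ):
        warnings.warn("non-monotonic k_on(I) beyond noise", stacklevel=2)
    if series.k_on_errs is not None:
        w = (series.k_on_values / np.asarray(series.k_on_errs)) ** 2  # ln-space weights
    else:
        w = np.ones_like(y)
    sw = np.sqrt(w)
    a = np.column_stack([np.ones_like(x), x])
    coef, *_ = np.linalg.lstsq(a * sw[:, None], y * sw, rcond=None)
    ln_kb, energy = coef
    resid = y - a @ coef
    dof = max(len(y) - 2, 1)
    cov = np.linalg.inv((a * w[:, None]).T @ a) * float(np.sum(w * resid**2) / dof)
    se = np.sqrt(cov[0, 0])
    return DebyeHuckelFit(
        k_basal=float(np.exp(ln_kb)),
        k_basal_ci=(float(np.exp(ln_kb - 1.96 * se)), float(np.exp(ln_kb + 1.96 * se))),
        elec_energy_kt=float(energy),
        a_contact_nm=a_contact_nm,
    )


def smoluchowski_kon(
    mw_a_kda: float,
    mw_b_kda: float,
    temperature_k: float = ROOM_TEMPERATURE_K,
    viscosity_mpas: float = WATER_VISCOSITY_MPAS,
) -> SmoluchowskiRate:
    """Einstein-Smoluchowski diffusion-limited association rate.

    k = 4 pi (D_a + D_b)(R_a + R_b) N_A with Stokes-Einstein diffusion
    coefficients and hydrated Stokes radii from mass.  For two protein-sized
    partners in water the rate is a few 1e9 M^-1 s^-1, i.e. of order 1e9;
    the returned ``order_of_magnitude`` is floor(log10 k).
    """
    ra = stokes_radius_nm(mw_a_kda)
    rb = stokes_radius_nm(mw_b_kda)
    da = stokes_einstein_d(ra, temperature_k, viscosity_mpas)
    db = stokes_einstein_d(rb, temperature_k, viscosity_mpas)
    k = diffusion_limited_k(da + db, ra + rb)
    return SmoluchowskiRate(float(k), int(np.floor(np.log10(k))))


def analyze_flow_campaign(traces: list[AnisotropyTrace]) -> dict:
    """Fit every transient, regress both phases, and fit the endpoint isotherm.

    The standard two-phase pipeline: per-trace biexponential fits (fast phase
    first), k_obs-versus-concentration regressions for the ultrafast and fast
    phases independently, the mean fitted major-amplitude fraction, and the
    apparent Kd from endpoint anisotropies.
    """
    fits = [fit_biexp(tr) for tr in traces]
    concs = np.array([tr.ntr_conc_m for tr in traces])
    rate_ultra = fit_kobs_line([f.k_obs_ultrafast for f in fits], concs, "ultrafast")
    two = [f for f in fits if f.n_components_selected == 2]
    rate_fast = (
        fit_kobs_line(
            [f.k_obs_fast for f in two],
            [tr.ntr_conc_m for tr, f in zip(traces, fits) if f.n_components_selected == 2],
            "fast",
        )
        if len(two) >= 4
        else None
    )
    endpoint = fit_endpoint_kd([f.r_inf for f in fits], concs)
    frac = float(np.mean([f.amp_fraction_ultrafast for f in two])) if two else 1.0
    return {
        "fits": fits,
        "rate_ultrafast": rate_ultra,
        "rate_fast": rate_fast,
        "amp_fraction_ultrafast": frac,
        "endpoint": endpoint,
    }
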