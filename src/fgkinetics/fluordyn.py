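"""Fluorescence-correlation and FRET-line models.

Two observables establish that the FG domain keeps fluctuating rapidly when
bound: the nanosecond part of the fluorescence correlation function and the
position of (FRET efficiency, donor lifetime) populations relative to the
static FRET line.

The nanosecond FCS curve is modelled as a product of three factors,

    G(t) = (1 - alpha exp(-t/tau_alpha))
           * (1 + beta exp(-t/tau_beta))
           * (1 + gamma exp(-t/tau_gamma))

antibunching (alpha), donor-acceptor distance dynamics (beta) and triplet
blinking (gamma); all exponentials decay with lag time.  The microsecond-to-
millisecond part is fit separately with a 3-D Gaussian-focus diffusion model,
which also supplies the triplet time that is then held fixed in the
nanosecond fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import lmfit
import numpy as np

__all__ = [
    "CorrelationCurve",
    "NsfcsParams",
    "DiffusionFit",
    "nsfcs_model",
    "fcs_diffusion_model",
    "fit_nsfcs",
    "fit_fcs_diffusion",
    "static_fret_line",
    "classify_fret_points",
]


@dataclass
class NsfcsParams:
    """Three-component nanosecond-correlation model parameters.

    Amplitudes are dimensionless; times in ns.  ``alpha`` is the antibunching
    amplitude (1 = complete antibunching at zero lag), ``beta`` the
    distance-dynamics amplitude, ``gamma`` the triplet amplitude.
    """

    alpha: float
    tau_alpha_ns: float
    beta: float
    tau_beta_ns: float
    gamma: float
    tau_gamma_ns: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        for name in ("tau_alpha_ns", "tau_beta_ns", "tau_gamma_ns"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class CorrelationCurve:
    """A correlation curve G(t) over lag times in ns."""

    lags_ns: np.ndarray
    g: np.ndarray
    channel_pair: str = "parallel x perpendicular"
    ground_truth: "object | None" = None

    def __post_init__(self) -> None:
        self.lags_ns = np.asarray(self.lags_ns, dtype=float)
        self.g = np.asarray(self.g, dtype=float)
        if len(self.lags_ns) != len(self.g):
            raise ValueError("length mismatch")
        if np.any(np.diff(self.lags_ns) <= 0):
            raise ValueError("lags must be strictly increasing")
        if not np.all(np.isfinite(self.g)):
            raise ValueError("G values must be finite")


@dataclass
class FittedNsfcs(NsfcsParams):
    """Fit result: parameters plus uncertainty diagnostics."""

    tau_beta_se_ns: float = np.nan
    beta_se: float = np.nan
    dynamics_identifiable: bool = True


def nsfcs_model(t_ns, params: NsfcsParams) -> np.ndarray:
    """Evaluate the three-factor nanosecond correlation model."""
    t = np.asarray(t_ns, dtype=float)
    return (
        (1.0 - params.alpha * np.exp(-t / params.tau_alpha_ns))
        * (1.0 + params.beta * np.exp(-t / params.tau_beta_ns))
        * (1.0 + params.gamma * np.exp(-t / params.tau_gamma_ns))
    )


def fit_nsfcs(
    curve: CorrelationCurve,
    fixed_tau_gamma_ns: float | None = None,
    dead_time_ns: float = 1.0,
) -> FittedNsfcs:
    """Least-squares fit of the three-factor model to a correlation curve.

    Lags below ``dead_time_ns`` are excluded (detector dead time).  The
    triplet time can be fixed from a preceding diffusion fit, which is the
    default analysis route.  When the fitted dynamics amplitude ``beta`` is
    indistinguishable from zero the result is flagged as unidentifiable.
    """
    mask = curve.lags_ns >= dead_time_ns
    t = curve.lags_ns[mask]
    g = curve.g[mask]
    if len(t) < 8:
        raise ValueError("too few lags above dead time")

    def model(x, alpha, tau_a, beta, tau_b, gamma, tau_g):
        return nsfcs_model(x, NsfcsParams(alpha, tau_a, beta, tau_b, gamma, tau_g))

    m = lmfit.Model(model, independent_vars=["x"])
    tg0 = fixed_tau_gamma_ns if fixed_tau_gamma_ns is not None else t.max() / 5.0
    params = m.make_params(
        alpha=dict(value=0.8, min=0.0, max=1.0),
        tau_a=dict(value=max(2.0 * t.min(), 2.0), min=t.min() / 10.0),
        beta=dict(value=0.2, min=0.0),
        tau_b=dict(value=np.sqrt(t.min() * t.max()), min=t.min() / 10.0),
        gamma=dict(value=0.3, min=0.0),
        tau_g=dict(value=tg0, min=t.min() / 10.0, vary=fixed_tau_gamma_ns is None),
    )
    res = m.fit(g, params, x=t)
    if not res.success:
        raise RuntimeError(f"nsFCS fit failed: {res.message}")
    p = res.params
    beta_se = float(p["beta"].stderr or np.nan)
    identifiable = p["beta"].value > 1e-4 and (
        not np.isfinite(beta_se) or p["beta"].value > 2.0 * beta_se
    )
    if not identifiable:
        warnings.warn("dynamics amplitude beta indistinguishable from zero", stacklevel=2)
    return FittedNsfcs(
        alpha=float(p["alpha"].value),
        tau_alpha_ns=float(p["tau_a"].value),
        beta=float(p["beta"].value),
        tau_beta_ns=float(p["tau_b"].value),
        gamma=float(p["gamma"].value),
        tau_gamma_ns=float(p["tau_g"].value),
        tau_beta_se_ns=float(p["tau_b"].stderr or np.nan),
        beta_se=beta_se,
        dynamics_identifiable=identifiable,
    )


@dataclass
class DiffusionFit:
    """Single-component 3-D Gaussian-focus diffusion fit."""

    n_mol: float
    tau_d_ms: float
    aspect: float
    triplet_amp: float = 0.0
    tau_triplet_ns: float = np.nan


def fcs_diffusion_model(
    lag_ns,
    n_mol: float,
    tau_d_ms: float,
    aspect: float = 5.0,
    triplet_amp: float = 0.0,
    tau_triplet_ns: float = 1e3,
) -> np.ndarray:
    """G(t) for one diffusing species in a 3-D Gaussian focus (+ triplet)."""
    t = np.asarray(lag_ns, dtype=float) * 1e-6  # ms
    x = t / tau_d_ms
    g = 1.0 + (1.0 / n_mol) / ((1.0 + x) * np.sqrt(1.0 + x / aspect**2))
    if triplet_amp > 0:
        g = 1.0 + (g - 1.0) * (
            1.0 + triplet_amp / (1.0 - triplet_amp) * np.exp(-t * 1e6 / tau_triplet_ns)
        )
    return g


def fit_fcs_diffusion(
    curve: CorrelationCurve,
    aspect: float = 5.0,
    fit_triplet: bool = False,
) -> DiffusionFit:
    """Fit the translational diffusion model; lags must bracket tau_d.

    The amplitude G(0+) - 1 = 1/N gives the mean number of molecules in the
    focus; the axial/lateral aspect ratio is fixed (it is a calibration
    property of the instrument, not of the sample).
    """
    t = curve.lags_ns
    g = curve.g
    span = t.max() / t.min()
    if span < 1e3:
        raise ValueError("lag range must span >= 3 decades around tau_d")

    m = lmfit.Model(fcs_diffusion_model, independent_vars=["lag_ns"])
    amp0 = max(g.max() - 1.0, 1e-3)
    params = m.make_params(
        n_mol=dict(value=1.0 / amp0, min=1e-6),
        tau_d_ms=dict(value=float(np.sqrt(t.min() * t.max())) * 1e-6, min=1e-9),
        aspect=dict(value=aspect, vary=False),
        triplet_amp=dict(value=0.1 if fit_triplet else 0.0, min=0.0, max=0.99,
                         vary=fit_triplet),
        tau_triplet_ns=dict(value=2e3, min=1.0, vary=fit_triplet),
    )
    res = m.fit(g, params, lag_ns=t)
    if not res.success:
        raise RuntimeError(f"diffusion fit failed: {res.message}")
    p = res.params
    return DiffusionFit(
        n_mol=float(p["n_mol"].value),
        tau_d_ms=float(p["tau_d_ms"].value),
        aspect=aspect,
        triplet_amp=float(p["triplet_amp"].value),
        tau_triplet_ns=float(p["tau_triplet_ns"].value) if fit_triplet else np.nan,
    )


def static_fret_line(tau_da_ns, tau_d0_ns: float) -> np.ndarray:
    """FRET efficiency on the static line, E = 1 - tau_DA / tau_D0.

    Molecules with a single fixed donor-acceptor distance fall on this line
    in an (E, lifetime) histogram; systematic displacement indicates distance
    dynamics faster than the burst duration.  Lifetimes exceeding tau_D0 are
    clamped to E = 0 with a warning.
    """
    if tau_d0_ns <= 0:
        raise ValueError("tau_d0 must be positive")
    tau = np.asarray(tau_da_ns, dtype=float)
    if np.any(tau < 0):
        raise ValueError("lifetimes must be non-negative")
    if np.any(tau > tau_d0_ns):
        warnings.warn("tau_DA > tau_D0 encountered; clamping E to 0", stacklevel=2)
    return np.clip(1.0 - tau / tau_d0_ns, 0.0, 1.0)


def classify_fret_points(
    e_obs, tau_obs_ns, tau_d0_ns: float, tol: float = 0.05
) -> np.ndarray:
    """Classify (E, lifetime) points as 'static' (on-line) or 'dynamic'.

    A point is dynamic when its efficiency deviates from the static-line
    prediction at its lifetime by more than ``tol``.  Fast two-state
    interconversion shifts points off the line toward longer lifetime
    (intensity-weighted lifetime mixing versus linear efficiency averaging).
    """
    e_line = static_fret_line(tau_obs_ns, tau_d0_ns)
    dev = np.abs(np.asarray(e_obs, dtype=float) - e_line)
    return np.where(dev > tol, "dynamic", "static")
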