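"""Synthetic datasets with known ground truth for every analysis stage.

Each generator produces data with exactly the statistical structure the
corresponding analysis assumes — population-weighted fast-exchange R2
titrations, biexponential pseudo-first-order anisotropy transients,
Debye-Hueckel-screened k_on(I) series, three-factor nanosecond correlation
curves, hyperbolic chemical-shift titrations — plus declared noise, and
embeds the :class:`GroundTruth` used to make it.  Identical (parameters,
seed) regenerate identical data.

Scenario defaults are the study conditions of the system the package
models: a 250 uM PxFG-rich Nup domain titrated with Importin-beta at molar
ratios 0.17/0.33/0.72 (NMR), a 6-point 0.25-2 uM receptor ladder with
ultrafast/fast phases 1.5e9 / 6.1e7 M^-1 s^-1 split 70/30 (stopped flow),
a 9-point 0.05-1 M ionic-strength ladder extrapolating to a 2.9e8 M^-1 s^-1
basal rate, and an 89 ns FRET-dynamics correlation time (nsFCS).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .flow import AnisotropyTrace, IonicSeries
from .fluordyn import CorrelationCurve, NsfcsParams, nsfcs_model
from .nmr import RelaxationContext, ResidueTitration, ShiftTitration, bound_r2
from .constants import debye_kappa_nm

__all__ = [
    "GroundTruth",
    "gen_r2_titration",
    "gen_anisotropy_traces",
    "gen_ionic_series",
    "gen_nsfcs_curve",
    "gen_cs_titration",
    "SCENARIOS",
    "generate_scenario",
]


@dataclass(frozen=True)
class GroundTruth:
    """The parameters, seed and noise model behind a synthetic dataset."""

    scenario_name: str
    parameters: dict
    seed: int
    noise_model: str

    def to_json(self) -> str:
        def default(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=default, indent=2)


@dataclass
class R2TitrationSet:
    titrations: list[ResidueTitration]
    ground_truth: GroundTruth


@dataclass
class AnisotropySet:
    traces: list[AnisotropyTrace]
    ground_truth: GroundTruth


def gen_r2_titration(
    residue_kds_m: dict[str, float],
    ntr_concs_m,
    r2_free: float,
    relax_ctx: RelaxationContext,
    noise_sd: float,
    seed: int,
) -> R2TitrationSet:
    """Fast-exchange population-weighted R2 titrations.

    R2_obs(c) = R2_free + p_b(c) (R2_bound - R2_free), p_b = c/(Kd + c),
    with R2_bound from the rotational correlation time of the complex, plus
    additive Gaussian noise of standard deviation ``noise_sd`` (s^-1).
    The total titrant concentration is used as the free concentration
    (valid while per-site Kd >> titrant, checked elsewhere).
    """
    concs = np.asarray(ntr_concs_m, dtype=float)
    if np.any(concs < 0) or np.any(np.diff(concs) <= 0):
        raise ValueError("concentrations must be non-negative, strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    for res, kd in residue_kds_m.items():
        if not (kd > 0):  # rejects NaN too; np.inf allowed (non-binder)
            raise ValueError(f"Kd for {res} must be positive")
    rng = np.random.default_rng(seed)
    r2b = bound_r2(relax_ctx)
    tits = []
    for res, kd in residue_kds_m.items():
        pb = np.where(np.isinf(kd), 0.0, concs / (kd + concs))
        r2 = r2_free + pb * (r2b - r2_free) + rng.normal(0.0, noise_sd, size=concs.shape)
        err = np.full_like(concs, noise_sd)
        tits.append(ResidueTitration(res, concs, r2, err if noise_sd > 0 else None))
    gt = GroundTruth(
        "r2-titration",
        {
            "residue_kds_M": dict(residue_kds_m),
            "ntr_concs_M": concs,
            "r2_free_s1": r2_free,
            "r2_bound_s1": r2b,
            "bound_tauc_ns": relax_ctx.bound_tauc_ns,
            "noise_sd_s1": noise_sd,
        },
        seed,
        f"additive Gaussian, sd={noise_sd} s^-1",
    )
    return R2TitrationSet(tits, gt)


def gen_anisotropy_traces(
    rates: tuple[tuple[float, float], tuple[float, float]],
    amp_fractions: tuple[float, float],
    r_start: float,
    r_end_max: float,
    kd_app_m: float,
    ntr_concs_m,
    tgrid_s,
    noise_sd: float,
    seed: int,
) -> AnisotropySet:
    """Biexponential pseudo-first-order association transients.

    r(t) = r_inf(c) - sum_i A_i(c) exp(-k_obs,i t) with
    k_obs,i = k_on,i c + k_off,i; the total amplitude r_inf(c) - r_start is
    split by ``amp_fractions`` and the endpoint follows the hyperbolic
    isotherm toward ``r_end_max`` with midpoint ``kd_app_m`` (receptor in
    large excess over the labelled Nup).  Additive Gaussian noise.
    """
    (kon1, koff1), (kon2, koff2) = rates
    f1, f2 = amp_fractions
    if abs(f1 + f2 - 1.0) > 1e-9:
        raise ValueError("amp_fractions must sum to 1")
    t = np.asarray(tgrid_s, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("tgrid must be strictly increasing")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    traces = []
    for c in np.asarray(ntr_concs_m, dtype=float):
        r_inf = r_start + (r_end_max - r_start) * c / (kd_app_m + c)
        amp = r_inf - r_start
        k1 = kon1 * c + koff1
        k2 = kon2 * c + koff2
        r = r_inf - f1 * amp * np.exp(-k1 * t) - f2 * amp * np.exp(-k2 * t)
        r = r + rng.normal(0.0, noise_sd, size=t.shape)
        traces.append(AnisotropyTrace(t, r, float(c), label=f"c={c:.3g} M"))
    gt = GroundTruth(
        "anisotropy-traces",
        {
            "k_on_M1s1": (kon1, kon2),
            "k_off_s1": (koff1, koff2),
            "amp_fractions": (f1, f2),
            "r_start": r_start,
            "r_end_max": r_end_max,
            "kd_app_M": kd_app_m,
            "ntr_concs_M": np.asarray(ntr_concs_m, dtype=float),
            "noise_sd": noise_sd,
        },
        seed,
        f"additive Gaussian, sd={noise_sd}",
    )
    return AnisotropySet(traces, gt)


def gen_ionic_series(
    k_basal: float,
    elec_energy_kt: float,
    a_contact_nm: float,
    ionic_strengths_m,
    noise_frac: float,
    seed: int,
) -> IonicSeries:
    """Debye-Hueckel-screened association rates across an ionic ladder.

    ln k(I) = ln k_basal + E/(1 + kappa(I) a), kappa = 3.29 sqrt(I) nm^-1
    at 25 degC, with multiplicative log-normal noise of relative scale
    ``noise_frac``.
    """
    ii = np.asarray(ionic_strengths_m, dtype=float)
    if np.any(ii <= 0):
        raise ValueError("ionic strengths must be positive")
    if noise_frac < 0:
        raise ValueError("noise_frac must be non-negative")
    rng = np.random.default_rng(seed)
    ln_k = np.log(k_basal) + elec_energy_kt / (1.0 + debye_kappa_nm(ii) * a_contact_nm)
    k = np.exp(ln_k + rng.normal(0.0, noise_frac, size=ii.shape))
    errs = k * noise_frac if noise_frac > 0 else None
    gt = GroundTruth(
        "ionic-series",
        {
            "k_basal_M1s1": k_basal,
            "elec_energy_kT": elec_energy_kt,
            "a_contact_nm": a_contact_nm,
            "ionic_strengths_M": ii,
            "noise_frac": noise_frac,
        },
        seed,
        f"multiplicative log-normal, rel scale {noise_frac}",
    )
    return IonicSeries(ii, k, errs, ground_truth=gt)


def gen_nsfcs_curve(
    params: NsfcsParams,
    tgrid_ns,
    noise_sd: float,
    seed: int,
) -> CorrelationCurve:
    """Three-factor nanosecond correlation curve with additive noise.

    Evaluates (1 - a e^(-t/ta))(1 + b e^(-t/tb))(1 + g e^(-t/tg)); all
    exponentials decay with lag (correlation amplitudes relax toward
    G(inf) = 1).
    """
    t = np.asarray(tgrid_ns, dtype=float)
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    g = nsfcs_model(t, params) + rng.normal(0.0, noise_sd, size=t.shape)
    gt = GroundTruth(
        "nsfcs-curve",
        {"params": params, "noise_sd": noise_sd},
        seed,
        f"additive Gaussian, sd={noise_sd}",
    )
    return CorrelationCurve(t, g, ground_truth=gt)


def gen_cs_titration(
    kd_m: float,
    delta_max_ppm: float,
    ligand_concs_m,
    noise_sd_ppm: float,
    seed: int,
    residue_id: str = "res",
) -> tuple[ShiftTitration, GroundTruth]:
    """Hyperbolic chemical-shift titration, excess-ligand approximation."""
    if kd_m <= 0:
        raise ValueError("kd must be positive")
    if noise_sd_ppm < 0:
        raise ValueError("noise_sd must be non-negative")
    c = np.asarray(ligand_concs_m, dtype=float)
    rng = np.random.default_rng(seed)
    delta = delta_max_ppm * c / (kd_m + c) + rng.normal(0.0, noise_sd_ppm, size=c.shape)
    gt = GroundTruth(
        "cs-titration",
        {"kd_M": kd_m, "delta_max_ppm": delta_max_ppm, "ligand_concs_M": c,
         "noise_sd_ppm": noise_sd_ppm},
        seed,
        f"additive Gaussian, sd={noise_sd_ppm} ppm",
    )
    return ShiftTitration(residue_id, c, delta), gt


# --------------------------------------------------------------------------
# study-condition scenarios
# --------------------------------------------------------------------------

#: Importin-beta molar-ratio ladder over a 250 uM Nup domain
NMR_LADDER_M = np.array([0.0, 0.17, 0.33, 0.72]) * 250e-6
#: stopped-flow receptor concentration ladder (pseudo-first-order, M)
FLOW_LADDER_M = np.array([0.25, 0.5, 0.75, 1.0, 1.5, 2.0]) * 1e-6
#: log-spaced acquisition grid covering both kinetic phases (s)
FLOW_TGRID_S = np.geomspace(1e-5, 0.25, 300)
#: published two-phase rate constants (M^-1 s^-1) and amplitude split
FLOW_KON = (1.5e9, 6.1e7)
FLOW_KOFF = (100.0, 5.0)  # intercepts, not printed; fixed scenario choice
FLOW_AMP_SPLIT = (0.7, 0.3)
FLOW_R_START, FLOW_R_END = 0.18, 0.30
FLOW_KD_APP_M = 100e-9
FLOW_NOISE_SD = 0.002
#: mutant receptor: 30% reduction of both association rate constants
DA_KON_FACTOR = 0.7
#: ionic-strength ladder (M) and screened-electrostatics truth
IONIC_LADDER_M = np.array([0.05, 0.08, 0.1, 0.2, 0.3, 0.45, 0.65, 0.75, 1.0])
IONIC_K_BASAL = 2.9e8
IONIC_ELEC_ENERGY_KT = 2.9  # reproduces the ultrafast rate at I = 0.15 M
IONIC_A_CONTACT_NM = 0.6
IONIC_NOISE_FRAC = 0.1
#: nsFCS defaults: free-Nup dynamics time 89 ns; amplitudes are scenario
#: choices (not printed), triplet time from the diffusion fit
NSFCS_FREE = NsfcsParams(alpha=0.8, tau_alpha_ns=3.0, beta=0.25, tau_beta_ns=89.0,
                         gamma=0.3, tau_gamma_ns=2000.0)
NSFCS_TGRID_NS = np.geomspace(1.0, 1e4, 200)
NSFCS_NOISE_SD = 0.005
#: per-residue NMR truth: strongest site 0.8 mM in the wild-type context,
#: 7.3 mM for the same site isolated in the all-A mutant
NMR_WT_KDS = {"F1374": 0.8e-3, "F2": 2.0e-3, "F3": 4.0e-3}
NMR_AG_KDS = {"F1374": 7.3e-3}
NMR_R2_FREE = 3.0  # s^-1, typical IDP backbone at 600 MHz
NMR_NOISE_FRAC = 0.02  # 2% of R2_free


def _flow_scenario(kon_factor: float):
    def gen(seed: int, noise: float | None = None):
        kon = tuple(k * kon_factor for k in FLOW_KON)
        return gen_anisotropy_traces(
            ((kon[0], FLOW_KOFF[0]), (kon[1], FLOW_KOFF[1])),
            FLOW_AMP_SPLIT,
            FLOW_R_START,
            FLOW_R_END,
            FLOW_KD_APP_M,
            FLOW_LADDER_M,
            FLOW_TGRID_S,
            FLOW_NOISE_SD if noise is None else noise,
            seed,
        )

    return gen


def _nmr_scenario(kds: dict[str, float]):
    def gen(seed: int, noise: float | None = None):
        ctx = RelaxationContext()
        noise_sd = NMR_NOISE_FRAC * NMR_R2_FREE if noise is None else noise
        return gen_r2_titration(kds, NMR_LADDER_M, NMR_R2_FREE, ctx, noise_sd, seed)

    return gen


def _ionic_scenario(seed: int, noise: float | None = None):
    return gen_ionic_series(
        IONIC_K_BASAL,
        IONIC_ELEC_ENERGY_KT,
        IONIC_A_CONTACT_NM,
        IONIC_LADDER_M,
        IONIC_NOISE_FRAC if noise is None else noise,
        seed,
    )


def _nsfcs_scenario(seed: int, noise: float | None = None):
    return gen_nsfcs_curve(
        NSFCS_FREE, NSFCS_TGRID_NS, NSFCS_NOISE_SD if noise is None else noise, seed
    )


SCENARIOS = {
    "wt-importinb-flow": _flow_scenario(1.0),
    "da-importinb-flow": _flow_scenario(DA_KON_FACTOR),
    "wt-nmr-kd": _nmr_scenario(NMR_WT_KDS),
    "ag-mutant-nmr-kd": _nmr_scenario(NMR_AG_KDS),
    "ionic-series": _ionic_scenario,
    "nsfcs-free": _nsfcs_scenario,
}


def generate_scenario(name: str, seed: int, noise: float | None = None):
    """Generate a named study-condition scenario dataset."""
    try:
        gen = SCENARIOS[name]
    except KeyError:
        raise KeyError(f"unknown scenario {name!r}; choose from {sorted(SCENARIOS)}")
    return gen(seed, noise)


# --------------------------------------------------------------------------
# CSV export with JSON ground-truth sidecars
# --------------------------------------------------------------------------

def _write_sidecar(path: Path, gt: GroundTruth) -> None:
    path.with_suffix(path.suffix + ".json").write_text(gt.to_json())


def write_r2_titrations(dataset: R2TitrationSet, path: str | Path) -> Path:
    path = Path(path)
    rows = []
    for tit in dataset.titrations:
        err = tit.r2_err if tit.r2_err is not None else np.full_like(tit.concs_m, np.nan)
        for c, r2, e in zip(tit.concs_m, tit.r2_obs, err):
            rows.append({"residue": tit.residue_id, "conc_M": c, "R2_s1": r2, "R2_err_s1": e})
    pd.DataFrame(rows).to_csv(path, index=False)
    _write_sidecar(path, dataset.ground_truth)
    return path


def read_r2_titrations(path: str | Path) -> list[ResidueTitration]:
    df = pd.read_csv(path)
    out = []
    for res, grp in df.groupby("residue", sort=False):
        err = grp["R2_err_s1"].to_numpy()
        out.append(
            ResidueTitration(
                str(res),
                grp["conc_M"].to_numpy(),
                grp["R2_s1"].to_numpy(),
                None if np.all(np.isnan(err)) else err,
            )
        )
    return out


def write_anisotropy_traces(dataset: AnisotropySet, path: str | Path) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"time_s": tr.times_s, "anisotropy": tr.anisotropy, "conc_M": tr.ntr_conc_m}
        )
        for tr in dataset.traces
    ]
    pd.concat(frames).to_csv(path, index=False)
    _write_sidecar(path, dataset.ground_truth)
    return path


def read_anisotropy_traces(path: str | Path) -> list[AnisotropyTrace]:
    df = pd.read_csv(path)
    return [
        AnisotropyTrace(g["time_s"].to_numpy(), g["anisotropy"].to_numpy(), float(c))
        for c, g in df.groupby("conc_M", sort=True)
    ]


def write_ionic_series(series: IonicSeries, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "ionic_strength_M": series.ionic_strengths_m,
            "kon_M1s1": series.k_on_values,
            "kon_err_M1s1": series.k_on_errs
            if series.k_on_errs is not None
            else np.nan,
        }
    ).to_csv(path, index=False)
    if series.ground_truth is not None:
        _write_sidecar(path, series.ground_truth)
    return path


def read_ionic_series(path: str | Path) -> IonicSeries:
    df = pd.read_csv(path)
    errs = df["kon_err_M1s1"].to_numpy()
    return IonicSeries(
        df["ionic_strength_M"].to_numpy(),
        df["kon_M1s1"].to_numpy(),
        None if np.all(np.isnan(errs)) else errs,
    )


def write_correlation_curve(curve: CorrelationCurve, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame({"lag_ns": curve.lags_ns, "G": curve.g}).to_csv(path, index=False)
    if curve.ground_truth is not None:
        _write_sidecar(path, curve.ground_truth)
    return path


def read_correlation_curve(path: str | Path) -> CorrelationCurve:
    df = pd.read_csv(path)
    return CorrelationCurve(df["lag_ns"].to_numpy(), df["G"].to_numpy())
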