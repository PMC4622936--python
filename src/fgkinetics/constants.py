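"""Physical constants and small hydrodynamics helpers shared across modules.

All constants are SI unless a unit suffix says otherwise.  Module-level
helpers convert between the units used throughout the package: lengths in
nm, times in ns, rates in s^-1 or M^-1 s^-1, energies in units of kT.
"""

from __future__ import annotations

import numpy as np

# CODATA values
KB = 1.380649e-23  # J/K
NA = 6.02214076e23  # 1/mol
HBAR = 1.054571817e-34  # J*s
MU0 = 4.0e-7 * np.pi  # T*m/A
E_CHARGE = 1.602176634e-19  # C
EPS0 = 8.8541878128e-12  # F/m

# gyromagnetic ratios (rad s^-1 T^-1)
GAMMA_H = 2.6752218744e8
GAMMA_N = -2.7126e7  # 15N

# solvent defaults: water at 25 degC
WATER_VISCOSITY_MPAS = 0.89  # mPa*s
ROOM_TEMPERATURE_K = 298.15

# Debye screening at 25 degC in water: kappa = 3.29 * sqrt(I[M]) nm^-1
DEBYE_KAPPA_COEF = 3.29
# Bjerrum length of water at 25 degC
BJERRUM_LENGTH_NM = 0.714

# Stokes-radius-from-mass convention: R = 0.066 nm * (MW[g/mol])^(1/3),
# scaled by a hydration factor (shell of bound water).
STOKES_RADIUS_PREFACTOR_NM = 0.066
HYDRATION_FACTOR = 1.3


def stokes_radius_nm(mw_kda: float, hydration: float = HYDRATION_FACTOR) -> float:
    """Hydrodynamic radius (nm) of a globular protein of mass ``mw_kda`` kDa."""
    if mw_kda <= 0:
        raise ValueError(f"molecular weight must be positive, got {mw_kda}")
    return STOKES_RADIUS_PREFACTOR_NM * (mw_kda * 1e3) ** (1.0 / 3.0) * hydration


def stokes_einstein_d(
    radius_nm: float,
    temperature_k: float = ROOM_TEMPERATURE_K,
    viscosity_mpas: float = WATER_VISCOSITY_MPAS,
) -> float:
    """Translational diffusion coefficient (m^2/s) of a sphere."""
    if radius_nm <= 0:
        raise ValueError(f"radius must be positive, got {radius_nm}")
    return KB * temperature_k / (6.0 * np.pi * viscosity_mpas * 1e-3 * radius_nm * 1e-9)


def stokes_einstein_debye_drot(
    radius_nm: float,
    temperature_k: float = ROOM_TEMPERATURE_K,
    viscosity_mpas: float = WATER_VISCOSITY_MPAS,
) -> float:
    """Rotational diffusion coefficient (rad^2/s) of a sphere."""
    if radius_nm <= 0:
        raise ValueError(f"radius must be positive, got {radius_nm}")
    return KB * temperature_k / (
        8.0 * np.pi * viscosity_mpas * 1e-3 * (radius_nm * 1e-9) ** 3
    )


def debye_kappa_nm(ionic_strength_m) -> np.ndarray | float:
    """Inverse Debye length (nm^-1) in water at 25 degC."""
    ionic_strength_m = np.asarray(ionic_strength_m, dtype=float)
    if np.any(ionic_strength_m <= 0):
        raise ValueError("ionic strength must be positive")
    out = DEBYE_KAPPA_COEF * np.sqrt(ionic_strength_m)
    return out if out.ndim else float(out)


def diffusion_limited_k(d_total_m2s: float, contact_radius_nm: float) -> float:
    """Smoluchowski rate 4*pi*D*sigma*N_A in M^-1 s^-1."""
    return 4.0 * np.pi * d_total_m2s * contact_radius_nm * 1e-9 * NA * 1e3
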