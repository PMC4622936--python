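"""Diffusion-influenced association rates from coarse-grained Brownian dynamics.

Two rigid spheres carrying surface reactive sites (FG motifs on one side,
binding pockets on the other) diffuse translationally and rotationally under
optional short-range attraction ("apolar desolvation", a Gaussian well at
surface contact) and screened-Coulomb monopole electrostatics.  Trajectories
are launched uniformly on a sphere of radius b and terminated on reaction or
on escape past q; the Northrup-Allison-McCammon (NAM) formalism converts the
reaction fraction beta into a bimolecular rate constant,

    k = k_D(b) * beta / (1 - (1 - beta) * k_D(b) / k_D(q)),

where k_D(x) = 4 pi (D_a + D_b) x N_A is the diffusion-limited rate to a
perfectly absorbing sphere of radius x.  Reaction criteria are "n independent
site contacts within a cutoff"; a campaign is scored against many criteria
simultaneously.

Internal units: lengths nm, times ns, energies kT.  Both potentials act
between the body centers, so rotations are torque-free; the sites enter only
through the reaction criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .constants import (
    BJERRUM_LENGTH_NM,
    diffusion_limited_k,
    stokes_einstein_d,
    stokes_einstein_debye_drot,
)

__all__ = [
    "BDSystem",
    "ReactionCriterion",
    "BDOutcome",
    "propagate",
    "propagate_campaign",
    "nam_rate",
    "rate_vs_criterion",
]


def _default_sites(radius: float, n: int, patch_deg: float = 25.0) -> np.ndarray:
    """n reactive sites clustered in a surface patch around the +x axis.

    FG motifs along a chain segment (and the receptor's binding pockets) sit
    close together on the molecular surface, which is what makes multi-contact
    reaction criteria attainable; ``patch_deg`` is the angular spacing.
    """
    ang = np.deg2rad(patch_deg)
    out = [np.array([1.0, 0.0, 0.0])]
    for i in range(1, n):
        theta = 2.0 * np.pi * (i - 1) / max(n - 1, 1)
        v = np.array(
            [np.cos(ang), np.sin(ang) * np.cos(theta), np.sin(ang) * np.sin(theta)]
        )
        out.append(v)
    return radius * np.asarray(out)


def _rodrigues_apply(mats: np.ndarray, rotvecs: np.ndarray) -> np.ndarray:
    """Left-compose rotation matrices with rotations given as rotation vectors."""
    theta = np.linalg.norm(rotvecs, axis=1)
    small = theta < 1e-12
    axis = np.where(small[:, None], np.array([1.0, 0.0, 0.0]), rotvecs / np.where(
        small, 1.0, theta)[:, None])
    zeros = np.zeros_like(theta)
    k = np.stack(
        [
            np.stack([zeros, -axis[:, 2], axis[:, 1]], axis=1),
            np.stack([axis[:, 2], zeros, -axis[:, 0]], axis=1),
            np.stack([-axis[:, 1], axis[:, 0], zeros], axis=1),
        ],
        axis=1,
    )
    eye = np.eye(3)[None]
    rot = (
        eye
        + np.sin(theta)[:, None, None] * k
        + (1.0 - np.cos(theta))[:, None, None] * (k @ k)
    )
    return rot @ mats


@dataclass
class ReactionCriterion:
    """Reaction requires ``n_contacts`` independent site pairs within ``cutoff``."""

    n_contacts: int
    cutoff_nm: float

    def __post_init__(self) -> None:
        if self.n_contacts < 1:
            raise ValueError("n_contacts must be >= 1")
        if self.cutoff_nm <= 0:
            raise ValueError("cutoff must be positive")


@dataclass
class BDSystem:
    """Two diffusing rigid bodies with reactive surface sites.

    Diffusion coefficients default to Stokes-Einstein(-Debye) values for the
    given radii.  ``b_radius_nm`` (launch surface) defaults to contact + 3 nm
    and ``q_radius_nm`` (escape surface) to 4x the launch radius.
    """

    radius_a_nm: float
    radius_b_nm: float
    d_a_m2s: float | None = None
    d_b_m2s: float | None = None
    drot_a_s: float | None = None  # rad^2/s
    drot_b_s: float | None = None
    n_sites_a: int = 4
    n_sites_b: int = 2
    site_coords_a_nm: np.ndarray | None = None
    site_coords_b_nm: np.ndarray | None = None
    well_depth_kt: float = 0.0
    well_range_nm: float = 0.5
    charge_a_e: float = 0.0
    charge_b_e: float = 0.0
    debye_length_nm: float = 1.0
    b_radius_nm: float | None = None
    q_radius_nm: float | None = None

    def __post_init__(self) -> None:
        if self.radius_a_nm <= 0 or self.radius_b_nm <= 0:
            raise ValueError("radii must be positive")
        if self.d_a_m2s is None:
            self.d_a_m2s = stokes_einstein_d(self.radius_a_nm)
        if self.d_b_m2s is None:
            self.d_b_m2s = stokes_einstein_d(self.radius_b_nm)
        if self.drot_a_s is None:
            self.drot_a_s = stokes_einstein_debye_drot(self.radius_a_nm)
        if self.drot_b_s is None:
            self.drot_b_s = stokes_einstein_debye_drot(self.radius_b_nm)
        if self.site_coords_a_nm is None:
            self.site_coords_a_nm = _default_sites(self.radius_a_nm, self.n_sites_a)
        self.site_coords_a_nm = np.atleast_2d(np.asarray(self.site_coords_a_nm, float))
        if self.site_coords_b_nm is None:
            self.site_coords_b_nm = _default_sites(self.radius_b_nm, self.n_sites_b)
        self.site_coords_b_nm = np.atleast_2d(np.asarray(self.site_coords_b_nm, float))
        contact = self.contact_nm
        if self.b_radius_nm is None:
            self.b_radius_nm = contact + 3.0
        if self.q_radius_nm is None:
            self.q_radius_nm = 4.0 * self.b_radius_nm
        if not self.q_radius_nm > self.b_radius_nm > contact:
            raise ValueError("require q_radius > b_radius > radius_a + radius_b")

    @property
    def contact_nm(self) -> float:
        return self.radius_a_nm + self.radius_b_nm

    @property
    def d_rel_nm2ns(self) -> float:
        return (self.d_a_m2s + self.d_b_m2s) * 1e9  # m^2/s -> nm^2/ns


@dataclass
class BDOutcome:
    """Result of one campaign scored against a single reaction criterion."""

    n_launched: int
    n_reacted: int
    beta: float
    k_on_bd: float
    k_on_ci: tuple[float, float]
    beta_raw: float  # uncorrected reaction fraction (= beta)
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.n_reacted <= self.n_launched:
            raise ValueError("invalid counts")


def _radial_force(system: BDSystem, r: np.ndarray, use_well: bool, use_elec: bool) -> np.ndarray:
    """Radial force (kT/nm, positive = outward/repulsive) at separations r."""
    f = np.zeros_like(r)
    sigma = system.contact_nm
    if use_well and system.well_depth_kt != 0.0:
        w = system.well_range_nm
        x = (r - sigma) / w
        # U = -eps exp(-x^2); F_r = -dU/dr = -2 eps x/w exp(-x^2) (attractive)
        f -= 2.0 * system.well_depth_kt * x / w * np.exp(-np.square(x))
    if use_elec and system.charge_a_e != 0.0 and system.charge_b_e != 0.0:
        zz = system.charge_a_e * system.charge_b_e
        kappa = 1.0 / system.debye_length_nm
        # U = zz lB exp(-kappa r)/r; F_r = zz lB exp(-kappa r)(1/r^2 + kappa/r)
        f += zz * BJERRUM_LENGTH_NM * np.exp(-kappa * r) * (1.0 / r**2 + kappa / r)
    return f


def _n_independent_contacts(d: np.ndarray, cutoff: float) -> np.ndarray:
    """Number of independent site contacts per walker, d of shape (N, nA, nB).

    A contact engages one site on each body; the count is the number of
    engaged A sites or engaged B sites, whichever is smaller.
    """
    hit = d <= cutoff
    a_engaged = hit.any(axis=2).sum(axis=1)
    b_engaged = hit.any(axis=1).sum(axis=1)
    return np.minimum(a_engaged, b_engaged)


def launch_points(rng: np.random.Generator, n: int, radius_nm: float) -> np.ndarray:
    """Uniformly distributed launch positions on a sphere of given radius."""
    u = rng.normal(size=(n, 3))
    return radius_nm * u / np.linalg.norm(u, axis=1, keepdims=True)


def propagate_campaign(
    system: BDSystem,
    n_traj: int,
    seed: int,
    criteria: list[ReactionCriterion] | None = None,
    absorbing_contact: bool = False,
    use_well: bool = True,
    use_elec: bool = True,
    dt_max_ns: float | None = None,
    max_steps: int = 200_000,
    return_min_r: bool = False,
) -> np.ndarray:
    """Run ``n_traj`` NAM trajectories; returns the per-criterion hit matrix.

    Walkers start uniformly on the b sphere and terminate on escape past q
    (or, with ``absorbing_contact``, on touching the hard-core contact
    distance — the spherically symmetric oracle mode).  In criterion mode a
    trajectory is scored as reacted for a criterion if the criterion was
    satisfied at any time before escape; the hard core reflects.

    Returns a boolean array of shape (n_traj, n_criteria); in absorbing mode
    a single column (touched contact before escaping).
    """
    rng = np.random.default_rng(seed)
    sigma = system.contact_nm
    q = system.q_radius_nm
    d_rel = system.d_rel_nm2ns

    min_cutoff = min((c.cutoff_nm for c in criteria), default=system.well_range_nm) \
        if criteria else system.well_range_nm
    cap = (0.2 * max(min_cutoff, 0.05)) ** 2 / (6.0 * d_rel)
    if dt_max_ns is None:
        dt_max_ns = max((0.1 * (q - sigma)) ** 2 / (6.0 * d_rel), cap)
    elif np.sqrt(6.0 * d_rel * dt_max_ns) >= 0.2 * min_cutoff and criteria:
        raise ValueError(
            "dt too large: RMS step exceeds 0.2x the smallest contact cutoff; "
            f"use dt_max_ns <= {cap:.3g}"
        )

    # launch uniformly on the b sphere; arrays below are compacted to the
    # still-active walkers, ``idx_global`` maps back to launch order
    x = launch_points(rng, n_traj, system.b_radius_nm)
    idx_global = np.arange(n_traj)
    min_r = np.full(n_traj, np.inf)

    n_crit = len(criteria) if criteria else 1
    hits = np.zeros((n_traj, n_crit), dtype=bool)
    hits_act = np.zeros((n_traj, n_crit), dtype=bool)

    if criteria:
        rng_rot = np.random.RandomState(seed % (2**31 - 1))
        mat_a = Rotation.random(n_traj, random_state=rng_rot).as_matrix()
        mat_b = Rotation.random(n_traj, random_state=rng_rot).as_matrix()
        drot_a = system.drot_a_s * 1e-9  # rad^2/ns
        drot_b = system.drot_b_s * 1e-9
        sites_a = system.site_coords_a_nm
        sites_b = system.site_coords_b_nm
        max_cutoff = max(c.cutoff_nm for c in criteria)
        pending = np.zeros(n_traj)  # banked rotational-diffusion time (ns)

    for _ in range(max_steps):
        n_act = idx_global.size
        if n_act == 0:
            break
        r = np.linalg.norm(x, axis=1)
        gap = np.maximum(r - sigma, 0.0)
        dt = (0.15 * np.maximum(gap, 0.05)) ** 2 / (6.0 * d_rel)
        if not absorbing_contact:
            # reflecting core: only the criterion resolution limits the step
            dt = np.maximum(dt, cap)
        dt = np.minimum(dt, dt_max_ns)

        f_r = _radial_force(system, r, use_well, use_elec)
        x += (d_rel * f_r * dt / r)[:, None] * x
        x += rng.normal(size=(n_act, 3)) * np.sqrt(2.0 * d_rel * dt)[:, None]

        r_new = np.linalg.norm(x, axis=1)
        if absorbing_contact:
            reacted = r_new <= sigma
            hits_act[:n_act, 0] |= reacted
        else:
            # reflecting hard core
            inside = r_new < sigma
            if np.any(inside):
                scale = (2.0 * sigma - r_new[inside]) / r_new[inside]
                x[inside] *= scale[:, None]
                r_new[inside] = 2.0 * sigma - r_new[inside]
            reacted = np.zeros(n_act, dtype=bool)

        if return_min_r:
            np.minimum.at(min_r, idx_global, r_new)

        if criteria:
            # rotational diffusion is accumulated and applied lazily: the
            # orientation is only read when the bodies are close enough for
            # site contacts, so far from contact the elapsed rotation time is
            # banked and flushed as one update on re-entry (uniform
            # re-orientation once the accumulated spread is ~isotropic)
            pending[:n_act] += dt

            # sites sit on the surfaces, so pair distance >= r - sigma
            near = np.flatnonzero(r_new - sigma <= max_cutoff + 0.5)
            if near.size:
                for mats, drot in ((mat_a, drot_a), (mat_b, drot_b)):
                    var = 2.0 * drot * pending[near]
                    uni = var > 1.5  # rad^2 per axis: effectively isotropic
                    if np.any(uni):
                        mats[near[uni]] = Rotation.random(
                            int(uni.sum()), random_state=rng_rot
                        ).as_matrix()
                    rest = ~uni
                    if np.any(rest):
                        rv = rng.normal(size=(int(rest.sum()), 3)) * np.sqrt(
                            var[rest]
                        )[:, None]
                        mats[near[rest]] = _rodrigues_apply(mats[near[rest]], rv)
                pending[near] = 0.0
                aw = np.einsum("nij,sj->nsi", mat_a[near], sites_a)
                bw = x[near][:, None, :] + np.einsum("nij,sj->nsi", mat_b[near], sites_b)
                d = np.linalg.norm(aw[:, :, None, :] - bw[:, None, :, :], axis=3)
                for ci, crit in enumerate(criteria):
                    ncon = _n_independent_contacts(d, crit.cutoff_nm)
                    hits_act[near[ncon >= crit.n_contacts], ci] = True
            reacted = hits_act[:n_act].all(axis=1)  # nothing further to learn

        done = reacted | (r_new >= q)
        if np.any(done):
            hits[idx_global[done]] = hits_act[:n_act][done]
            keep = ~done
            idx_global = idx_global[keep]
            x = x[keep]
            hits_act = hits_act[:n_act][keep]
            if criteria:
                mat_a = mat_a[keep]
                mat_b = mat_b[keep]
                pending = pending[:n_act][keep]
    else:
        if idx_global.size:
            hits[idx_global] = hits_act[: idx_global.size]
            warnings.warn(
                f"{idx_global.size} trajectories not terminated after {max_steps} steps",
                stacklevel=2,
            )
    if return_min_r:
        return hits, min_r
    return hits


def nam_rate(beta: float, system: BDSystem) -> float:
    """Convert a reaction fraction into a bimolecular rate (M^-1 s^-1).

    k = k_D(b) beta_inf with the escape-recrossing correction
    beta_inf = beta / (1 - (1 - beta) k_D(b)/k_D(q)).
    """
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must be in [0, 1]")
    d_tot = system.d_a_m2s + system.d_b_m2s
    kd_b = diffusion_limited_k(d_tot, system.b_radius_nm)
    kd_q = diffusion_limited_k(d_tot, system.q_radius_nm)
    if beta == 1.0 and np.isclose(kd_b, kd_q):
        raise ValueError("degenerate: beta = 1 with b = q")
    beta_inf = beta / (1.0 - (1.0 - beta) * kd_b / kd_q)
    return float(kd_b * beta_inf)


def _wilson_ci(k: int, n: int, z: float = 1.96) -> tuple[float, float]:
    if n == 0:
        return (0.0, 1.0)
    p = k / n
    denom = 1.0 + z**2 / n
    center = (p + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
    return (max(center - half, 0.0), min(center + half, 1.0))


def propagate(
    system: BDSystem,
    criterion: ReactionCriterion | None = None,
    n_traj: int = 1,
    seed: int = 0,
    **kwargs,
) -> BDOutcome:
    """Run a campaign against one criterion and return the NAM rate.

    With no criterion the spherically symmetric absorbing-contact mode is
    used (every touch of the hard core reacts).
    """
    hits = propagate_campaign(
        system,
        n_traj,
        seed,
        criteria=[criterion] if criterion else None,
        absorbing_contact=criterion is None,
        **kwargs,
    )
    n_reacted = int(hits[:, 0].sum())
    beta = n_reacted / n_traj
    lo, hi = _wilson_ci(n_reacted, n_traj)
    return BDOutcome(
        n_launched=n_traj,
        n_reacted=n_reacted,
        beta=beta,
        k_on_bd=nam_rate(beta, system),
        k_on_ci=(nam_rate(lo, system), nam_rate(hi, system)),
        beta_raw=beta,
        seed=seed,
    )


def rate_vs_criterion(
    system: BDSystem,
    criteria: list[ReactionCriterion],
    n_traj: int,
    seed: int,
    **kwargs,
) -> pd.DataFrame:
    """Score one BD campaign against many (cutoff, n_contacts) criteria.

    Every trajectory runs to escape; each criterion it satisfied along the
    way counts as a reaction for that criterion.  Returns a table of
    cutoff_nm, n_contacts, beta, kon_M1s1, ci_lo, ci_hi.
    """
    if n_traj < 1000:
        raise ValueError("need >= 1000 trajectories for stable rate estimates")
    hits = propagate_campaign(system, n_traj, seed, criteria=criteria, **kwargs)
    rows = []
    for ci, crit in enumerate(criteria):
        n_reacted = int(hits[:, ci].sum())
        beta = n_reacted / n_traj
        lo, hi = _wilson_ci(n_reacted, n_traj)
        rows.append(
            {
                "cutoff_nm": crit.cutoff_nm,
                "n_contacts": crit.n_contacts,
                "beta": beta,
                "kon_M1s1": nam_rate(beta, system),
                "ci_lo": nam_rate(lo, system),
                "ci_hi": nam_rate(hi, system),
            }
        )
    return pd.DataFrame(rows)
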