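# Methods

This note documents the models implemented in `fgkinetics`, the assumptions
behind them, the defaults of the synthetic-data scenarios, and the numerical
choices that matter when reproducing or extending the analyses.

## Fast-exchange NMR titration analysis (`fgkinetics.nmr`)

**Model.** A disordered Nup residue in fast exchange between free and bound
states shows the population-weighted transverse relaxation rate

    R2_obs(c) = R2_free + p_b(c) · (R2_bound − R2_free),  p_b = c/(K_d + c).

R2_bound is computed from standard ¹⁵N dipole–dipole + CSA relaxation with
Lorentzian spectral densities J(ω) = (2/5)τ_c/(1 + (ωτ_c)²), under the
assumptions: rigid isotropic tumbling, order parameter 1, r_NH = 1.02 Å,
CSA = −160 ppm, 600 MHz ¹H frequency. The bound-state correlation time
defaults to the Stokes–Einstein–Debye estimate for a 97 kDa receptor
(τ_c = η·V_h/(k_B T) with V_h from 0.73 cm³/g specific volume + 0.32 cm³/g
hydration → 36.6 ns at 25 °C), implementing literally the assumption that a
bound residue tumbles with the receptor. All of these are fields of
`RelaxationContext` and can be overridden.

**K_d extraction.** R2_obs is regressed linearly on titrant concentration
(inverse-variance weights when errors are supplied; points with relative R2
error above 20% excluded first). To first order the slope is
(R2_bound − R2_free)/K_d. At the standard ladder (0, 42.5, 82.5, 180 µM over
a 250 µM Nup) and K_d = 0.8 mM, the isotherm reaches p_b ≈ 0.18 and the naive
inversion overestimates K_d by ~24%; `kd_from_slope` therefore optionally
root-finds the K_d whose model slope over the supplied ladder matches the
observed slope (Brent's method on log₁₀ K_d ∈ [−8, 2]), which makes
zero-noise recovery exact while reducing to the naive formula for c ≪ K_d.
A warning is raised when the implied p_b at the top of the ladder exceeds
0.3, where the free-ligand approximation (total titrant used as free
concentration) also degrades. A non-positive slope is reported as a flagged
non-binder, not an error, so per-residue scans keep running.

**CPMG forward model.** The Luz–Meiboom fast-exchange closed form
R2_eff = R2_0 + Φτ_ex[1 − 4ντ_ex·tanh(1/(4ντ_ex))] is provided as a forward
model only (no dispersion fitting); the test suite validates it against a
numerically propagated two-site Bloch–McConnell oracle to within 2% for
p_b ≤ 0.05 and τ_ex ≤ 10 µs.

## Stopped-flow kinetics (`fgkinetics.flow`)

**Model.** Under pseudo-first-order conditions (receptor in large excess over
labelled Nup) the anisotropy relaxes as
r(t) = r_∞ − A₁e^(−k₁t) − A₂e^(−k₂t), k_obs,i = k_on,i·c + k_off,i. Each
trace gets its own r_∞ (the endpoint isotherm is fit separately); the two
phases are regressed against concentration independently. Rate initialisation
uses a log-spaced grid over [0.3/span, 2/dt_min] with amplitudes solved
linearly at each candidate (variable projection), the best grid point refined
by Levenberg–Marquardt; ties break by lowest residual sum of squares. Model
order (1 vs 2 exponentials) is chosen by BIC, and a two-component solution
with negative amplitudes is demoted to one component. Phases are always
reported fast-first; a rate separation below 3× triggers a warning.

**Ionic-strength dependence.** ln k_on(I) = ln k_basal + E/(1 + κ(I)a) with
κ = 3.29√I nm⁻¹ at 25 °C. With the contact distance fixed (default
a = 0.6 nm; a three-parameter fit is ill-conditioned on a nine-point series)
the model is linear in (ln k_basal, E) and solved by weighted least squares;
the basal rate is reported with a 95% normal interval on the intercept.

**Diffusion limit.** k = 4π(D_a + D_b)(R_a + R_b)N_A with Stokes–Einstein D
and hydrated radii R = 0.066·MW^(1/3) nm × 1.3. For two protein-sized
partners in water this is ~7.5×10⁹ M⁻¹s⁻¹ regardless of size (the size
dependence cancels), i.e. of order 10⁹; `smoluchowski_kon` reports
floor(log₁₀ k) as the order of magnitude.

## Multivalent avidity and barrier transit (`fgkinetics.multivalent`)

Sites are independent and identical by default (heterogeneous per-site K_d
supported). The occupancy process is a birth–death chain on 0..n bound
motifs: birth rate (n − m)·k_on·c, death rate m·k_off. Its stationary law is
binomial(n, c/(c + K_d)); the mean first-passage time to full dissociation is
computed by the standard downward-recursion h_n = 1/(n·k_off),
h_m = (1 + λ_m h_{m+1})/μ_m. The Gillespie simulator is the exact stochastic
counterpart and is cross-checked against both closed forms in the tests.
For a bivalent system this chain gives MFPT/UT = 1.5 + r/2 (from the doubly
bound state) at rebinding/off ratio r = k_on[FG]/k_off — a ~6.5× slow-down at
r = 10, growing linearly with the rebinding strength and combinatorially with
valency.

Rebinding inside the chain uses an effective local motif concentration
(`fg_conc`); this represents the observed positive effect of neighbouring
motifs phenomenologically, not via explicit allosteric coupling.

**Creep transit model.** At the single-contact level the receptor is
translationally free a fraction f = k_off/(k_off + k_on[FG]) of the time, so
it moves with D_eff = D_free·f; the mean first-passage time across a 1-D slab
(reflecting entry face, absorbing exit face) is τ = L²/(2D_eff). With
L = 30 nm, [FG] = 50 mM, per-motif unbinding time 1 µs and per-motif
k_on = 10⁹ M⁻¹s⁻¹ (D_free for a 97 kDa receptor: 6.2×10⁻¹¹ m²/s) this gives
τ ≈ 0.37 ms — comfortably inside millisecond transport times. A mobile
fraction below 10⁻⁶ is flagged as kinetically trapped. The model ignores
partial-binding mobility ("slides while singly bound" would only shorten τ),
crowding, and any spatial structure of the barrier.

## Brownian-dynamics association rates (`fgkinetics.bd`)

Two rigid spheres with surface reactive sites diffuse (translation +
rotation, Stokes–Einstein(–Debye) defaults) between a launch surface b
(default contact + 3 nm) and an escape surface q (default 4b). The
Northrup–Allison–McCammon estimator converts the reacted fraction β into
k = k_D(b)·β∞, β∞ = β/(1 − (1 − β)k_D(b)/k_D(q)); the recrossing correction
is always applied and the raw β also reported (Wilson intervals on β
propagate to the rate).

Design choices, in decreasing order of physical commitment:

* The bodies are coarse-grained single spheres — the module's claim is the
  NAM formalism and the n-contact criterion logic, not atomistic energetics.
* "Apolar desolvation" is a Gaussian attractive well at surface contact,
  U = −ε·exp(−((r − σ)/w)²) (default range 0.5 nm); "electrostatics" is a
  screened Coulomb monopole pair U = z_a z_b l_B e^(−κr)/r. Both act between
  the body centers, so rotational motion is torque-free and the reactive
  sites enter only through the reaction criterion. Both are toggleable to
  mirror ablation comparisons.
* Default sites are clustered in a ~25° surface patch (FG motifs along a
  chain segment; adjacent binding pockets), which is what makes simultaneous
  multi-contact criteria geometrically attainable.
* An "n independent contacts within cutoff" criterion counts the engaged
  sites on each body and takes the smaller number; a campaign is scored
  against all criteria simultaneously (a trajectory reacts for a criterion if
  it satisfied it at any time before escape), so nesting relations between
  criteria hold exactly per trajectory.

**Time stepping.** The step is adaptive: RMS displacement 0.15× the gap to
contact, capped above by 0.1(q − σ) RMS and below (in reflecting mode) by the
criterion resolution bound RMS = 0.2× the smallest cutoff; a user-supplied
step violating that bound is refused. In absorbing mode the step shrinks
geometrically near the boundary (RMS = 0.15×gap, floor 0.05 nm), the standard
way to control first-passage discretisation bias; the suite verifies the
absorbing estimator against the Smoluchowski rate and, with the well, against
the Debye closed form 4πD·N_A/∫exp(U/kT)r⁻²dr to within a few percent at 10⁴
trajectories. Rotational diffusion is applied lazily: orientation is only
read when the bodies are within contact range, so rotation time is banked
during far excursions and flushed as a single Gaussian rotation-vector update
on re-entry (a uniform re-orientation once the per-axis angular variance
exceeds 1.5 rad², where the heat kernel on SO(3) is effectively isotropic).
The hard core reflects; penetration is corrected by radial mirroring.

## Fluorescence correlation and FRET-line analysis (`fgkinetics.fluordyn`)

The nanosecond correlation model is the three-factor product
G(t) = (1 − αe^(−t/τ_α))(1 + βe^(−t/τ_β))(1 + γe^(−t/τ_γ)) — antibunching,
distance dynamics, triplet — with *decaying* exponentials (correlation
amplitudes relax toward G(∞) = 1). Fits exclude lags below a 1 ns dead-time
parameter and by default fix the triplet time from a preceding diffusion fit
(3-D Gaussian focus, fixed axial/lateral aspect ratio — an instrument
calibration property, not a sample property). A dynamics amplitude within 2
standard errors of zero is flagged unidentifiable rather than reported as a
time scale.

The static FRET line is the linear convention E = 1 − τ_DA/τ_D0; no
linker-correction polynomial is applied (the tolerance band of the
static/dynamic classifier, default 0.05 in E, absorbs small convention
differences). Lifetimes above τ_D0 are clamped to E = 0 with a warning.

## Synthetic data (`fgkinetics.synthdata`)

Each generator produces exactly the functional form its analysis assumes plus
declared noise — additive Gaussian for R₂, shifts, anisotropy and G(t);
multiplicative log-normal for rate constants — and embeds a `GroundTruth`
record (parameters, seed, noise model). Identical (parameters, seed)
regenerate identical data; all randomness flows through
`numpy.random.default_rng(seed)`.

Scenario defaults are the study conditions of the modelled system:

| scenario | key truth | ladder / grid | noise |
|---|---|---|---|
| `wt-nmr-kd` | K_d = 0.8 mM (strongest motif) + 2, 4 mM | 0, 42.5, 82.5, 180 µM | 2% of R₂_free |
| `ag-mutant-nmr-kd` | K_d = 7.3 mM (isolated motif) | same | same |
| `wt-importinb-flow` | k_on = 1.5×10⁹ / 6.1×10⁷ M⁻¹s⁻¹, 70/30 split | 0.25–2 µM, 6 points, log grid 10 µs–0.25 s | 0.002 anisotropy |
| `da-importinb-flow` | both k_on × 0.7 (mutant receptor) | same | same |
| `ionic-series` | k_basal = 2.9×10⁸ M⁻¹s⁻¹, E = 2.9 kT, a = 0.6 nm | 0.05–1 M, 9 points | 10% log-normal |
| `nsfcs-free` | τ_β = 89 ns (α = 0.8, τ_α = 3 ns, β = 0.25, γ = 0.3, τ_γ = 2 µs) | 1 ns–10 µs, 200 lags | 0.005 |

Values not fixed by the modelled study (stopped-flow k_off intercepts of
100 and 5 s⁻¹, K_d,app = 100 nM, the anisotropy noise after trace averaging,
R₂_free = 3 s⁻¹, the nsFCS amplitudes, E = 2.9 kT chosen so the screened
model reproduces the ultrafast rate at physiological ionic strength) were
fixed once as realistic choices and are documented in the scenario constants.

What the generators deliberately do **not** emulate: photon statistics and
shot noise (FCS curves get additive Gaussian noise, not correlator noise),
instrument dead time and mixing artefacts in stopped flow, spectral overlap
or peak-picking errors in NMR, ligand depletion (valid because per-site K_d ≫
titrant concentrations, guarded by the p_b check), and any inter-motif
cooperativity beyond the effective rebinding concentration. Passing recovery
tests therefore demonstrates correctness of the estimators under the stated
models, not robustness to instrument systematics.

## Problem sizes

The test suite and the acceptance script run at sizes chosen to make
Monte-Carlo error comfortably smaller than the tolerances they check: 3–15
replicate seeds for the regression pipelines, 50 curves for the nsFCS median,
40–60 Gillespie runs covering thousands of excursions, and 10⁴ Brownian
trajectories for the closed-form rate comparisons (β standard error < 1%).
Larger campaigns only shrink error bars; no conclusion depends on these
sizes.

## Known limitations

* The BD module is not an atomistic rate calculator: absolute multi-contact
  rates depend on the (coarse) site geometry; only the criterion logic,
  closed-form limits, and ablation orderings are quantitative claims.
* The slope-method K_d assumes the bound-state τ_c is known; errors in τ_c
  propagate linearly into every K_d (the default is a hydrodynamic estimate,
  not a measurement).
* The endpoint K_d,app is weakly constrained when the ladder sits mostly
  above the transition (flagged ill-conditioned).
* `mfpt_all_unbound` and `gillespie` describe a well-mixed rebinding bath;
  no spatial escape competition is modelled.
* The creep transit model is a one-dimensional effective-diffusion picture;
  it brackets time scales and is not a transport-selectivity model.
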