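# fgkinetics

Quantitative analysis of ultrafast, low-affinity, multivalent binding between
intrinsically disordered FG-nucleoporins (FG-Nups) and nuclear transport
receptors (NTRs) such as Importin-β.

## The problem

The central channel of the nuclear pore complex is filled with disordered
FG-Nups at ~50 mM motif concentration, yet NTR–cargo complexes cross this
~30 nm barrier within milliseconds. Naive two-state kinetics (K_d ~ 100 nM,
k_on ~ 10⁶ M⁻¹s⁻¹ ⇒ unbinding times of seconds) cannot explain this
"transport paradox". The resolution studied here: each FG motif binds its
receptor *individually*, with millimolar affinity and near–diffusion-limited
association, so that per-motif unbinding is microsecond-fast while
polyvalency keeps the overall complex apparent affinity high.

`fgkinetics` implements the analysis pipeline by which those numbers are
established, together with a synthetic-data module that generates inputs with
exactly the statistical structure each analysis assumes (known ground truth,
declared noise), so every stage is testable end to end:

* **`fgkinetics.nmr`** — per-residue K_d from fast-exchange ¹⁵N R₂
  titrations. In fast exchange, R₂_obs(c) = R₂_free + p_b(c)(R₂_bound −
  R₂_free) with p_b = c/(K_d + c); R₂_bound follows from standard
  dipolar + CSA relaxation of a residue tumbling with the ~100 kDa complex
  (τ_c from Stokes–Einstein–Debye). Includes the Luz–Meiboom CPMG forward
  model, chemical-shift isotherm fits, and intensity-ratio broadening.
* **`fgkinetics.flow`** — stopped-flow anisotropy transients under
  pseudo-first-order conditions: biexponential fits r(t) = r_∞ − A₁e^(−k₁t) −
  A₂e^(−k₂t) with model selection, k_obs = k_on·c + k_off rate laws per phase,
  endpoint K_d,app isotherms, Debye–Hückel ionic-strength extrapolation
  ln k(I) = ln k_basal + E/(1 + κ(I)a), and the Einstein–Smoluchowski
  diffusion limit 4π(D_a + D_b)(R_a + R_b)N_A.
* **`fgkinetics.multivalent`** — avidity of N weak sites: the independent-site
  binding chain (stationary occupancy, analytic mean first-passage time to
  full dissociation, exact Gillespie simulation) and the "creep" transit
  model τ = L²/(2 D_free f_mobile) with f_mobile = k_off/(k_off + k_on[FG]).
* **`fgkinetics.bd`** — coarse-grained Brownian dynamics of two rigid bodies
  with reactive surface sites; association rates via the
  Northrup–Allison–McCammon formalism, k = k_D(b)·β/(1 − (1 − β)k_D(b)/k_D(q)),
  with n-contact reaction criteria and toggleable short-range attraction /
  screened electrostatics.
* **`fgkinetics.fluordyn`** — nanosecond FCS three-factor model
  G(t) = (1 − αe^(−t/τ_α))(1 + βe^(−t/τ_β))(1 + γe^(−t/τ_γ)), FCS diffusion
  fits, and the static FRET line E = 1 − τ_DA/τ_D0.
* **`fgkinetics.synthdata`** — generators and named study-condition scenarios
  with embedded ground truth and seed-exact reproducibility.

## Worked example

Simulate a stopped-flow campaign at the wild-type study conditions (six
Importin-β concentrations, 0.25–2 µM, two kinetic phases split 70/30), fit
every transient, regress both phases, and compare to the generating truth:

```bash
fgk run --scenario wt-importinb-flow --seed 1 --out report.json
```

prints

```
scenario=wt-importinb-flow seed=1
relative errors -> k_on_ultrafast_M1s1: 0.0276, k_on_fast_M1s1: 0.0338, amp_fraction_ultrafast: 0.00142, kd_app_M: 0.298
```

and `report.json` contains the recovered parameters: the major-phase
association rate constant 1.46×10⁹ M⁻¹s⁻¹ (truth 1.5×10⁹ — ultrafast,
i.e. at the diffusion limit for proteins of this size), the minor phase
5.9×10⁷ M⁻¹s⁻¹ (truth 6.1×10⁷), a 69.9% major-phase amplitude fraction
(truth 70%), and an apparent K_d of 130 nM from the endpoint isotherm
(truth 100 nM; endpoints constrain K_d,app only weakly at this ladder and
noise, hence the larger spread).

The same pattern works for the other scenarios (`wt-nmr-kd`,
`ag-mutant-nmr-kd`, `ionic-series`, `nsfcs-free`), and each stage is also
exposed directly (`fgk simulate`, `fgk nmr-kd`, `fgk flow-fit`,
`fgk flow-ionic`, `fgk multivalent`, `fgk transit`, `fgk bd`, `fgk nsfcs`,
`fgk fretline`). As a library:

```python
from fgkinetics import synthdata, flow

campaign = synthdata.generate_scenario("wt-importinb-flow", seed=1)
result = flow.analyze_flow_campaign(campaign.traces)
print(result["rate_ultrafast"].k_on)   # 1.46e9 M^-1 s^-1
```

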