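"""Fast-exchange relaxation analysis: rates, slopes, Kd inversion, CPMG."""

import numpy as np
import pytest
from oracles import bloch_mcconnell_r2eff

from fgkinetics import nmr, synthdata
from fgkinetics.nmr import RelaxationContext


@pytest.fixture(scope="module")
def ctx():
    return RelaxationContext()


class TestRelaxationRates:
    def test_matches_independent_spectral_density_oracle(self, ctx):
        # frozen from an independently coded dipolar+CSA calculation at
        # 600 MHz, r_NH = 1.02 A, CSA = -160 ppm, tau_c = 58 ns
        r1, r2 = nmr.relaxation_rates(ctx, 58.0)
        assert r1 == pytest.approx(0.246345347, rel=1e-6)
        assert r2 == pytest.approx(79.7359339, rel=1e-6)

    def test_vanishing_spectral_density_at_small_tauc(self, ctx):
        r1, r2 = nmr.relaxation_rates(ctx, 1e-6)
        assert 0 < r1 < 1e-3 and 0 < r2 < 1e-3

    def test_r2_monotonic_in_tauc_and_exceeds_r1(self, ctx):
        taucs = np.linspace(1.0, 100.0, 25)
        r1s, r2s = zip(*(nmr.relaxation_rates(ctx, tc) for tc in taucs))
        assert np.all(np.diff(r2s) > 0)
        assert all(r2 > r1 > 0 for r1, r2 in zip(r1s, r2s))

    def test_rejects_nonpositive_tauc(self, ctx):
        with pytest.raises(ValueError):
            nmr.relaxation_rates(ctx, 0.0)


class TestTaucFromMw:
    def test_linear_in_mass(self):
        assert nmr.tauc_from_mw(194.0) == pytest.approx(2 * nmr.tauc_from_mw(97.0))

    def test_receptor_sized_protein_is_tens_of_ns(self):
        # eta*V_h/(kB T) with v_bar + hydration = 1.05 cm^3/g gives 36.6 ns
        # for 97 kDa at 25 degC in water (hand-checked closed form)
        tauc = nmr.tauc_from_mw(97.0)
        assert tauc == pytest.approx(36.57, rel=1e-3)
        assert 10.0 < tauc < 100.0

    def test_inverse_temperature_scaling_at_fixed_viscosity(self):
        a = nmr.tauc_from_mw(97.0, temperature_k=298.15, viscosity_mpas=0.89)
        b = nmr.tauc_from_mw(97.0, temperature_k=2 * 298.15, viscosity_mpas=0.89)
        assert b == pytest.approx(a / 2)


class TestSlopeFit:
    def test_exact_on_noiseless_line(self, ctx):
        c = np.array([0.0, 42.5e-6, 82.5e-6, 180e-6])
        tit = nmr.ResidueTitration("r1", c, 3.0 + 5e3 * c)
        fit = nmr.fit_r2_slope(tit)
        assert fit.slope == pytest.approx(5e3, rel=1e-12)
        assert fit.intercept == pytest.approx(3.0, rel=1e-12)

    def test_high_error_points_excluded(self):
        c = np.array([0.0, 40e-6, 80e-6, 160e-6, 320e-6])
        r2 = 3.0 + 5e3 * c
        r2[-1] += 50.0  # grossly wrong point ...
        err = np.array([0.1, 0.1, 0.1, 0.1, 30.0])  # ... with > 20% rel error
        fit = nmr.fit_r2_slope(nmr.ResidueTitration("r", c, r2, err))
        assert fit.n_used == 4
        assert fit.slope == pytest.approx(5e3, rel=1e-9)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="3"):
            nmr.fit_r2_slope(
                nmr.ResidueTitration("r", [0.0, 1e-6], [3.0, 3.1])
            )

    def test_slope_matches_generator_truth_in_linear_regime(self, ctx):
        # c << Kd: slope -> (R2_bound - R2_free)/Kd
        kd = 20e-3
        ds = synthdata.gen_r2_titration(
            {"r": kd}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.0, 0
        )
        fit = nmr.fit_r2_slope(ds.titrations[0])
        expected = (nmr.bound_r2(ctx) - 3.0) / kd
        assert fit.slope == pytest.approx(expected, rel=0.02)


class TestKdFromSlope:
    @pytest.mark.parametrize("kd", [0.8e-3, 7.3e-3])
    def test_zero_noise_recovery_exact(self, ctx, kd):
        ds = synthdata.gen_r2_titration(
            {"r": kd}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.0, 0
        )
        est = nmr.estimate_kds(ds.titrations, ctx, r2_free=3.0)[0]
        assert est.kd_m == pytest.approx(kd, rel=1e-3)

    def test_nonpositive_slope_flagged_not_raised(self, ctx):
        est = nmr.kd_from_slope(0.0, 3.0, ctx)
        assert est.flag == "no-binding" and est.kd_m is None

    def test_noisy_recovery_median_error_bounded(self, ctx):
        # 5% noise on R2_free across the titration ladder
        errs = []
        for seed in range(200):
            ds = synthdata.gen_r2_titration(
                {"r": 2e-3}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.15, seed
            )
            est = nmr.estimate_kds(ds.titrations, ctx, r2_free=3.0)[0]
            errs.append(abs(est.kd_m - 2e-3) / 2e-3)
        assert np.median(errs) < 0.15

    def test_agrees_with_shift_isotherm_on_shared_kd(self, ctx):
        kd = 0.8e-3
        ds = synthdata.gen_r2_titration(
            {"r": kd}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.0, 0
        )
        slope_est = nmr.estimate_kds(ds.titrations, ctx, r2_free=3.0)[0]
        shift_ladder = np.array([0.33, 1.0, 2.0, 4.0]) * 250e-6
        tit, _ = synthdata.gen_cs_titration(kd, 0.2, shift_ladder, 0.0, 0)
        iso = nmr.fit_shift_isotherm(tit)
        assert slope_est.kd_m == pytest.approx(iso.kd_m, rel=0.10)


class TestShiftIsotherm:
    def test_noiseless_exact_recovery(self):
        tit, _ = synthdata.gen_cs_titration(
            1e-3, 0.2, np.array([0.33, 1.0, 2.0, 4.0]) * 250e-6, 0.0, 0
        )
        fit = nmr.fit_shift_isotherm(tit)
        assert fit.kd_m == pytest.approx(1e-3, rel=1e-6)
        assert fit.delta_max_ppm == pytest.approx(0.2, rel=1e-6)

    def test_data_below_half_saturation_flagged(self):
        tit, _ = synthdata.gen_cs_titration(
            10e-3, 0.2, np.array([1e-5, 3e-5, 1e-4]), 0.0, 0
        )
        with pytest.warns(UserWarning, match="half-saturation"):
            fit = nmr.fit_shift_isotherm(tit)
        assert fit.ill_conditioned

    def test_recovery_unbiased_over_replicates(self):
        # ladder spanning sub- and supra-Kd concentrations (well conditioned)
        ladder = np.array([1e-4, 3e-4, 1e-3, 3e-3, 1e-2])
        kds = []
        for seed in range(100):
            tit, _ = synthdata.gen_cs_titration(1e-3, 0.2, ladder, 0.01, seed)
            kds.append(nmr.fit_shift_isotherm(tit).kd_m)
        assert abs(np.mean(kds) - 1e-3) / 1e-3 < 0.05


class TestLuzMeiboom:
    def test_refocused_limit_returns_baseline(self):
        assert nmr.luz_meiboom_r2eff(10.0, 4e7, 1e-6, 1e9) == pytest.approx(10.0, abs=1e-3)

    def test_no_exchange_contribution_is_flat(self):
        nu = np.array([25.0, 100.0, 1000.0])
        out = nmr.luz_meiboom_r2eff(10.0, 0.0, 1e-6, nu)
        assert np.allclose(out, 10.0)

    @pytest.mark.parametrize("nu", [25.0, 100.0, 500.0, 1000.0])
    def test_matches_bloch_mcconnell_within_2pct(self, nu):
        pb, tau_ex, phi = 0.02, 1e-6, 4e7
        dw = np.sqrt(phi / (pb * (1 - pb)))
        lm = nmr.luz_meiboom_r2eff(10.0, phi, tau_ex, nu)
        bm = bloch_mcconnell_r2eff(10.0, pb, dw, 1.0 / tau_ex, nu)
        assert lm == pytest.approx(bm, rel=0.02)


class TestBroadeningRatio:
    def test_no_broadening_gives_unity(self):
        assert nmr.broadening_ratio(3.0, 3.0, 0.05) == 1.0

    def test_half_intensity_at_ln2_over_tacq(self):
        tacq = 0.05
        assert nmr.broadening_ratio(3.0, 3.0 + np.log(2) / tacq, tacq) == pytest.approx(0.5)

    def test_narrowing_flagged(self):
        with pytest.warns(UserWarning, match="narrowing"):
            ratio = nmr.broadening_ratio(5.0, 3.0, 0.05)
        assert ratio > 1.0

    def test_profile_dips_only_at_binding_sites(self, ctx):
        # residues with FG-localized Kd (finite) vs non-binders (infinite Kd)
        kds = {"G1": np.inf, "F2": 1e-3, "G3": np.inf, "F4": 2e-3}
        ds = synthdata.gen_r2_titration(
            kds, synthdata.NMR_LADDER_M, 3.0, ctx, 0.0, 0
        )
        ratios = {
            t.residue_id: nmr.broadening_ratio(3.0, t.r2_obs[-1], 0.05)
            for t in ds.titrations
        }
        assert ratios["G1"] == pytest.approx(1.0) and ratios["G3"] == pytest.approx(1.0)
        assert ratios["F2"] < 1.0 and ratios["F4"] < 1.0
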