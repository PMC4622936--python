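"""Generator contracts: determinism, ground-truth embedding, physical ranges."""

import json

import numpy as np
import pytest

from fgkinetics import synthdata
from fgkinetics.fluordyn import NsfcsParams
from fgkinetics.nmr import RelaxationContext


@pytest.fixture(scope="module")
def ctx():
    return RelaxationContext()


class TestReproducibility:
    @pytest.mark.parametrize("scenario", sorted(synthdata.SCENARIOS))
    def test_identical_seed_regenerates_identical_data(self, scenario):
        a = synthdata.generate_scenario(scenario, seed=42)
        b = synthdata.generate_scenario(scenario, seed=42)
        c = synthdata.generate_scenario(scenario, seed=43)

        def arrays(obj):
            if hasattr(obj, "titrations"):
                return np.concatenate([t.r2_obs for t in obj.titrations])
            if hasattr(obj, "traces"):
                return np.concatenate([t.anisotropy for t in obj.traces])
            if hasattr(obj, "k_on_values"):
                return obj.k_on_values
            return obj.g

        assert np.array_equal(arrays(a), arrays(b))
        assert not np.array_equal(arrays(a), arrays(c))

    def test_unknown_scenario_rejected(self):
        with pytest.raises(KeyError, match="unknown scenario"):
            synthdata.generate_scenario("nope", 0)


class TestR2TitrationGenerator:
    def test_no_binding_limit_is_flat(self, ctx):
        ds = synthdata.gen_r2_titration(
            {"r": np.inf}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.0, 0
        )
        assert np.allclose(ds.titrations[0].r2_obs, 3.0)

    def test_half_saturation_midpoint(self, ctx):
        ds = synthdata.gen_r2_titration({"r": 1e-3}, [0.0, 5e-4, 1e-3], 3.0, ctx, 0.0, 0)
        from fgkinetics.nmr import bound_r2

        mid = 0.5 * (3.0 + bound_r2(ctx))
        assert ds.titrations[0].r2_obs[-1] == pytest.approx(mid)

    def test_weak_binding_ladder_nearly_linear_and_increasing(self, ctx):
        # c << Kd at the standard ladder: monotone, curvature bounded
        ds = synthdata.gen_r2_titration(
            {"r": 0.8e-3}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.0, 0
        )
        r2 = ds.titrations[0].r2_obs
        c = ds.titrations[0].concs_m
        assert np.all(np.diff(r2) > 0)
        lin = r2[0] + (r2[-1] - r2[0]) * c / c[-1]
        dev = np.abs(r2 - lin) / (r2[-1] - r2[0])
        assert np.max(dev) < 0.2

    def test_positive_rates_and_embedded_truth(self, ctx):
        ds = synthdata.gen_r2_titration(
            {"r": 1e-3}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.06, 5
        )
        assert np.all(ds.titrations[0].r2_obs > 0)
        assert ds.ground_truth.seed == 5
        assert ds.ground_truth.parameters["residue_kds_M"]["r"] == 1e-3

    def test_invalid_parameters_rejected(self, ctx):
        with pytest.raises(ValueError):
            synthdata.gen_r2_titration({"r": -1.0}, [0.0, 1e-6], 3.0, ctx, 0.0, 0)
        with pytest.raises(ValueError):
            synthdata.gen_r2_titration({"r": 1e-3}, [0.0, 1e-6], 3.0, ctx, -0.1, 0)


class TestAnisotropyGenerator:
    def test_fractions_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sum to 1"):
            synthdata.gen_anisotropy_traces(
                ((1e9, 100.0), (6e7, 5.0)), (0.6, 0.3), 0.18, 0.30, 1e-7,
                [1e-6], np.linspace(1e-5, 0.1, 60), 0.0, 0,
            )

    def test_zero_koff_trace_is_pure_association(self):
        c = 1e-6
        ds = synthdata.gen_anisotropy_traces(
            ((1e9, 0.0), (6e7, 0.0)), (0.7, 0.3), 0.18, 0.30, 1e-7,
            [c], np.geomspace(1e-6, 0.1, 80), 0.0, 0,
        )
        tr = ds.traces[0]
        r_inf = 0.18 + (0.30 - 0.18) * c / (1e-7 + c)
        amp = r_inf - 0.18
        expected = r_inf - 0.7 * amp * np.exp(-1e9 * c * tr.times_s) \
            - 0.3 * amp * np.exp(-6e7 * c * tr.times_s)
        assert np.allclose(tr.anisotropy, expected)

    def test_anisotropy_within_physical_bounds(self):
        ds = synthdata.generate_scenario("wt-importinb-flow", 0, noise=0.0)
        for tr in ds.traces:
            assert np.all(tr.anisotropy >= 0.18 - 1e-12)
            assert np.all(tr.anisotropy <= 0.30 + 1e-12)


class TestIonicSeriesGenerator:
    def test_no_steering_gives_flat_series(self):
        s = synthdata.gen_ionic_series(2.9e8, 0.0, 0.6, synthdata.IONIC_LADDER_M, 0.0, 0)
        assert np.allclose(s.k_on_values, 2.9e8)

    def test_infinite_shielding_limit_is_basal(self):
        s = synthdata.gen_ionic_series(2.9e8, 2.9, 0.6, [1e8], 0.0, 0)
        assert s.k_on_values[0] == pytest.approx(2.9e8, rel=1e-3)

    def test_monotonically_decreasing_for_attractive_steering(self):
        s = synthdata.gen_ionic_series(
            synthdata.IONIC_K_BASAL, synthdata.IONIC_ELEC_ENERGY_KT,
            synthdata.IONIC_A_CONTACT_NM, synthdata.IONIC_LADDER_M, 0.0, 0,
        )
        assert np.all(np.diff(s.k_on_values) < 0)
        # scenario truth reproduces the ultrafast rate near physiological I
        k_at_015 = np.interp(0.15, s.ionic_strengths_m, s.k_on_values)
        assert k_at_015 == pytest.approx(1.5e9, rel=0.1)

    def test_nonpositive_ionic_strength_rejected(self):
        with pytest.raises(ValueError):
            synthdata.gen_ionic_series(1e8, 1.0, 0.6, [0.0, 0.1], 0.0, 0)


class TestNsfcsGenerator:
    def test_complete_antibunching_at_zero_lag(self):
        p = NsfcsParams(1.0, 3.0, 0.0, 89.0, 0.0, 2000.0)
        c = synthdata.gen_nsfcs_curve(p, np.array([1e-9, 1.0, 10.0]), 0.0, 0)
        assert c.g[0] == pytest.approx(0.0, abs=1e-6)

    def test_reduces_to_antibunching_factor_when_beta_gamma_zero(self):
        t = np.geomspace(1.0, 1e4, 50)
        p = NsfcsParams(0.8, 3.0, 0.0, 89.0, 0.0, 2000.0)
        c = synthdata.gen_nsfcs_curve(p, t, 0.0, 0)
        assert np.allclose(c.g, 1.0 - 0.8 * np.exp(-t / 3.0))

    def test_curve_nonnegative_and_normalized_at_long_lag(self):
        c = synthdata.generate_scenario("nsfcs-free", 1, noise=0.0)
        assert np.all(c.g >= 0.0)
        long = synthdata.gen_nsfcs_curve(
            synthdata.NSFCS_FREE, np.geomspace(1.0, 1e6, 60), 0.0, 0
        )
        assert long.g[-1] == pytest.approx(1.0, abs=1e-9)

    def test_negative_time_constant_rejected(self):
        with pytest.raises(ValueError):
            NsfcsParams(0.8, -3.0, 0.2, 89.0, 0.3, 2000.0)


class TestCsvRoundTrips:
    def test_r2_titrations(self, ctx, tmp_path):
        ds = synthdata.gen_r2_titration(
            {"a": 1e-3, "b": 2e-3}, synthdata.NMR_LADDER_M, 3.0, ctx, 0.06, 3
        )
        p = synthdata.write_r2_titrations(ds, tmp_path / "tit.csv")
        back = synthdata.read_r2_titrations(p)
        assert [t.residue_id for t in back] == ["a", "b"]
        assert np.allclose(back[0].r2_obs, ds.titrations[0].r2_obs)
        sidecar = json.loads(p.with_suffix(".csv.json").read_text())
        assert sidecar["seed"] == 3

    def test_anisotropy_traces(self, tmp_path):
        ds = synthdata.generate_scenario("wt-importinb-flow", 2)
        p = synthdata.write_anisotropy_traces(ds, tmp_path / "traces.csv")
        back = synthdata.read_anisotropy_traces(p)
        assert len(back) == len(ds.traces)
        assert np.allclose(
            sorted(t.ntr_conc_m for t in back),
            sorted(t.ntr_conc_m for t in ds.traces),
        )

    def test_ionic_series(self, tmp_path):
        s = synthdata.generate_scenario("ionic-series", 4)
        p = synthdata.write_ionic_series(s, tmp_path / "ionic.csv")
        back = synthdata.read_ionic_series(p)
        assert np.allclose(back.k_on_values, s.k_on_values)

    def test_correlation_curve(self, tmp_path):
        c = synthdata.generate_scenario("nsfcs-free", 6)
        p = synthdata.write_correlation_curve(c, tmp_path / "curve.csv")
        back = synthdata.read_correlation_curve(p)
        assert np.allclose(back.g, c.g)
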