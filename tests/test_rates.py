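"""Rate equations, blank correction, daily integration and batch reduction."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import chamberflux as cf
from chamberflux.rates import integrate_daily


class TestControlCorrection:
    @pytest.mark.parametrize(
        "treat,controls,expected",
        [
            (60.0, [10.0, 10.0, 10.0], 50.0),
            (20.0, [2.0, 4.0], 17.0),  # hand arithmetic
            (5.0, [5.0], 0.0),  # blank identity
        ],
    )
    def test_subtracts_mean_control(self, treat, controls, expected):
        corrected = cf.control_corrected_drift(treat, controls)
        assert corrected.value == pytest.approx(expected)
        assert corrected.n_controls == len(controls)

    def test_missing_controls_is_an_error(self):
        with pytest.raises(ValueError, match="control"):
            cf.control_corrected_drift(10.0, [])


class TestCalcificationRate:
    def test_hand_arithmetic(self, sample_interval):
        # dTA=100 umol/kg, rho=1.025, V=1 L, I_t=3 h, SA=0.0012 m2
        assert cf.calcification_rate(sample_interval, 100.0) == \
            pytest.approx(14.236, abs=1e-3)

    def test_zero_drift_zero_rate(self, sample_interval):
        assert cf.calcification_rate(sample_interval, 0.0) == 0.0

    @given(dta=st.floats(1.0, 200.0), c=st.floats(0.1, 5.0))
    @settings(max_examples=40, deadline=None)
    def test_homogeneity_in_drift(self, dta, c):
        s = cf.WaterSample("ch", "treatment", "light", 0, 2300, 200, 35, 28)
        e = cf.WaterSample("ch", "treatment", "light", 3, 2280, 220, 35, 28)
        itv = cf.IncubationInterval("ch", "treatment", "light", s, e,
                                    V=1.0, rho=1.025, SA=0.0012)
        assert cf.calcification_rate(itv, c * dta) == \
            pytest.approx(c * cf.calcification_rate(itv, dta))

    def test_proportionality_in_volume_and_time(self, sample_interval):
        base = cf.calcification_rate(sample_interval, 50.0)
        i2 = cf.IncubationInterval(
            chamber_id="ch1", role="treatment", phase="light",
            start=sample_interval.start, end=sample_interval.end,
            V=2.0, rho=1.025, SA=0.0012,
        )
        assert cf.calcification_rate(i2, 50.0) == pytest.approx(2 * base)

    def test_control_interval_rejected(self):
        s = cf.WaterSample("ch", "control", "light", 0, 2300, 200, 35, 28)
        e = cf.WaterSample("ch", "control", "light", 3, 2300, 200, 35, 28)
        ctrl = cf.IncubationInterval("ch", "control", "light", s, e, V=1.0, rho=1.025)
        with pytest.raises(ValueError, match="treatment"):
            cf.calcification_rate(ctrl, 10.0)


class TestOxygenFluxRate:
    def test_hand_arithmetic(self, sample_interval):
        # dO2=50 umol/L, V=1 L, I_t=3 h, SA=0.0012 m2; no rho, no 0.5
        assert cf.oxygen_flux_rate(sample_interval, 50.0) == \
            pytest.approx(13.889, abs=1e-3)

    def test_zero(self, sample_interval):
        assert cf.oxygen_flux_rate(sample_interval, 0.0) == 0.0

    def test_dark_sign_flip_gives_positive_respiration(self):
        s = cf.WaterSample("ch", "treatment", "dark", 0, 2300, 200, 35, 28)
        e = cf.WaterSample("ch", "treatment", "dark", 3, 2300, 180, 35, 28)
        itv = cf.IncubationInterval("ch", "treatment", "dark", s, e,
                                    V=1.0, rho=1.025, SA=0.0012)
        d = cf.drift(s, e, "O2")  # -20
        assert cf.oxygen_flux_rate(itv, d) > 0


class TestGrossPhotosynthesis:
    def test_zero(self):
        assert cf.gross_photosynthesis(0.0, 0.0) == 0.0

    def test_additivity(self):
        assert cf.gross_photosynthesis(6.4, 5.0) == pytest.approx(11.4)
        assert cf.gross_photosynthesis(5.4, 3.0) == pytest.approx(8.4)


class TestDailyIntegration:
    def test_constant_rate_closed_form(self):
        # 2 mmol m-2 h-1 over four 3 h light windows -> 24 mmol m-2 d-1
        res = integrate_daily([(2.0, 3.0)] * 4, photoperiod_h=12.0)
        assert res.value == pytest.approx(24.0)
        assert res.coverage_fraction == pytest.approx(1.0)

    def test_single_window(self):
        assert integrate_daily([(5.0, 3.0)]).value == pytest.approx(15.0)

    def test_hand_sum(self):
        assert integrate_daily([(1, 3), (2, 3), (3, 3)]).value == pytest.approx(18.0)

    def test_overlapping_windows_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            integrate_daily([(1.0, 0.0, 3.0), (2.0, 2.0, 5.0)])

    def test_negative_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            integrate_daily([(1.0, -3.0)])

    def test_partial_coverage_reported_not_extrapolated(self):
        res = integrate_daily([(2.0, 3.0)], photoperiod_h=12.0)
        assert res.value == pytest.approx(6.0)
        assert res.coverage_fraction == pytest.approx(0.25)
        assert not res.extrapolated

    def test_explicit_extrapolation(self):
        res = integrate_daily([(2.0, 3.0)], photoperiod_h=12.0, extrapolate=True)
        assert res.value == pytest.approx(24.0)
        assert res.extrapolated


class TestProcessIncubationSet:
    def test_noise_free_round_trip(self, noise_free_sim):
        res = cf.process_incubation_set(
            noise_free_sim.samples, noise_free_sim.colonies, cf.RunConfig()
        )
        row = res.summary.iloc[0]
        truth = noise_free_sim.truth.iloc[0]
        for col in ("G_light", "G_dark", "P_N", "R", "P_G"):
            assert row[col] == pytest.approx(truth[col], rel=1e-9)

    def test_gross_photosynthesis_identity_on_every_row(self, noise_free_sim):
        res = cf.process_incubation_set(
            noise_free_sim.samples, noise_free_sim.colonies, cf.RunConfig()
        )
        assert np.allclose(res.summary["P_G"], res.summary["P_N"] + res.summary["R"])

    def test_control_invariance(self, noise_free_sim):
        """Adding a shared microbial drift to treatments and controls changes nothing."""
        colony = cf.ColonyTruth("c0", 0.0012, 12.0, 6.0, 5.0, 4.0)
        drifted = cf.simulate_incubation(
            cf.SimulationConfig(colonies=[colony], noise_ta=0.0, noise_o2=0.0,
                                control_drift_ta=3.0, control_drift_o2=-1.5)
        )
        res0 = cf.process_incubation_set(
            noise_free_sim.samples, noise_free_sim.colonies, cf.RunConfig()
        )
        res1 = cf.process_incubation_set(drifted.samples, drifted.colonies,
                                         cf.RunConfig())
        for col in ("G_light", "P_N", "R"):
            assert res1.summary[col].iloc[0] == \
                pytest.approx(res0.summary[col].iloc[0], rel=1e-9)

    def test_missing_control_is_an_error(self, noise_free_sim):
        samples = noise_free_sim.samples
        no_controls = samples[samples["role"] == "treatment"]
        with pytest.raises(ValueError, match="control"):
            cf.process_incubation_set(no_controls, noise_free_sim.colonies,
                                      cf.RunConfig())

    def test_duplicate_rows_rejected(self, noise_free_sim):
        dup = pd.concat(
            [noise_free_sim.samples, noise_free_sim.samples.iloc[[0]]],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="duplicate"):
            cf.process_incubation_set(dup, noise_free_sim.colonies, cf.RunConfig())

    def test_empty_treatment_set_warns(self, noise_free_sim):
        controls_only = noise_free_sim.samples[
            noise_free_sim.samples["role"] == "control"
        ]
        with pytest.warns(UserWarning, match="no treatment"):
            res = cf.process_incubation_set(controls_only, noise_free_sim.colonies,
                                            cf.RunConfig())
        assert res.summary.empty

    def test_missing_end_sample_flagged_not_dropped_silently(self, noise_free_sim):
        samples = noise_free_sim.samples
        # drop the dark end sample of the treatment chamber
        mask = ~(
            (samples["role"] == "treatment")
            & (samples["phase"] == "dark")
            & (samples["time_h"] > 0)
        )
        res = cf.process_incubation_set(samples[mask], noise_free_sim.colonies,
                                        cf.RunConfig())
        assert (res.anomalies["flag"] == "missing_end_sample").any()

    def test_negative_respiration_flagged(self, noise_free_sim):
        # a colony that produces O2 in the dark is anomalous, kept and flagged
        colony = cf.ColonyTruth("odd", 0.0012, 12.0, 6.0, 5.0, -2.0)
        sim = cf.simulate_incubation(
            cf.SimulationConfig(colonies=[colony], noise_ta=0.0, noise_o2=0.0)
        )
        res = cf.process_incubation_set(sim.samples, sim.colonies, cf.RunConfig())
        assert (res.anomalies["flag"] == "negative_respiration").any()
        assert res.summary["R"].iloc[0] == pytest.approx(-2.0, rel=1e-9)

    def test_volume_resolution_order(self, noise_free_sim):
        # strip per-cycle volumes: config default must take over, else error
        samples = noise_free_sim.samples.drop(
            columns=["extracted_volume_ml", "residual_volume_ml"]
        )
        with pytest.raises(ValueError, match="volume"):
            cf.process_incubation_set(samples, noise_free_sim.colonies,
                                      cf.RunConfig())
        res = cf.process_incubation_set(
            samples, noise_free_sim.colonies, cf.RunConfig(default_volume_l=1.05)
        )
        assert (res.rates["volume_source"] == "config:default").all()
        truth = noise_free_sim.truth.iloc[0]
        assert res.summary["G_light"].iloc[0] == pytest.approx(truth["G_light"],
                                                               rel=1e-9)

    def test_daily_integrals_match_stepwise_sum(self, noise_free_sim):
        res = cf.process_incubation_set(noise_free_sim.samples,
                                        noise_free_sim.colonies, cf.RunConfig())
        daily = res.daily.iloc[0]
        # one 3 h window per phase at constant rate
        assert daily["P_N_daily"] == pytest.approx(5.0 * 3.0, rel=1e-9)
        assert daily["R_daily"] == pytest.approx(4.0 * 3.0, rel=1e-9)
        assert daily["light_coverage_h"] == pytest.approx(3.0)
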