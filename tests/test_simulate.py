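"""Forward model: kinetics closed forms, signal composition, determinism,
scenario bank structure, and the endotoxemia cohort generator."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nevolt import (
    BolusKinetics,
    CohortParams,
    ConfigurationError,
    ElectrodeModel,
    ScanProtocol,
    ScenarioSpec,
    StimReleaseKinetics,
    make_endotoxemia_cohort,
    make_scenario_bank,
    simulate_concentration,
    simulate_cycles,
    simulate_recording,
)
from nevolt.preprocess import background_subtract
from nevolt.simulate import scenario_seed
from nevolt.waveform import Event

QUIET = ElectrodeModel(noise_sd=0.0, drift_rate=0.0, drift_rw_sd=0.0)


class TestBolusKinetics:
    def test_peak_concentration_from_dose_and_vd(self):
        # 100 µL of 10 µg/mL into 2 mL blood -> 1 µg total -> 0.5 µg/mL
        k = BolusKinetics(dose_ug=1.0, vd_ml=2.0)
        assert k.c_peak == pytest.approx(0.5)
        t = np.linspace(0, 300, 3001)
        c = k.concentration(t, onset=10.0)
        assert c.max() == pytest.approx(0.5, rel=1e-4)

    def test_zero_dose_gives_zero_series(self):
        k = BolusKinetics(dose_ug=0.0)
        t = np.linspace(0, 100, 1001)
        assert not np.any(k.concentration(t, onset=5.0))

    @given(
        k_rise=st.floats(0.05, 2.0),
        ratio=st.floats(1.5, 20.0),
    )
    @settings(max_examples=40, deadline=None)
    def test_peak_time_matches_closed_form(self, k_rise, ratio):
        k_clear = k_rise / ratio
        k = BolusKinetics(dose_ug=1.0, k_rise=k_rise, k_clear=k_clear)
        dt = 0.05
        t = np.arange(0, 600, dt)
        c = k.concentration(t, onset=0.0)
        assert np.all(c >= 0)
        t_argmax = t[np.argmax(c)]
        expected = np.log(k_rise / k_clear) / (k_rise - k_clear)
        assert t_argmax == pytest.approx(expected, abs=dt)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ConfigurationError):
            BolusKinetics(dose_ug=1.0, k_rise=0.01, k_clear=0.02)
        with pytest.raises(ConfigurationError):
            BolusKinetics(dose_ug=-1.0)


class TestStimKinetics:
    def test_linear_limit_decay_rate(self):
        # R = 0, c0 << km: dc/dt ~ -(vmax/km + k_diff) c
        kin = StimReleaseKinetics(vmax=0.0015, km=0.1, k_diff=0.005)
        c0 = 1e-4  # 0.1% of km keeps the Michaelis term effectively linear
        t = np.arange(0.0, 60.0, 0.1)
        c = kin.concentration(
            t, onset=-100.0, train_s=1.0, intensity_uA=0.0, pw_us=0.0, freq_hz=0.0,
            c0=c0,
        )
        rate = kin.vmax / kin.km + kin.k_diff
        np.testing.assert_allclose(c, c0 * np.exp(-rate * t), rtol=2e-3)

    def test_saturating_limit_zero_order_reuptake(self):
        # c >> km: dc/dt ~ -vmax - k_diff*c
        kin = StimReleaseKinetics(vmax=0.0015, km=0.001, k_diff=0.005)
        c0 = 1.0  # 1000x km
        t = np.array([0.0, 0.5])
        c = kin.concentration(
            t, onset=-100.0, train_s=1.0, intensity_uA=0.0, pw_us=0.0, freq_hz=0.0,
            c0=c0,
        )
        dcdt = (c[1] - c[0]) / 0.5
        assert dcdt == pytest.approx(-kin.vmax - kin.k_diff * c0, rel=0.01)

    def test_rk4_step_halving_converges(self):
        kin = StimReleaseKinetics()
        t = np.arange(0.0, 120.0, 0.1)
        args = dict(onset=10.0, train_s=10.0, intensity_uA=300.0, pw_us=500.0,
                    freq_hz=10.0)
        c1 = kin.concentration(t, substeps=1, **args)
        c2 = kin.concentration(t, substeps=2, **args)
        assert np.max(np.abs(c1 - c2)) < 1e-9

    def test_drive_saturates(self):
        kin = StimReleaseKinetics(u50=0.5)
        d_small = kin.drive(10, 500, 10)
        d_large = kin.drive(5000, 500, 10)
        assert 0 < d_small < d_large < 1.0

    @given(
        release_gain=st.floats(0.0, 0.1),
        vmax=st.floats(0.0, 0.01),
        km=st.floats(0.01, 1.0),
        k_diff=st.floats(0.0, 0.05),
        block=st.floats(0.0, 1.0),
    )
    @settings(max_examples=30, deadline=None)
    def test_concentration_never_negative(self, release_gain, vmax, km, k_diff, block):
        kin = StimReleaseKinetics(
            release_gain=release_gain, vmax=vmax, km=km, k_diff=k_diff,
            block_factor=block,
        )
        t = np.arange(0.0, 60.0, 0.2)
        c = kin.concentration(
            t, onset=5.0, train_s=10.0, intensity_uA=300.0, pw_us=500.0, freq_hz=10.0
        )
        assert np.all(c >= 0)


class TestSimulateRecording:
    def spec(self, **kw):
        defaults = dict(
            scenario_id="t", modality="ne_bolus", est_conc_ug_ml=0.25,
            duration_s=40.0, onset_s=20.0, seed=11, sample_rate=10_000.0,
        )
        defaults.update(kw)
        return ScenarioSpec(**defaults)

    def test_same_seed_bit_identical(self):
        rec1, _ = simulate_recording(self.spec())
        rec2, _ = simulate_recording(self.spec())
        np.testing.assert_array_equal(rec1.current, rec2.current)
        cm1, _ = simulate_cycles(self.spec())
        cm2, _ = simulate_cycles(self.spec())
        np.testing.assert_array_equal(cm1.currents, cm2.currents)

    def test_noiseless_saline_subtracts_to_zero(self):
        spec = self.spec(modality="saline", est_conc_ug_ml=0.0)
        cm, truth = simulate_cycles(spec, electrode=QUIET)
        assert not np.any(truth)
        sub = background_subtract(cm, event_time=spec.onset_s)
        np.testing.assert_allclose(sub.currents, 0.0, atol=1e-12)

    def test_constant_concentration_peak_at_e_ox(self):
        # in-vitro step to a constant level: anodic peak lands on E°
        spec = ScenarioSpec(
            scenario_id="w", modality="invitro", medium="spleen",
            est_conc_ug_ml=0.5, duration_s=40.0, onset_s=10.0, seed=1,
            sample_rate=10_000.0,
        )
        cm, _ = simulate_cycles(spec, electrode=QUIET)
        sub = background_subtract(cm, event_time=spec.onset_s)
        last = sub.currents[-1, : cm.n_anodic]
        v_at_max = cm.voltages[np.argmax(last)]
        assert v_at_max == pytest.approx(QUIET.e_ox, abs=cm.protocol.voltage_step)

    def test_doubling_gain_doubles_faradaic_component(self):
        e1 = QUIET
        e2 = ElectrodeModel(
            noise_sd=0.0, drift_rate=0.0, drift_rw_sd=0.0, gain=2 * QUIET.gain
        )
        spec = self.spec()
        cm1, _ = simulate_cycles(spec, electrode=e1)
        cm2, _ = simulate_cycles(spec, electrode=e2)
        proto = cm1.protocol
        background = e1.c_dl * proto.dv_dt_at(
            np.arange(proto.n_sweep_samples) / proto.sample_rate
        )
        far1 = cm1.currents - background
        far2 = cm2.currents - background
        np.testing.assert_allclose(far2, 2 * far1, atol=1e-9)

    def test_e_ox_outside_sweep_rejected(self):
        bad = ElectrodeModel(e_ox=1.5, noise_sd=0.0)
        with pytest.raises(ConfigurationError, match="outside the sweep"):
            simulate_cycles(self.spec(), electrode=bad)

    def test_recording_and_fast_path_share_sweep_template(self):
        spec = self.spec(seed=3)
        rec, truth_r = simulate_recording(spec, electrode=QUIET)
        cm_direct, truth_c = simulate_cycles(spec, electrode=QUIET)
        from nevolt import segment_cycles

        cm_seg = segment_cycles(rec)
        np.testing.assert_allclose(truth_r, truth_c)
        np.testing.assert_allclose(cm_seg.currents, cm_direct.currents, atol=1e-9)


class TestScenarioBank:
    def test_default_bank_contains_dose_ladder(self):
        bank = make_scenario_bank(seed=5)
        ladder = [s for s in bank if s.family == "ne_bolus"]
        assert len(ladder) == 3 * 5
        concs = sorted({s.est_conc_ug_ml for s in ladder})
        assert concs == [0.01, 0.05, 0.1, 0.25, 0.5]

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigurationError, match="unknown scenario families"):
            make_scenario_bank(seed=1, families=("nope",))

    def test_reserpine_blocks_release(self):
        bank = make_scenario_bank(seed=5, families=("reserpine",))
        res = [s for s in bank if s.blockade == "reserpine"]
        assert res and all(s.block_factor == 0.0 for s in res)
        _, truth = simulate_cycles(res[0], electrode=QUIET)
        assert not np.any(truth)

    def test_afferent_only_vns_silent_without_bradycardia(self):
        bank = make_scenario_bank(seed=5, families=("optogenetic",))
        aff = [s for s in bank if s.blockade == "afferent_only"]
        assert aff and all(not s.bradycardia for s in aff)
        _, truth = simulate_cycles(aff[0], electrode=QUIET)
        assert not np.any(truth)
        eff = [s for s in bank if s.blockade == "none"]
        assert all(s.bradycardia for s in eff)

    def test_scenario_seeds_stable_and_distinct(self):
        assert scenario_seed(3, "a") == scenario_seed(3, "a")
        assert scenario_seed(3, "a") != scenario_seed(3, "b")
        assert 0 <= scenario_seed(3, "a") < 2**31


class TestEndotoxemiaCohort:
    def test_noiseless_cohort_recovers_power_law_exactly(self):
        from nevolt import power_fit

        params = CohortParams(tnf_sigma=0.0, a=5.0, b=1.5)
        coh = make_endotoxemia_cohort(params, seed=2)
        stim = coh[coh["group"] == "spns"]
        fit = power_fit(stim["qo_uC"], stim["tnf_pg_ml"])
        assert fit.a == pytest.approx(5.0, rel=1e-6)
        assert fit.b == pytest.approx(1.5, rel=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_group_sizes_and_nonnegative_tnf(self):
        coh = make_endotoxemia_cohort(CohortParams(n_stim=17, n_sham=10), seed=0)
        assert (coh["group"] == "spns").sum() == 17
        assert (coh["group"] == "sham").sum() == 10
        assert (coh["tnf_pg_ml"] >= 0).all()
        assert (coh.loc[coh["group"] == "sham", "qo_uC"] == 0).all()
        assert (coh.loc[coh["group"] == "spns", "qo_uC"] > 0).all()

    def test_invalid_params_rejected(self):
        with pytest.raises(ConfigurationError):
            CohortParams(n_stim=2)
        with pytest.raises(ConfigurationError):
            CohortParams(a=-1.0)
        with pytest.raises(ConfigurationError):
            CohortParams(qo_min_uC=5.0, qo_max_uC=1.0)


class TestSimulateConcentrationDispatch:
    def test_onset_outside_grid_rejected(self):
        k = BolusKinetics(dose_ug=1.0)
        with pytest.raises(ConfigurationError, match="outside the time grid"):
            simulate_concentration(k, np.linspace(0, 10, 11), Event("b", 50.0))
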