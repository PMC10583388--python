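"""i°/E°/window/Q° extraction against closed forms and brute-force oracles."""

import numpy as np
import pytest

from nevolt import (
    AnalysisError,
    ConfigurationError,
    ElectrodeModel,
    OxidationTrace,
    ScanProtocol,
    ScenarioSpec,
    SignalWindow,
    WindowParams,
    compute_io,
    compute_qo,
    detect_window,
    estimate_concentration,
    estimate_eo,
    extract_event,
    oxidation_trace,
    simulate_cycles,
)
from nevolt.oxidation import DEFAULT_BAND
from nevolt.preprocess import SubtractedCycleMatrix, preprocess_cycles

QUIET = ElectrodeModel(noise_sd=0.0, drift_rate=0.0, drift_rw_sd=0.0)


def toy_cycles(currents: np.ndarray, proto: ScanProtocol | None = None):
    """Wrap a (n_cycles, n_sweep) current array as a subtracted matrix."""
    proto = proto or ScanProtocol(n_cycles=currents.shape[0], sample_rate=10_000.0)
    return SubtractedCycleMatrix(
        start_times=np.arange(currents.shape[0]) / proto.cycle_freq,
        currents=np.asarray(currents, dtype=float),
        voltages=proto.sweep_voltages(),
        n_anodic=proto.n_anodic_samples,
        protocol=proto,
        background_template=np.zeros(currents.shape[1]),
    )


def brute_force_io(cycles, band=DEFAULT_BAND):
    """O(n²)-style oracle: scan every sample for the band maximum (ties to
    the lowest voltage), then scan every lower-voltage band sample for the
    minimum; i° is the difference."""
    out_io, out_v = [], []
    v = cycles.voltages
    for row in cycles.currents:
        best_j = None
        for j in range(cycles.n_anodic):
            if band[0] <= v[j] <= band[1]:
                if best_j is None or row[j] > row[best_j]:
                    best_j = j
        trough = row[best_j]
        for j in range(cycles.n_anodic):
            if band[0] <= v[j] <= band[1] and v[j] <= v[best_j]:
                trough = min(trough, row[j])
        out_io.append(row[best_j] - trough)
        out_v.append(v[best_j])
    return np.array(out_io), np.array(out_v)


class TestComputeIo:
    def test_all_zero_cycle(self):
        cm = toy_cycles(np.zeros((3, ScanProtocol(sample_rate=10_000.0).n_sweep_samples)))
        io, _ = compute_io(cm)
        np.testing.assert_array_equal(io, 0.0)

    def test_injected_peak_and_trough(self):
        proto = ScanProtocol(n_cycles=1, sample_rate=10_000.0)
        v = proto.sweep_voltages()
        row = np.zeros(proto.n_sweep_samples)
        j_peak = int(np.argmin(np.abs(v[: proto.n_anodic_samples] - 0.88)))
        j_trough = int(np.argmin(np.abs(v[: proto.n_anodic_samples] - 0.55)))
        row[j_peak] = 100.0
        row[j_trough] = -20.0
        cm = toy_cycles(row[None, :], proto)
        io, e_pk = compute_io(cm)
        assert io[0] == pytest.approx(120.0)
        assert e_pk[0] == pytest.approx(0.88, abs=proto.voltage_step)

    def test_matches_brute_force_on_random_cycles(self):
        proto = ScanProtocol(n_cycles=100, sample_rate=10_000.0)
        rng = np.random.default_rng(42)
        cm = toy_cycles(rng.normal(size=(100, proto.n_sweep_samples)), proto)
        io, e_pk = compute_io(cm)
        io_b, v_b = brute_force_io(cm)
        np.testing.assert_allclose(io, io_b, atol=1e-12)
        np.testing.assert_allclose(e_pk, v_b, atol=1e-12)

    def test_io_always_nonnegative(self):
        proto = ScanProtocol(n_cycles=50, sample_rate=10_000.0)
        rng = np.random.default_rng(3)
        cm = toy_cycles(rng.normal(size=(50, proto.n_sweep_samples)), proto)
        io, _ = compute_io(cm)
        assert np.all(io >= 0)

    def test_empty_band_rejected(self):
        proto = ScanProtocol(n_cycles=1, sample_rate=10_000.0)
        cm = toy_cycles(np.zeros((1, proto.n_sweep_samples)), proto)
        with pytest.raises(AnalysisError, match="search band"):
            compute_io(cm, band=(2.0, 3.0))


class TestDetectWindow:
    def trace(self, io, dt=1.0, baseline_mean=10.0, baseline_sd=1.0):
        io = np.asarray(io, dtype=float)
        return OxidationTrace(
            cycle_times=np.arange(io.size) * dt,
            io=io,
            e_at_peak=np.full(io.size, 0.88),
            baseline_mean=baseline_mean,
            baseline_sd=baseline_sd,
        )

    def test_flat_zero_trace_not_detected(self):
        tr = self.trace(np.zeros(40), baseline_mean=0.0, baseline_sd=0.0)
        w = detect_window(tr, event_onset=5.0)
        assert not w.detected

    def test_hand_walked_twenty_cycle_trace(self):
        # 1 Hz trace, event at t = 5 s; baseline mean 10, SD 1.
        # rise threshold 13 (k_rise=3), end threshold 11 (k_end=1).
        io = [10, 10, 10, 10, 10,
              11, 14, 15, 16, 15,
              14, 12, 10.5, 10, 10,
              10, 10, 10, 10, 10]
        # Hand walk: first 2-cycle run above 13 starts at t=6 (14, 15);
        # after the rise run, the first 3-cycle run below 11 starts at
        # t=12 (10.5, 10, 10) -> window [6, 12).
        params = WindowParams(
            k_rise=3.0, k_end=1.0, min_rise_cycles=2, min_quiet_cycles=3,
            max_latency_s=10.0, max_window_s=100.0,
        )
        w = detect_window(self.trace(io), event_onset=5.0, params=params)
        assert w.detected
        assert w.t_start == pytest.approx(6.0)
        assert w.t_end == pytest.approx(12.0)
        # Q° over [6, 12]: trapezoid of max(io-10, 0) = [4,5,6,5,4,2,0.5]
        # = 24.25 nA·s = 0.02425 µC
        tr = self.trace(io)
        assert compute_qo(tr, w) == pytest.approx(0.02425)

    def test_late_rise_beyond_latency_not_detected(self):
        io = np.full(100, 10.0)
        io[80:] = 20.0
        params = WindowParams(min_rise_cycles=2, max_latency_s=30.0,
                              min_quiet_cycles=3)
        w = detect_window(self.trace(io), event_onset=5.0, params=params)
        assert not w.detected

    def test_window_capped_at_max_length(self):
        io = np.full(200, 20.0)
        io[:10] = 10.0
        params = WindowParams(min_rise_cycles=2, min_quiet_cycles=3,
                              max_latency_s=30.0, max_window_s=50.0)
        w = detect_window(self.trace(io), event_onset=5.0, params=params)
        assert w.detected
        assert w.t_end - w.t_start == pytest.approx(50.0)

    def test_insufficient_baseline_rejected(self):
        proto = ScanProtocol(n_cycles=20, sample_rate=10_000.0)
        cm = toy_cycles(np.zeros((20, proto.n_sweep_samples)), proto)
        with pytest.raises(AnalysisError, match="pre-event"):
            oxidation_trace(cm, event_onset=0.5)


class TestComputeQo:
    def trace_from(self, io, dt=1.0, baseline=0.0):
        io = np.asarray(io, dtype=float)
        return OxidationTrace(
            cycle_times=np.arange(io.size) * dt, io=io,
            e_at_peak=np.full(io.size, 0.88),
            baseline_mean=baseline, baseline_sd=0.0,
        )

    def test_rectangle_sixty_seconds(self):
        # constant i° = baseline + 100 nA over a 60 s window -> 6 µC
        tr = self.trace_from(np.full(100, 105.0), dt=1.0, baseline=5.0)
        w = SignalWindow(t_start=10.0, t_end=70.0, detected=True)
        assert compute_qo(tr, w) == pytest.approx(6.0)

    def test_triangle_closed_form(self):
        # triangular pulse height h, base b: area h*b/2 nA·s
        h, half = 80.0, 20
        dt = 0.5
        up = np.linspace(0, h, half + 1)
        tri = np.concatenate([np.zeros(20), up, up[-2::-1], np.zeros(20)])
        tr = self.trace_from(tri, dt=dt)
        w = SignalWindow(t_start=20 * dt, t_end=(20 + 2 * half) * dt, detected=True)
        base_s = 2 * half * dt
        assert compute_qo(tr, w) == pytest.approx(h * base_s / 2 / 1000.0, rel=1e-9)

    def test_undetected_window_gives_zero(self):
        tr = self.trace_from(np.full(50, 10.0))
        assert compute_qo(tr, SignalWindow.none()) == 0.0

    def test_additivity_at_interior_node(self):
        rng = np.random.default_rng(9)
        tr = self.trace_from(rng.uniform(0, 50, 120), dt=0.1)
        a, b, c = 2.0, 5.3, 9.8  # b is a cycle time (multiple of 0.1)
        q_ac = compute_qo(tr, SignalWindow(a, c, True))
        q_ab = compute_qo(tr, SignalWindow(a, b, True))
        q_bc = compute_qo(tr, SignalWindow(b, c, True))
        assert q_ac == pytest.approx(q_ab + q_bc, rel=1e-12)

    def test_raw_flag_skips_baseline_offset(self):
        tr = self.trace_from(np.full(100, 105.0), baseline=5.0)
        w = SignalWindow(10.0, 70.0, True)
        assert compute_qo(tr, w, subtract_baseline=False) == pytest.approx(6.3)


class TestEstimateEo:
    @pytest.mark.parametrize("medium,e_ox", [("pbs", 0.57), ("blood", 0.72),
                                             ("spleen", 0.88)])
    def test_noiseless_presets_recovered_within_one_grid_step(self, medium, e_ox):
        elec = ElectrodeModel(
            e_ox=e_ox, noise_sd=0.0, drift_rate=0.0, drift_rw_sd=0.0
        )
        spec = ScenarioSpec(
            scenario_id=f"eo_{medium}", modality="invitro", medium=medium,
            est_conc_ug_ml=3.3, duration_s=60.0, onset_s=25.0, seed=0,
        )
        cm, _ = simulate_cycles(spec, electrode=elec)
        sub = preprocess_cycles(cm, spec.onset_s)
        summary = extract_event(sub, spec.onset_s)
        assert summary.window.detected
        assert summary.e_ox_hat == pytest.approx(
            e_ox, abs=2 * cm.protocol.voltage_step
        )

    def test_no_supra_baseline_cycles_returns_undefined(self):
        proto = ScanProtocol(n_cycles=60, sample_rate=10_000.0)
        cm = toy_cycles(np.zeros((60, proto.n_sweep_samples)), proto)
        tr = oxidation_trace(cm, event_onset=3.0)
        eo = estimate_eo(cm, tr, SignalWindow(3.0, 5.0, True))
        assert eo is None


class TestScaleEquivariance:
    def test_current_scaling_propagates_linearly(self):
        spec = ScenarioSpec(
            scenario_id="sc", modality="ne_bolus", est_conc_ug_ml=0.25,
            duration_s=60.0, onset_s=20.0, seed=0, sample_rate=10_000.0,
        )
        cm, _ = simulate_cycles(spec, electrode=QUIET)
        sub = preprocess_cycles(cm, spec.onset_s)
        s1 = extract_event(sub, spec.onset_s)
        scaled = SubtractedCycleMatrix(
            start_times=sub.start_times, currents=3.0 * sub.currents,
            voltages=sub.voltages, n_anodic=sub.n_anodic, protocol=sub.protocol,
            background_template=sub.background_template,
        )
        s3 = extract_event(scaled, spec.onset_s)
        assert s3.peak_io == pytest.approx(3.0 * s1.peak_io, rel=1e-12)
        assert s3.qo == pytest.approx(3.0 * s1.qo, rel=1e-12)
        assert s3.e_ox_hat == s1.e_ox_hat
        assert s3.window == s1.window

    def test_noiseless_qo_monotone_in_dose(self):
        qos = []
        for conc in (0.05, 0.1, 0.25, 0.5):
            spec = ScenarioSpec(
                scenario_id=f"m{conc}", modality="ne_bolus", est_conc_ug_ml=conc,
                duration_s=120.0, onset_s=20.0, seed=0, sample_rate=10_000.0,
            )
            cm, _ = simulate_cycles(spec, electrode=QUIET)
            sub = preprocess_cycles(cm, spec.onset_s)
            qos.append(extract_event(sub, spec.onset_s).qo)
        assert all(b > a for a, b in zip(qos, qos[1:]))


class TestBolusWindowCoverage:
    def test_window_covers_truth_support(self):
        spec = ScenarioSpec(
            scenario_id="cov", modality="ne_bolus", est_conc_ug_ml=0.25,
            duration_s=260.0, onset_s=20.0, seed=0, sample_rate=10_000.0,
        )
        cm, truth = simulate_cycles(spec, electrode=QUIET)
        sub = preprocess_cycles(cm, spec.onset_s)
        summary = extract_event(sub, spec.onset_s)
        assert summary.window.detected
        assert summary.window.t_start - spec.onset_s <= 3.0
        support = cm.start_times[truth > 0.01 * truth.max()]
        inside = (support >= summary.window.t_start) & (
            support < summary.window.t_end
        )
        assert inside.mean() >= 0.95


class TestEstimateConcentration:
    @pytest.mark.parametrize(
        "vol,conc,expected",
        [(100.0, 10.0, 0.5), (100.0, 0.2, 0.01), (0.0, 10.0, 0.0)],
    )
    def test_printed_dose_examples(self, vol, conc, expected):
        assert estimate_concentration(vol, conc, vd_ml=2.0) == pytest.approx(expected)

    def test_zero_vd_rejected(self):
        with pytest.raises(ConfigurationError, match="distribution"):
            estimate_concentration(100.0, 10.0, vd_ml=0.0)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ConfigurationError):
            estimate_concentration(-1.0, 10.0)
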