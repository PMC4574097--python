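"""Fits and derived quantities: exact synthetics, oracles, parameter recovery."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize

import kvclamp as kv
from kvclamp.analysis import DegenerateFitError, UnidentifiableError


class TestFitMonoexp:
    def test_exact_synthetic(self):
        t = np.arange(0, 1000, 0.5)
        y = 5.0 * np.exp(-t / 100.0) + 2.0
        fit = kv.fit_monoexp(t, y)
        assert fit.amplitudes[0] == pytest.approx(5.0, rel=1e-6)
        assert fit.tau == pytest.approx(100.0, rel=1e-6)
        assert fit.offset == pytest.approx(2.0, rel=1e-6)
        assert fit.converged

    def test_flat_trace_degenerate(self):
        t = np.arange(0, 100, 0.5)
        with pytest.raises(DegenerateFitError):
            kv.fit_monoexp(t, np.full(t.size, 3.0))

    def test_too_few_samples(self):
        with pytest.raises(ValueError):
            kv.fit_monoexp(np.arange(5.0), np.arange(5.0), window=(0, 4))

    def test_against_independent_optimizer(self, equine, tr_act_equine):
        """Activation fit at 0 mV agrees with a generic Nelder-Mead fit."""
        i0 = list(tr_act_equine.sweep_voltages).index(0.0)
        tloc, seg = tr_act_equine.epoch_segment(0)
        fit = kv.fit_monoexp(tloc, seg[i0], window=(0.0, 500.0))
        m = tloc <= 500.0
        t, y = tloc[m], seg[i0][m]

        def sse(p):
            a, tau, c = p
            return np.sum((y - (a * np.exp(-t / abs(tau)) - c)) ** 2)

        res = minimize(sse, x0=(y[0] - y[-1], 200.0, -y[-1]),
                       method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        tau_ref = abs(res.x[1])
        assert fit.tau == pytest.approx(tau_ref, rel=0.10)

    def test_tau_invariant_under_current_rescaling(self):
        t = np.arange(0, 800, 0.5)
        y = -2.0 * np.exp(-t / 60.0) + 0.3
        tau1 = kv.fit_monoexp(t, y).tau
        tau2 = kv.fit_monoexp(t, 50.0 * y).tau
        assert tau1 == pytest.approx(tau2, rel=1e-8)


class TestFitBiexp:
    def test_exact_synthetic_with_ordering_and_weight(self):
        t = np.arange(0, 4000, 0.5)
        y = 3.0 * np.exp(-t / 80.0) + 1.0 * np.exp(-t / 600.0)
        fit = kv.fit_biexp(t, y)
        assert fit.tau_fast == pytest.approx(80.0, rel=1e-5)
        assert fit.tau_slow == pytest.approx(600.0, rel=1e-5)
        assert fit.weight_fast == pytest.approx(0.75, rel=1e-5)
        assert "effectively_monoexponential" not in fit.flags

    def test_monoexponential_input_collapses(self):
        t = np.arange(0, 2000, 0.5)
        y = 4.0 * np.exp(-t / 200.0) + 0.1
        fit = kv.fit_biexp(t, y)
        assert "effectively_monoexponential" in fit.flags

    def test_needs_enough_samples(self):
        t = np.arange(0, 10, 0.5)
        with pytest.raises(ValueError):
            kv.fit_biexp(t, np.exp(-t))


class TestPeakTail:
    def test_pure_decay_peaks_at_window_start(self):
        t = np.arange(0, 500, 0.5)
        y = -3.0 * np.exp(-t / 100.0)
        peak = kv.measure_peak_tail(t, y, blank_ms=0.0)
        assert peak == pytest.approx(-3.0)

    def test_hooked_tail_finds_hook_not_first_sample(self):
        """Rising-then-falling magnitude: the true hook peak is selected."""
        t = np.arange(0, 500, 0.5)
        y = -(1.0 - np.exp(-t / 3.0)) * np.exp(-t / 150.0) * 2.5
        peak = kv.measure_peak_tail(t, y, blank_ms=2.0)
        brute = y[t >= 2.0]
        assert peak == pytest.approx(brute[np.argmax(np.abs(brute))])
        assert abs(peak) > abs(y[4])  # larger than the first post-blank sample

    def test_zero_trace(self):
        t = np.arange(0, 100, 0.5)
        assert kv.measure_peak_tail(t, np.zeros(t.size)) == 0.0

    def test_epoch_shorter_than_blank(self):
        t = np.arange(0, 1.0, 0.5)
        with pytest.raises(ValueError):
            kv.measure_peak_tail(t, np.zeros(t.size), blank_ms=2.0)

    def test_hook_fit_matches_peak_on_clean_sweeps(self, tr_iv_equine):
        tloc, seg = tr_iv_equine.epoch_segment(1)
        for i in (0, 3, 8):
            raw = kv.measure_peak_tail(tloc, seg[i])
            fit = kv.tail_amplitude_hook_fit(tloc, seg[i])
            assert fit == pytest.approx(raw, rel=0.03, abs=5e-3)


class TestActivationCurve:
    def test_exact_boltzmann_samples_recovered(self):
        v = np.arange(-60.0, 41.0, 10.0)
        y = 1.0 / (1.0 + np.exp((-20.0 - v) / 5.0))
        tab = pd.DataFrame({"voltage_mV": v, "peak_uA": -2.0 * y})
        fit = kv.activation_curve(tab)
        assert fit.v_half == pytest.approx(-20.0, abs=1e-6)
        assert fit.k == pytest.approx(5.0, abs=1e-6)

    def test_invariant_to_current_rescaling(self, tr_act_equine):
        tab = kv.peak_tail_table(tr_act_equine)
        scaled = tab.assign(peak_uA=tab.peak_uA * 37.0)
        a = kv.activation_curve(tab)
        b = kv.activation_curve(scaled)
        assert a.v_half == pytest.approx(b.v_half, abs=1e-9)
        assert a.k == pytest.approx(b.k, abs=1e-9)

    def test_non_spanning_data_unidentifiable(self):
        v = np.arange(-60.0, 41.0, 10.0)
        with pytest.raises(UnidentifiableError):
            kv.activation_curve(pd.DataFrame(
                {"voltage_mV": v, "peak_uA": np.full(v.size, -2.0)}))
        with pytest.raises(UnidentifiableError):
            kv.activation_curve(pd.DataFrame(
                {"voltage_mV": v[:4], "peak_uA": -np.linspace(0, 1, 4)}))

    def test_normalized_tails_reproduce_open_fraction(self, equine, tr_act_equine):
        """Peak tails at -120 mV report n_inf at the preceding step (<2%)."""
        tab = kv.peak_tail_table(tr_act_equine)
        n_inf = kv.steady_state_activation(tab.voltage_mV.values, equine)
        norm = np.abs(tab.peak_uA.values) / np.abs(tab.peak_uA.values).max()
        ratio = norm / (n_inf / n_inf.max())
        assert np.all(np.abs(ratio - 1.0) < 0.02)


class TestFullyActivatedIV:
    def test_ohmic_synthetic_exact(self):
        """I = 2 uS * (V + 100 mV) tails give G = 2 uS, e_rev = -100 mV."""
        proto = kv.fully_activated_iv_protocol(step_duration=50.0, tail_duration=50.0)
        n = int(round(proto.total_duration * proto.sampling_rate / 1000.0))
        time = np.arange(n) * 0.5
        sl = proto.epoch_sample_slice(1)
        sweeps = np.zeros((proto.n_sweeps, n))
        for i, v in enumerate(proto.sweep_voltages):
            sweeps[i, sl] = 1e-3 * 2.0 * (v + 100.0)
        tr = kv.TraceSet(time=time, sweeps=sweeps,
                         sweep_voltages=np.array(proto.sweep_voltages),
                         protocol=proto)
        iv = kv.fully_activated_iv(tr)
        assert iv.g == pytest.approx(2.0, rel=1e-9)
        assert iv.e_rev == pytest.approx(-100.0, abs=1e-9)

    def test_recovers_conductance_and_reversal(self, tr_iv_equine):
        iv = kv.fully_activated_iv(tr_iv_equine)
        assert iv.g == pytest.approx(159.0, rel=0.03)
        assert iv.e_rev == pytest.approx(-103.0, abs=1.0)

    def test_alternative_window_agrees(self, tr_iv_equine):
        """The two windows the analysis convention allows give the same G
        within 3% on clean data."""
        g1 = kv.fully_activated_iv(tr_iv_equine, fit_window=(-120.0, -90.0)).g
        g2 = kv.fully_activated_iv(tr_iv_equine, fit_window=(-110.0, -90.0)).g
        assert g2 == pytest.approx(g1, rel=0.03)

    def test_window_needs_two_points(self, tr_iv_equine):
        with pytest.raises(ValueError):
            kv.fully_activated_iv(tr_iv_equine, fit_window=(-118.0, -115.0))


class TestRectification:
    def test_r_near_one_in_linear_window(self, tr_iv_equine):
        rect = kv.rectification_curve(kv.fully_activated_iv(tr_iv_equine))
        m = (rect.voltages >= -120.0) & (rect.voltages <= -90.0)
        assert np.all(np.abs(rect.r[m] - 1.0) < 0.03)

    def test_recovers_inactivation_midpoint(self, equine, tr_iv_equine):
        rect = kv.rectification_curve(kv.fully_activated_iv(tr_iv_equine))
        assert rect.boltzmann.v_half == pytest.approx(equine.v_half_inact, abs=2.0)
        assert not rect.boltzmann.increasing

    def test_voltages_near_reversal_excluded(self, tr_iv_equine):
        rect = kv.rectification_curve(kv.fully_activated_iv(tr_iv_equine))
        assert -100.0 in rect.excluded_voltages
        assert np.all(np.abs(rect.voltages + 103.0) >= 5.0 - 0.5)

    def test_unity_availability_gives_unity_r(self, equine):
        """R == 1 at all non-excluded voltages when the channel does not
        inactivate (availability forced to 1 across the range)."""
        from dataclasses import replace
        p = replace(equine, v_half_inact=1e4, k_inact=20.0)
        tr = kv.simulate_protocol(kv.fully_activated_iv_protocol(), p)
        rect = kv.rectification_curve(kv.fully_activated_iv(tr))
        assert np.all(np.abs(rect.r - 1.0) < 0.02)


class TestTauTables:
    def test_activation_taus_cover_restricted_range(self, tr_act_equine):
        tab = kv.activation_tau_table(tr_act_equine)
        assert list(tab.voltage_mV) == [-20.0, -10.0, 0.0, 10.0, 20.0]
        assert (tab.tau_ms > 0).all()
        assert tab.converged.all()

    def test_activation_taus_similar_between_sets(self, tr_act_equine, tr_act_human):
        """Equine and human share activation kinetics; the fitted time
        constants (which conflate activation and inactivation) must agree."""
        te = kv.activation_tau_table(tr_act_equine).tau_ms.values
        th = kv.activation_tau_table(tr_act_human).tau_ms.values
        assert np.all(np.abs(te / th - 1.0) < 0.10)

    def test_onset_taus_recover_generator_values(self, equine, tr_onset_equine):
        tab = kv.inactivation_onset_taus(tr_onset_equine)
        assert list(tab.voltage_mV) == [-20.0, -10.0, 0.0, 10.0, 20.0, 30.0, 40.0]
        true = equine.tau_inact_spec(tab.voltage_mV.values)
        assert np.all(np.abs(tab.tau_ms.values / true - 1.0) < 0.10)

    def test_onset_tau_decreases_with_depolarization(self, tr_onset_equine):
        tab = kv.inactivation_onset_taus(tr_onset_equine)
        upper = tab[tab.voltage_mV >= 0.0].tau_ms.values
        assert np.all(np.diff(upper) < 0)

    def test_equine_onset_slower_than_human(self, human, tr_onset_equine):
        te = kv.inactivation_onset_taus(tr_onset_equine)
        th = kv.inactivation_onset_taus(
            kv.simulate_protocol(kv.inactivation_onset_protocol(), human))
        assert np.all(te.tau_ms.values > th.tau_ms.values)


class TestDeactivation:
    def test_tables_cover_protocol_voltages(self, tr_deact_equine):
        tab = kv.deactivation_tables(tr_deact_equine)
        assert list(tab.voltage_mV) == [-100.0, -90.0, -80.0, -70.0]
        assert (tab.tau_fast_ms < tab.tau_slow_ms).all()

    def test_recovers_both_components(self, equine, tr_deact_equine):
        tab = kv.deactivation_tables(tr_deact_equine)
        tf = equine.tau_act_spec(tab.voltage_mV.values)
        ts = equine.tau_act_slow(tab.voltage_mV.values)
        w = equine.w_fast_spec(tab.voltage_mV.values)
        assert np.all(np.abs(tab.tau_fast_ms.values / tf - 1.0) < 0.15)
        assert np.all(np.abs(tab.tau_slow_ms.values / ts - 1.0) < 0.15)
        assert np.all(np.abs(tab.weight_fast.values - w) < 0.05)

    def test_fast_weight_dominates_at_hyperpolarized(self, tr_deact_equine):
        tab = kv.deactivation_tables(tr_deact_equine).sort_values("voltage_mV")
        assert np.all(np.diff(tab.weight_fast.values) < 0)


class TestSteadyStateIV:
    def test_kcne2_scaling_applies_at_every_voltage(self, equine, tr_act_equine):
        scaled = kv.apply_kcne2(equine, 0.423)
        ss = kv.steady_state_iv(tr_act_equine)
        ssk = kv.steady_state_iv(kv.simulate_protocol(kv.activation_protocol(), scaled))
        assert np.allclose(ssk.current_uA, 0.577 * ss.current_uA, rtol=1e-9)

    def test_zero_trace_gives_zeros(self):
        proto = kv.activation_protocol(step_duration=50.0, tail_duration=25.0)
        n = int(round(proto.total_duration * proto.sampling_rate / 1000.0))
        tr = kv.TraceSet(time=np.arange(n) * 0.5,
                         sweeps=np.zeros((proto.n_sweeps, n)),
                         sweep_voltages=np.array(proto.sweep_voltages),
                         protocol=proto)
        assert (kv.steady_state_iv(tr).current_uA == 0).all()


class TestStochasticRecovery:
    def test_noise_does_not_bias_recovered_parameters(self, equine):
        """With sigma = 0.1 uA additive noise and 10 replicates, the mean
        recovered activation midpoint/slope and tail conductance/reversal
        stay within 2 SEM of their noiseless recovery (the hook-regression
        amplitude estimator carries no extremum-selection bias), and within
        the deterministic recovery tolerances of the generator truth.
        """
        nl_b = kv.activation_curve(kv.peak_tail_table(
            kv.simulate_protocol(kv.activation_protocol(), equine),
            method="hook_fit"))
        nl_iv = kv.fully_activated_iv(
            kv.simulate_protocol(kv.fully_activated_iv_protocol(), equine),
            method="hook_fit")
        vhs, ks, gs, ers = [], [], [], []
        for rep in range(10):
            tr = kv.simulate_protocol(kv.activation_protocol(), equine,
                                      noise=kv.NoiseSpec(sigma=0.1, seed=200 + rep))
            b = kv.activation_curve(kv.peak_tail_table(tr, method="hook_fit"))
            vhs.append(b.v_half)
            ks.append(b.k)
            tri = kv.simulate_protocol(kv.fully_activated_iv_protocol(), equine,
                                       noise=kv.NoiseSpec(sigma=0.1, seed=300 + rep))
            iv = kv.fully_activated_iv(tri, method="hook_fit")
            gs.append(iv.g)
            ers.append(iv.e_rev)
        for vals, noiseless in ((vhs, nl_b.v_half), (ks, nl_b.k),
                                (gs, nl_iv.g), (ers, nl_iv.e_rev)):
            vals = np.asarray(vals)
            sem = vals.std(ddof=1) / np.sqrt(vals.size)
            assert abs(vals.mean() - noiseless) <= 2.0 * sem
        assert abs(np.mean(vhs) - equine.v_half_act) < 1.0
        assert abs(np.mean(gs) / equine.g_max - 1.0) < 0.03
        assert abs(np.mean(ers) - equine.e_rev) < 1.0
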