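"""Generator correctness: Poisson statistics, amplitude mixture, rendering
linearity, EAP template, coupling, and condition transforms."""

import math

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid

from gradespike import stats, synth


class TestSpikeTrain:
    def test_zero_rate_gives_empty_train(self):
        assert synth.generate_spike_train(0.0, 100.0, 0).size == 0

    @pytest.mark.parametrize("rate,duration", [(-1.0, 10.0), (1.0, 0.0), (1.0, -5.0)])
    def test_bad_arguments_rejected(self, rate, duration):
        with pytest.raises(ValueError):
            synth.generate_spike_train(rate, duration, 0)

    def test_poisson_moments_at_study_rate(self):
        # closed-form oracle: count ~ Poisson(rate*T), ISI CV -> 1
        rate, duration = 0.148, 1_000_000.0
        times = synth.generate_spike_train(rate, duration, 202)
        expected = rate * duration
        assert abs(times.size - expected) < 3 * math.sqrt(expected)
        isis = np.diff(times)
        cv = np.std(isis, ddof=1) / np.mean(isis)
        assert abs(np.mean(isis) - 1 / rate) < 3 * (1 / rate) / math.sqrt(isis.size)
        assert abs(cv - 1.0) < 3 * 1.0 / math.sqrt(isis.size)

    def test_strictly_increasing_and_inside_window(self):
        times = synth.generate_spike_train(2.0, 50.0, 3)
        assert np.all(np.diff(times) > 0)
        assert times[0] >= 0 and times[-1] < 50.0

    def test_seed_determinism(self):
        a = synth.generate_spike_train(1.0, 100.0, 9)
        b = synth.generate_spike_train(1.0, 100.0, 9)
        np.testing.assert_array_equal(a, b)


class TestAmplitudes:
    def test_degenerate_mixture_all_small(self, classes):
        import dataclasses

        p = dataclasses.replace(classes, p_large=0.0)
        truth = synth.assign_amplitudes(np.arange(1, 100, dtype=float), p, 0)
        assert set(truth.class_labels) == {"small"}

    def test_large_class_median(self):
        # log-normal median oracle: exp(mu); sample-median SE via 1/(2 f(m) sqrt(n))
        p = synth.SpikeClassParams(
            p_large=0.5,
            small_amp_mu=math.log(0.3), small_amp_sigma=0.3,
            large_amp_mu=math.log(1.5), large_amp_sigma=0.3,
        )
        n = 10_000
        truth = synth.assign_amplitudes(np.arange(1, n + 1, dtype=float), p, 11)
        large = truth.true_amplitudes[truth.class_labels == "large"]
        f_med = 1.0 / (1.5 * 0.3 * math.sqrt(2 * math.pi))
        se = 1.2533 / (f_med * math.sqrt(large.size))
        assert abs(np.median(large) - 1.5) < 3 * se

    def test_label_probability(self):
        n = 20_000
        truth = synth.assign_amplitudes(
            np.arange(1, n + 1, dtype=float), synth.SpikeClassParams(p_large=0.3), 4
        )
        frac = np.mean(truth.class_labels == "large")
        assert abs(frac - 0.3) < 3 * math.sqrt(0.3 * 0.7 / n)

    def test_separated_mixture_fails_normality_screen(self):
        truth = synth.assign_amplitudes(
            np.arange(1, 201, dtype=float), synth.SpikeClassParams(), 5
        )
        jb = stats.jarque_bera(truth.true_amplitudes)
        crit = stats.jb_critical_value(truth.n_events, replicates=20_000, seed=0)
        assert jb > crit

    def test_secondary_scale_distribution_median(self):
        n = 4001
        scales = synth.draw_secondary_scales(n, 8)
        # sample-median SE for log-normal(ln 0.23, sigma from quartiles)
        sigma = scales.std()  # not used for the bound; direct density bound below
        f_med = 1.0 / (0.23 * 0.899 * math.sqrt(2 * math.pi))
        se = 1.2533 / (f_med * math.sqrt(n))
        assert abs(np.median(scales) - 0.23) < 3 * se

    def test_scale_quartiles_match_population(self):
        # one log-normal cannot hit both reported quartiles exactly with the
        # median fixed; the generator matches their geometric spread
        scales = synth.draw_secondary_scales(50_000, 17)
        q25, q75 = np.percentile(scales, [25, 75])
        assert q75 / q25 == pytest.approx(0.37 / 0.11, rel=0.05)
        # quartiles of a log-normal are geometrically centred on the median
        assert math.sqrt(q25 * q75) == pytest.approx(0.23, rel=0.03)


class TestCaRendering:
    def test_noise_only_trace_sd(self, kernel):
        import dataclasses

        k = dataclasses.replace(kernel, noise_sd=0.07)
        truth = synth.GroundTruth(np.empty(0), np.empty(0), np.empty(0), np.empty(0), rate=0.0)
        tr = synth.render_ca_trace(truth, k, duration=400.0, seed=3)
        assert tr.n_samples >= 10_000
        assert abs(np.std(tr.samples) - 0.07) / 0.07 < 0.10

    def test_single_event_peak_equals_amplitude(self, kernel):
        import dataclasses

        k = dataclasses.replace(kernel, noise_sd=0.0)
        t_e = 150 / k.frame_rate  # on a frame boundary: no discretization error
        truth = synth.GroundTruth(
            np.array([t_e]), np.array(["small"], dtype=object),
            np.array([0.8]), np.array([0.0]), rate=0.1,
        )
        tr = synth.render_ca_trace(truth, k, duration=20.0)
        # the kernel peak falls between frames; sampled max is within a few %
        assert tr.samples.max() == pytest.approx(0.8, rel=0.02)

    def test_linearity_of_summated_transients(self, kernel):
        import dataclasses

        k = dataclasses.replace(kernel, noise_sd=0.0)

        def one(t, a):
            truth = synth.GroundTruth(
                np.array([t]), np.array(["small"], dtype=object),
                np.array([a]), np.array([0.0]), rate=0.1,
            )
            return synth.render_ca_trace(truth, k, duration=10.0).samples

        both = synth.GroundTruth(
            np.array([3.0, 3.2]), np.array(["small", "large"], dtype=object),
            np.array([0.5, 1.1]), np.array([0.0, 0.0]), rate=0.2,
        )
        combined = synth.render_ca_trace(both, k, duration=10.0).samples
        np.testing.assert_allclose(combined, one(3.0, 0.5) + one(3.2, 1.1), atol=1e-12)

    def test_events_outside_window_dropped_with_warning(self, kernel, caplog):
        truth = synth.GroundTruth(
            np.array([1.0, 50.0]), np.array(["small", "small"], dtype=object),
            np.array([0.5, 0.5]), np.array([0.0, 0.0]), rate=0.1,
        )
        import logging

        with caplog.at_level(logging.WARNING, logger="gradespike.synth"):
            synth.render_ca_trace(truth, kernel, duration=10.0, seed=0)
        assert any("outside the trace window" in r.message for r in caplog.records)


class TestEapRendering:
    def test_scale_zero_matches_primary_only_template(self, template):
        times = np.array([0.05])
        tr0 = synth.render_eap_train(times, template, np.array([0.0]), None, duration=0.1)
        # oracle: direct closed-form evaluation on the same grid
        t = np.arange(tr0.n_samples) / template.sample_rate - 0.05
        import dataclasses

        tpl0 = dataclasses.replace(template, noise_sd=0.0)
        expected = synth.eap_template_waveform(t, tpl0, 0.0)
        tr0n = synth.render_eap_train(times, tpl0, np.array([0.0]), None, duration=0.1)
        np.testing.assert_allclose(tr0n.samples, expected, atol=1e-5)

    def test_integral_peak_increases_with_scale(self, template):
        # numeric-integration oracle on the closed-form template
        peaks = [synth.template_integral_peak(template, s) for s in np.linspace(0, 1.4, 29)]
        assert np.all(np.diff(peaks) > 0)

    def test_rendered_integral_matches_template_oracle(self, template):
        import dataclasses

        tpl = dataclasses.replace(template, noise_sd=0.0)
        for s in (0.0, 0.5, 1.0):
            tr = synth.render_eap_train(np.array([0.05]), tpl, np.array([s]), None, duration=0.1)
            integ = cumulative_trapezoid(tr.samples, dx=1 / tpl.sample_rate, initial=0.0)
            assert integ.max() == pytest.approx(synth.template_integral_peak(tpl, s), rel=1e-3)

    def test_integral_nonnegative_at_peak(self, template):
        for s in (0.0, 0.3, 1.0):
            assert synth.template_integral_peak(template, s) >= 0

    def test_mismatched_scales_rejected(self, template):
        with pytest.raises(ValueError, match="one secondary scale per event"):
            synth.render_eap_train(np.array([0.1, 0.2]), template, np.array([0.5]), 0)


class TestPairedRecording:
    def test_exact_coupling_gives_r2_one(self, template, kernel):
        import dataclasses

        cfg = synth.PairedConfig(
            duration=200.0,
            classes=dataclasses.replace(synth.SpikeClassParams(), coupling_noise_sd=0.0),
            seed=21,
        )
        ca, eap_tr, truth = synth.generate_paired_recording(cfg)
        ipk = np.array(
            [synth.template_integral_peak(cfg.template, s) for s in truth.true_secondary_scales]
        )
        slope, _, r2 = stats.paired_regression(ipk, truth.true_amplitudes)
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert slope == pytest.approx(cfg.classes.coupling_slope, rel=1e-9)

    def test_variance_ratio_three_gives_r2_075(self):
        # analytic oracle: R^2 = var_signal / (var_signal + var_noise) = 3/4
        rng = np.random.default_rng(7)
        scales = synth.draw_secondary_scales(300, rng)
        tpl = synth.EapTemplateParams()
        ipk = np.array([synth.template_integral_peak(tpl, s) for s in scales])
        sd = synth.coupling_noise_for_variance_ratio(ipk, 12.0, 3.0)
        y = 12.0 * ipk + rng.normal(0, sd, ipk.size)
        _, _, r2 = stats.paired_regression(ipk, y)
        # MC spread of sample R^2 at n=300: sd ~ 2*rho*(1-rho^2)/sqrt(n)
        assert abs(r2 - 0.75) < 3 * 2 * math.sqrt(0.75) * 0.25 / math.sqrt(300)

    def test_identical_event_times_in_both_channels(self):
        cfg = synth.PairedConfig(duration=100.0, seed=5)
        ca, eap_tr, truth = synth.generate_paired_recording(cfg)
        assert ca.duration == pytest.approx(eap_tr.duration, rel=1e-6)
        assert truth.n_events > 0


class TestConditions:
    def _truth(self, n=200, seed=0, duration=1000.0):
        times = synth.generate_spike_train(n / duration, duration, seed)
        return synth.assign_amplitudes(times, synth.SpikeClassParams(), seed,
                                       rate=n / duration, duration=duration)

    def test_ttx_is_identity(self):
        truth = self._truth()
        out = synth.apply_condition(truth, "TTx", seed=1)
        np.testing.assert_array_equal(out.event_times, truth.event_times)
        np.testing.assert_array_equal(out.true_amplitudes, truth.true_amplitudes)

    def test_cd_forces_small_class(self):
        import dataclasses

        truth = self._truth(seed=2)
        truth = dataclasses.replace(
            truth, class_labels=np.full(truth.n_events, "large", dtype=object)
        )
        out = synth.apply_condition(truth, "Cd", seed=3)
        assert set(out.class_labels) == {"small"}
        assert np.all(out.true_secondary_scales == 0.0)
        # amplitudes redrawn from the small class: median near 0.3, not 1.5
        assert np.median(out.true_amplitudes) < 0.6

    def test_ml218_binomial_thinning(self):
        times = synth.generate_spike_train(10.0, 1000.0, 4)
        truth = synth.assign_amplitudes(times, synth.SpikeClassParams(), 4, rate=10.0,
                                        duration=1000.0)
        out = synth.apply_condition(truth, "ML218", seed=5)
        n, p = truth.n_events, 0.05
        assert abs(out.n_events - n * p) < 3 * math.sqrt(n * p * (1 - p))

    def test_electrode_triples_rate(self):
        times = synth.generate_spike_train(1.0, 2000.0, 6)
        truth = synth.assign_amplitudes(times, synth.SpikeClassParams(), 6, rate=1.0,
                                        duration=2000.0)
        out = synth.apply_condition(truth, "electrode", seed=7)
        assert out.rate == pytest.approx(3.0)
        expected = 3 * truth.n_events
        assert abs(out.n_events - expected) < 3 * math.sqrt(2 * truth.n_events)
        assert np.all(np.diff(out.event_times) > 0)
        # original events are preserved
        assert np.isin(truth.event_times, out.event_times).all()

    @pytest.mark.parametrize("cond,label", [("ACh", "large"), ("ATP", "small")])
    def test_evoked_trials_create_events_only_in_windows(self, cond, label):
        truth = self._truth(n=5, seed=8, duration=100.0)
        eff = synth.EffectConfig(stim_windows=((10.0, 15.0), (40.0, 45.0)), evoked_rate=3.0)
        out = synth.apply_condition(truth, cond, eff, seed=9)
        new = np.setdiff1d(out.event_times, truth.event_times)
        inside = ((new >= 10) & (new <= 15)) | ((new >= 40) & (new <= 45))
        assert inside.all()
        new_mask = ~np.isin(out.event_times, truth.event_times)
        assert set(out.class_labels[new_mask]) <= {label}
        assert np.all(np.diff(out.event_times) > 0)

    def test_unknown_condition_lists_valid_names(self):
        truth = self._truth(n=5, seed=10, duration=100.0)
        with pytest.raises(ValueError, match="TTx.*Cd.*ML218"):
            synth.apply_condition(truth, "nifedipine")

    @pytest.mark.parametrize("cond", ["TTx", "Cd", "ML218"])
    def test_transforms_never_create_events(self, cond):
        truth = self._truth(n=100, seed=11)
        out = synth.apply_condition(truth, cond, seed=12)
        assert out.n_events <= truth.n_events
        assert np.isin(out.event_times, truth.event_times).all()
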