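"""Rates, ISI CV, Jarque-Bera multimodality machinery, normalization,
regression, activity index and condition tests."""

import math

import numpy as np
import pytest
import scipy.stats as sst

from gradespike import stats, synth


class TestRateAndCv:
    def test_regular_train(self):
        rate, cv = stats.rate_and_cv(np.array([1.0, 2, 3, 4]), 10.0)
        assert rate == pytest.approx(0.4)
        assert cv == pytest.approx(0.0, abs=1e-12)

    def test_too_few_events_flagged(self):
        rate, cv = stats.rate_and_cv(np.array([1.0, 2.0]), 10.0)
        assert rate == pytest.approx(0.2)
        assert math.isnan(cv)

    def test_nonmonotone_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            stats.rate_and_cv(np.array([1.0, 3.0, 2.0]), 10.0)

    def test_exponential_isis_cv_near_one(self, rng):
        # analytic: exponential ISIs have CV exactly 1
        isis = rng.exponential(2.0, 10_000)
        times = np.cumsum(isis)
        _, cv = stats.rate_and_cv(times, times[-1] + 1)
        assert abs(cv - 1.0) < 3 * 1.0 / math.sqrt(10_000)

    def test_cv_invariant_under_time_dilation(self, rng):
        times = np.cumsum(rng.exponential(1.0, 500))
        _, cv1 = stats.rate_and_cv(times, times[-1] + 1)
        _, cv2 = stats.rate_and_cv(7.3 * times, 7.3 * (times[-1] + 1))
        assert cv1 == pytest.approx(cv2, rel=1e-12)


class TestJarqueBera:
    def test_symmetric_mesokurtic_sample_near_zero(self):
        # standard-normal quantiles: skewness 0 by symmetry, kurtosis ~3
        q = sst.norm.ppf(np.linspace(0.005, 0.995, 199))
        assert stats.jarque_bera(q) < 1.0

    def test_formula_vs_bruteforce_moments(self):
        x = np.array([0, 0, 0, 1, 1, 1, 2, 2, 2], dtype=float)
        n = len(x)
        mu = sum(x) / n
        m2 = sum((v - mu) ** 2 for v in x) / n
        m3 = sum((v - mu) ** 3 for v in x) / n
        m4 = sum((v - mu) ** 4 for v in x) / n
        s = m3 / m2**1.5
        k = m4 / m2**2
        expected = n / 6 * (s**2 + (k - 3) ** 2 / 4)
        assert stats.jarque_bera(x) == pytest.approx(expected, abs=1e-12)

    def test_matches_scipy_reference(self, rng):
        x = rng.normal(size=500)
        ours = stats.jarque_bera(x)
        ref = sst.jarque_bera(x).statistic
        assert ours == pytest.approx(ref, rel=1e-10)

    def test_asymptotic_chi2_distribution(self, rng):
        # large-n JB approaches chi^2 with 2 df; check the upper tail
        jbs = [stats.jarque_bera(rng.standard_normal(5000)) for _ in range(400)]
        frac = np.mean(np.array(jbs) > sst.chi2.ppf(0.95, 2))
        assert abs(frac - 0.05) < 3 * math.sqrt(0.05 * 0.95 / 400)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="n >= 8"):
            stats.jarque_bera(np.arange(5.0))
        with pytest.raises(ValueError, match="zero-variance"):
            stats.jarque_bera(np.full(20, 2.0))


class TestCriticalValues:
    def test_determinism(self):
        a = stats.jb_critical_value(30, replicates=5000, seed=3)
        b = stats.jb_critical_value(30, replicates=5000, seed=3)
        assert a == b

    def test_large_n_approaches_chi2_quantile(self):
        crit = stats.jb_critical_value(10_000, replicates=20_000, seed=1)
        assert crit == pytest.approx(sst.chi2.ppf(0.95, 2), abs=0.35)

    def test_null_rejection_rate_calibrated(self, rng):
        n, cells = 50, 400
        crit = stats.jb_critical_value(n, replicates=20_000, seed=2)
        hits = sum(stats.jarque_bera(rng.standard_normal(n)) > crit for _ in range(cells))
        assert abs(hits / cells - 0.05) < 3 * math.sqrt(0.05 * 0.95 / cells)

    def test_null_table_caches(self):
        table = stats.NullTable(replicates=2000, seed=0)
        v1 = table.critical(20)
        assert 20 in table.values
        assert table.critical(20) == v1


class TestMultimodality:
    def test_two_point_mixture_flagged(self):
        # balanced two-point sample: kurtosis 1 -> JB = n/6 far above critical
        amps = np.array([0.3, 1.5] * 25)
        table = stats.NullTable(replicates=5000, seed=1)
        assert stats.multimodality_flag(amps, table) is True

    def test_small_sample_indeterminate(self):
        table = stats.NullTable(replicates=2000, seed=1)
        assert stats.multimodality_flag(np.arange(5.0), table) is None

    def test_normal_samples_rarely_flagged(self, rng):
        table = stats.NullTable(replicates=10_000, seed=4)
        flags = [
            stats.multimodality_flag(rng.standard_normal(50), table) for _ in range(100)
        ]
        assert sum(flags) <= 13  # ~5% expected; 3-sigma binomial headroom


class TestNormalization:
    def _cells(self):
        rng = np.random.default_rng(0)
        return {
            f"c{i}": {
                "control": rng.lognormal(0.0, 0.4, 40) * (i + 1),
                "Cd": rng.lognormal(-1.0, 0.3, 40) * (i + 1),
            }
            for i in range(6)
        }

    def test_control_pool_has_unit_per_cell_mean(self):
        cells = self._cells()
        pooled = stats.normalize_amplitudes(cells)
        for cid, conds in cells.items():
            np.testing.assert_allclose(
                np.mean(conds["control"] / np.mean(conds["control"])), 1.0
            )
        assert pooled["control"].size == 240

    def test_within_cell_ratios_unchanged(self):
        cells = self._cells()
        pooled = stats.normalize_amplitudes(cells)
        raw = cells["c0"]["control"]
        norm = pooled["control"][:40]
        np.testing.assert_allclose(norm / norm[0], raw / raw[0], rtol=1e-12)

    def test_cell_without_control_excluded(self, caplog):
        import logging

        cells = self._cells()
        cells["orphan"] = {"Cd": np.ones(10)}
        with caplog.at_level(logging.WARNING):
            pooled = stats.normalize_amplitudes(cells)
        assert pooled["Cd"].size == 240  # orphan contributed nothing
        assert any("no 'control'" in r.message for r in caplog.records)

    def test_cd_transform_loses_upper_mode(self):
        # generator truth: Cd reassigns large-class events to small amplitudes,
        # so the pooled normalized distributions must differ (KS at alpha=0.01)
        rng = np.random.default_rng(3)
        cells = {}
        for i in range(10):
            times = synth.generate_spike_train(0.5, 200.0, rng)
            pre = synth.assign_amplitudes(times, synth.SpikeClassParams(), rng)
            post = synth.apply_condition(pre, "Cd", seed=rng)
            cells[f"c{i}"] = {
                "control": pre.true_amplitudes, "Cd": post.true_amplitudes
            }
        pooled = stats.normalize_amplitudes(cells)
        res = stats.compare_conditions(pooled["control"], pooled["Cd"], "distribution")
        assert res["p_value"] < 0.01
        # upper mode gone: the treated pool has almost no mass above 2x the mean
        assert np.mean(pooled["Cd"] > 2.0) < 0.01 < np.mean(pooled["control"] > 2.0)


class TestPairedRegression:
    def test_exact_line(self):
        x = np.arange(1.0, 11.0)
        slope, intercept, r2 = stats.paired_regression(x, 2 * x)
        assert slope == pytest.approx(2.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_r2_invariant_to_affine_rescaling(self, rng):
        x = rng.normal(size=100)
        y = 1.5 * x + rng.normal(0, 0.5, 100)
        _, _, r2 = stats.paired_regression(x, y)
        _, _, r2b = stats.paired_regression(3 * x - 7, 0.1 * y + 2)
        assert r2 == pytest.approx(r2b, rel=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            stats.paired_regression(np.ones(10), np.arange(10.0))
        with pytest.raises(ValueError, match="3 matched pairs"):
            stats.paired_regression(np.arange(2.0), np.arange(2.0))


class TestActivityIndex:
    def test_no_events_zero(self):
        assert stats.activity_index(np.empty(0), 100.0) == 0.0

    def test_amplitude_sum_rate(self):
        assert stats.activity_index(np.ones(10), 100.0) == pytest.approx(0.1)

    def test_electrode_condition_triples_index(self):
        # generator truth: rate x3 with the same amplitude distribution
        rng = np.random.default_rng(6)
        idx_base, idx_elec = [], []
        for rep in range(40):
            times = synth.generate_spike_train(0.148, 600.0, rng)
            truth = synth.assign_amplitudes(times, synth.SpikeClassParams(), rng,
                                            rate=0.148, duration=600.0)
            elec = synth.apply_condition(truth, "electrode", seed=rng)
            idx_base.append(stats.activity_index(truth.true_amplitudes, 600.0))
            idx_elec.append(stats.activity_index(elec.true_amplitudes, 600.0))
        ratio = np.mean(idx_elec) / np.mean(idx_base)
        assert abs(ratio - 3.0) < 3 * np.std(np.array(idx_elec) / np.mean(idx_base)) / math.sqrt(40)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            stats.activity_index(np.ones(3), 0.0)


class TestCompareConditions:
    def test_identical_paired_vectors_maximal_p(self):
        x = np.arange(10.0)
        res = stats.compare_conditions(x, x, "paired")
        assert res["p_value"] == 1.0

    def test_unpaired_design_detects_shift(self, rng):
        a = rng.normal(0, 1, 30)
        b = rng.normal(2, 1, 30)
        res = stats.compare_conditions(a, b, "unpaired")
        assert res["p_value"] < 0.001

    def test_pairing_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matched"):
            stats.compare_conditions(np.arange(10.0), np.arange(8.0), "paired")
        with pytest.raises(ValueError, match="unknown design"):
            stats.compare_conditions(np.arange(10.0), np.arange(10.0), "anova")

    def test_summary_reports_median_iqr(self):
        res = stats.compare_conditions(np.arange(10.0), np.arange(10.0) + 1, "paired")
        assert "median" in res["pre_summary"]
        assert res["pre_median"] == pytest.approx(4.5)
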