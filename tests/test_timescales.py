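"""Half-life fitting, shuffle nulls and group comparison tests."""

import numpy as np
import pandas as pd
import pytest

from ethokit import (
    MetricCurve,
    compare_sessions,
    fit_half_life,
    generate_markov_labels,
    make_repertoire,
    metric_curve,
    shuffle_null,
)
from ethokit.timescales import pairwise_session_ami, partialled_ttest, two_way_anova
from ethokit.transitions import compress_runs


class TestFitHalfLife:
    def test_noiseless_exact(self):
        lags = np.arange(1, 201)
        b = -np.log(2) / 30
        y = 1.0 * np.exp(b * lags) + 0.05
        fit = fit_half_life(MetricCurve(lags, y))
        assert fit.half_life == pytest.approx(30.0, abs=1e-6)
        assert fit.a == pytest.approx(1.0, abs=1e-6)
        assert fit.c == pytest.approx(0.05, abs=1e-6)

    def test_amplitude_does_not_change_half_life(self):
        lags = np.arange(1, 101)
        b = -np.log(2) / 15
        f1 = fit_half_life(MetricCurve(lags, 1.0 * np.exp(b * lags) + 0.02))
        f2 = fit_half_life(MetricCurve(lags, 2.0 * np.exp(b * lags) + 0.02))
        assert f1.half_life == pytest.approx(f2.half_life, rel=1e-6)

    def test_noisy_recovery_within_10pct(self):
        """Median recovered half-life within 10% at noise sd 0.01."""
        rng = np.random.default_rng(0)
        lags = np.arange(1, 201)
        b = -np.log(2) / 30
        errs = []
        for _ in range(100):
            y = np.exp(b * lags) + 0.05 + rng.normal(0, 0.01, lags.size)
            fit = fit_half_life(MetricCurve(lags, y))
            errs.append(abs(fit.half_life - 30) / 30)
        assert np.median(errs) <= 0.10

    def test_flat_curve_degenerate(self):
        fit = fit_half_life(MetricCurve(np.arange(1, 20), np.full(19, 0.3)))
        assert fit.degenerate
        assert fit.half_life is None

    def test_too_few_lags_rejected(self):
        with pytest.raises(ValueError):
            fit_half_life(MetricCurve(np.array([1, 2, 3]), np.array([3.0, 2, 1])))


class TestMetricCurve:
    @pytest.fixture(scope="class")
    def planted_runs(self):
        rep = make_repertoire(seed=1)
        labels, _ = generate_markov_labels(rep, 200000, seed=2)
        return compress_runs(labels)

    def test_modularity_decays_with_lag(self, planted_runs):
        from scipy.stats import spearmanr

        lags = [1, 2, 3, 5, 8, 12, 20, 35, 60, 100]
        curve = metric_curve(planted_runs, lags, metric="modularity")
        rho, _ = spearmanr(curve.lags, curve.values)
        assert rho < 0

    def test_stability_high_in_slow_chain(self):
        rep = make_repertoire(within_module_prob=0.95, seed=3)
        labels, _ = generate_markov_labels(rep, 200000, seed=4)
        runs = compress_runs(labels)
        curve = metric_curve(runs, [1, 2, 3, 4], metric="stability")
        assert curve.values[0] > 0.8

    def test_iid_sequence_inside_null_band(self):
        rng = np.random.default_rng(5)
        seq = rng.integers(0, 12, 30000)
        runs = compress_runs(seq)
        null = shuffle_null(runs, n=30, seed=6)
        curve = metric_curve(runs, [1, 5, 20], metric="modularity")
        hi = np.quantile(null.permuted, 0.995)
        lo = np.quantile(null.permuted, 0.005)
        spread = hi - lo
        assert (curve.values <= hi + spread).all()


class TestShuffleNull:
    def test_planted_structure_minimal_p(self):
        rep = make_repertoire(seed=7)
        labels, _ = generate_markov_labels(rep, 100000, seed=8)
        runs = compress_runs(labels)
        null = shuffle_null(runs, n=100, seed=9)
        assert null.p_value == pytest.approx(1 / 101)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        runs = compress_runs(rng.integers(0, 6, 5000))
        n1 = shuffle_null(runs, n=20, seed=11)
        n2 = shuffle_null(runs, n=20, seed=11)
        np.testing.assert_array_equal(n1.permuted, n2.permuted)

    def test_invalid_n_rejected(self):
        runs = compress_runs(np.array([0, 1, 0, 1]))
        with pytest.raises(ValueError):
            shuffle_null(runs, n=0)


class TestCompareSessions:
    def _session_table(self, rng, subj_effect=0.0):
        rows = []
        for subj, base in (("A", 0.4 + subj_effect), ("B", 0.4)):
            for task in ("OFF", "ON"):
                for rep in range(3):
                    rows.append(
                        {"subject": subj, "task": task, "value": base + rng.normal(0, 0.02)}
                    )
        return pd.DataFrame(rows)

    def test_anova_detects_subject_effect(self):
        rng = np.random.default_rng(1)
        hits = 0
        for _ in range(20):
            tbl = two_way_anova(self._session_table(rng, subj_effect=0.15))
            if tbl.loc["C(subject)", "PR(>F)"] < 0.05 and tbl.loc["C(task)", "PR(>F)"] >= 0.05:
                hits += 1
        assert hits >= 18

    def test_anova_null_calibrated(self):
        rng = np.random.default_rng(2)
        false_pos = 0
        for _ in range(40):
            tbl = two_way_anova(self._session_table(rng))
            if tbl.loc["C(subject)", "PR(>F)"] < 0.05:
                false_pos += 1
        assert false_pos <= 8  # ~5% nominal, binomial slack

    def test_anova_needs_two_levels(self):
        df = pd.DataFrame({"subject": ["A"] * 4, "task": ["x", "x", "y", "y"], "value": [1.0, 2, 3, 4]})
        with pytest.raises(ValueError):
            two_way_anova(df)

    def test_pairwise_ami_diagonal_one(self):
        parts = {
            "s1": {i: i % 3 for i in range(12)},
            "s2": {i: i % 3 for i in range(12)},
            "s3": {i: i % 4 for i in range(12)},
        }
        amis, pvals = pairwise_session_ami(parts, n_permutations=20, seed=3)
        assert (np.diag(amis.values) == 1.0).all()
        assert amis.loc["s1", "s2"] == pytest.approx(1.0)

    def test_partialled_ttest_detects_group_difference(self):
        rng = np.random.default_rng(4)
        rows = []
        for grp, base in (("within", 0.8), ("between", 0.5)):
            for task_pair in ("OFF-OFF", "ON-ON"):
                nudge = 0.1 if task_pair == "ON-ON" else 0.0
                for _ in range(10):
                    rows.append(
                        {"group": grp, "task_pair": task_pair, "ami": base + nudge + rng.normal(0, 0.05)}
                    )
        res = partialled_ttest(pd.DataFrame(rows), "group", "task_pair")
        assert res["p"] < 0.001
        assert res["t"] < 0 or res["t"] > 0

    def test_dispatch(self):
        rng = np.random.default_rng(5)
        tbl = compare_sessions(self._session_table(rng), comparison="anova")
        assert "PR(>F)" in tbl.columns
        with pytest.raises(ValueError):
            compare_sessions(None, comparison="nope")
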