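import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from phredlogit import evaluation
from phredlogit.evaluation import (
    calibration_table,
    empirical_discrimination_power,
    expected_discrimination_power,
    observed_score,
    quench_density,
    roc_and_pr,
)


class TestObservedScore:
    @pytest.mark.parametrize("err,corr,q", [(1, 999, 30.0), (10, 990, 20.0)])
    def test_known_points(self, err, corr, q):
        assert observed_score(err, corr) == pytest.approx(q)

    def test_equal_counts(self):
        assert observed_score(7, 7) == pytest.approx(3.0103, abs=1e-4)

    def test_zero_errors_is_infinite(self):
        assert observed_score(0, 100) == np.inf

    def test_empty_bin_rejected(self):
        with pytest.raises(ValueError):
            observed_score(0, 0)


class TestCalibrationTable:
    def test_perfectly_calibrated_bin(self):
        q = np.full(1000, 30)
        labels = np.ones(1000, int)
        labels[0] = 0
        tab = calibration_table(q, labels)
        assert len(tab) == 1
        assert tab.q_obs.iloc[0] == pytest.approx(30.0)

    def test_all_correct_gives_inf(self):
        tab = calibration_table([20, 20, 25], [1, 1, 1])
        assert np.all(np.isinf(tab.q_obs))

    def test_counts_partition_bases(self):
        q = np.r_[np.full(30, 10), np.full(70, 20)]
        labels = np.r_[np.zeros(10), np.ones(90)].astype(int)
        tab = calibration_table(q, labels)
        assert (tab.n_err + tab.n_corr).sum() == 100

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            calibration_table([], [])


def brute_force_power(scores, labels, r):
    """Oracle: check every prefix of the stable descending-score order."""
    order = np.argsort(-np.asarray(scores, float), kind="stable")
    err = (np.asarray(labels)[order] == 0).astype(float)
    best = 0
    for k in range(1, len(scores) + 1):
        if err[:k].mean() < r:
            best = k
    return best / len(scores)


class TestEmpiricalPower:
    def test_worked_example(self):
        # descending scores; prefix of 9 has error rate 1/9 < 0.15, full 0.2
        scores = np.arange(10, 0, -1)
        labels = 1 - np.array([0, 0, 0, 0, 1, 0, 0, 0, 0, 1])
        assert empirical_discrimination_power(scores, labels, 0.15) == 0.9

    def test_all_correct_is_one(self):
        assert empirical_discrimination_power([3, 2, 1], [1, 1, 1], 0.01) == 1.0

    def test_leading_error_gives_zero(self):
        scores = np.arange(10, 0, -1)
        labels = np.ones(10, int)
        labels[0] = 0
        assert empirical_discrimination_power(scores, labels, 0.05) == 0.0

    def test_r_domain(self):
        with pytest.raises(ValueError):
            empirical_discrimination_power([1], [1], 1.5)

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_prefix_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(1, 200)
        scores = rng.choice(np.arange(40), size=n).astype(float)
        labels = (rng.random(n) > 0.1).astype(int)
        r = rng.uniform(0.01, 0.5)
        assert empirical_discrimination_power(scores, labels, r) == \
            pytest.approx(brute_force_power(scores, labels, r))

    def test_monotone_in_r(self):
        rng = np.random.default_rng(1)
        scores = rng.random(500)
        labels = (rng.random(500) > 0.05).astype(int)
        powers = [empirical_discrimination_power(scores, labels, r)
                  for r in np.linspace(0.005, 0.3, 40)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))


class TestExpectedPower:
    def test_all_below_threshold(self):
        assert expected_discrimination_power([0.02] * 5, 0.04) == 1.0

    def test_all_above_threshold(self):
        assert expected_discrimination_power([0.08] * 5, 0.04) == 0.0

    def test_enumerated_example(self):
        # prefix means: 0.01, 0.015, 0.11 -> largest below 0.05 is 2 of 3
        assert expected_discrimination_power([0.01, 0.02, 0.30], 0.05) == \
            pytest.approx(2 / 3)


def concordance_auc(scores, labels):
    """Oracle: concordant-pair counting with ties worth 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum()
    ties = (pos[:, None] == neg[None, :]).sum()
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


class TestRoc:
    def test_perfect_separation(self):
        assert roc_and_pr([0.9, 0.6, 0.4], [1, 1, 0]).auc == 1.0

    def test_all_ties_is_half(self):
        assert roc_and_pr([1, 1, 1, 1], [1, 0, 1, 0]).auc == pytest.approx(0.5)

    def test_concordant_pairs_example(self):
        assert roc_and_pr([0.9, 0.4, 0.6], [1, 0, 1]).auc == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_and_pr([1, 2], [1, 1])

    @given(st.integers(0, 10_000))
    def test_auc_equals_concordance_counting(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 200)
        scores = rng.choice(np.arange(15), size=n).astype(float)
        labels = (rng.random(n) > 0.3).astype(int)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        roc = roc_and_pr(scores, labels)
        assert roc.auc == pytest.approx(concordance_auc(scores, labels))
        assert np.all(np.diff(roc.fpr) >= 0)
        assert np.all(np.diff(roc.tpr) >= 0)


class TestQuenchDensity:
    def test_quenched_tile_has_low_t_after_g(self, quenched_fixture):
        qd = quench_density(quenched_fixture.tile)
        others = [qd.means[x] for x in "ACT"]
        assert qd.means["G"] < min(others)

    def test_no_quench_null_has_similar_means(self):
        # phasing also moves the context means (carry-over adds to the same
        # channel when the previous base repeats), so the null switches off
        # both mechanisms and leaves only noise
        from dataclasses import replace

        from phredlogit import simulator

        cfg = replace(simulator.FIXTURES["quenched"], quench=1.0,
                      phasing=0.0, g_phasing_delta=0.0, seed=505)
        res = simulator.simulate_tile(cfg)
        qd = quench_density(res.tile)
        spread = max(qd.means.values()) - min(qd.means.values())
        assert spread < 0.02

    def test_densities_integrate_to_one(self, quenched_fixture):
        qd = quench_density(quenched_fixture.tile)
        for dens in qd.densities.values():
            assert np.trapezoid(dens, qd.grid) == pytest.approx(1.0, abs=1e-3)

    def test_window_must_be_covered(self, clean_fixture):
        with pytest.raises(ValueError):
            quench_density(clean_fixture.tile, cycles=(8, 40))


def test_discrimination_curve_includes_expected_power():
    rng = np.random.default_rng(5)
    eps = rng.uniform(1e-4, 0.05, size=2_000)
    labels = (rng.random(2_000) > eps).astype(int)
    scores = -10 * np.log10(eps)
    curve = evaluation.discrimination_curve(scores, labels,
                                            r_grid=[0.001, 0.01, 0.05],
                                            error_probs=eps)
    assert list(curve.columns) == ["r", "p_emp", "p_exp"]
    assert curve.p_emp.is_monotonic_increasing
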