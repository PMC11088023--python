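from itertools import combinations

import numpy as np
import pytest

from dynpet.diag_stats import (
    classify_at_cutoff,
    cohort_report,
    compare_groups,
    roc_analysis,
)
from dynpet.framing import ValidationError
from dynpet.synthetic import benign_ki_range_cohort, simulate_cohort


def exact_ranksum_p(a, b):
    """Enumeration oracle: two-sided p of the rank-sum statistic under the
    exact permutation null."""
    pooled = np.concatenate([a, b])
    n = len(a)
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    obs = ranks[:n].sum()
    stats = [
        sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n)
    ]
    stats = np.array(stats)
    mean = stats.mean()
    return np.mean(np.abs(stats - mean) >= abs(obs - mean) - 1e-12)


def pair_counting_auc(scores, y):
    """Brute-force Mann-Whitney AUC with half credit for ties."""
    pos = scores[y == 1]
    neg = scores[y == 0]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        x = list(range(1, 11))
        res = compare_groups(x, x)
        assert res.p_value >= 0.99

    def test_wilcoxon_matches_exact_enumeration(self):
        a, b = [1.0, 2.0, 3.0], [4.0, 5.0, 6.0]
        res = compare_groups(a, b, test="wilcoxon")
        assert res.test == "wilcoxon"
        assert res.p_value == pytest.approx(exact_ranksum_p(np.array(a), np.array(b)))
        assert res.p_value == pytest.approx(0.1)

    def test_known_effect_picks_t_branch(self):
        # seed chosen so both samples pass the Shapiro gate (a 5%-level
        # gate falsely rejects genuinely normal draws for some seeds)
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 200)
        b = rng.normal(1, 1, 200)
        res = compare_groups(a, b)
        assert res.test == "t_test"
        assert res.p_value < 1e-10
        assert res.summary_a["mean"] == pytest.approx(a.mean())

    def test_skewed_data_picks_wilcoxon(self):
        rng = np.random.default_rng(2)
        a = np.exp(rng.normal(0, 1.5, 100))
        b = np.exp(rng.normal(0.5, 1.5, 100))
        res = compare_groups(a, b)
        assert res.test == "wilcoxon"
        assert res.summary_a["median"] == pytest.approx(np.median(a))

    def test_small_groups_rejected(self):
        with pytest.raises(ValidationError):
            compare_groups([1, 2], [3, 4, 5])


class TestRocAnalysis:
    def test_perfect_separation(self):
        scores = np.array([1, 2, 3, 10, 11, 12], float)
        y = np.array([0, 0, 0, 1, 1, 1])
        res = roc_analysis(scores, y, n_boot=100, seed=0)
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3 < res.cutoff < 10

    def test_small_example(self):
        res = roc_analysis([1, 4, 2, 3], [0, 1, 1, 0], n_boot=100, seed=0)
        assert res.auc == pytest.approx(0.75)

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = rng.integers(6, 25)
            scores = rng.integers(0, 10, n).astype(float)  # many ties
            y = rng.integers(0, 2, n)
            if y.min() == y.max():
                continue
            res = roc_analysis(scores, y, n_boot=100, seed=0)
            bf = pair_counting_auc(scores, y)
            assert res.auc == pytest.approx(max(bf, 1 - bf), abs=1e-12)

    def test_cutoff_between_unique_scores(self):
        rng = np.random.default_rng(9)
        scores = rng.normal(0, 1, 40)
        y = (scores + rng.normal(0, 1, 40) > 0).astype(int)
        res = roc_analysis(scores, y, n_boot=100, seed=0)
        uniq = np.unique(scores)
        assert res.cutoff not in uniq
        if np.isfinite(res.cutoff):
            below = uniq[uniq < res.cutoff]
            above = uniq[uniq > res.cutoff]
            assert len(below) and len(above)
            # midpoint convention: equidistant from the two neighbours
            assert res.cutoff == pytest.approx((below.max() + above.min()) / 2)

    def test_bootstrap_deterministic_and_contains_auc(self):
        rng = np.random.default_rng(10)
        scores = rng.normal(0, 1, 60)
        y = (scores + rng.normal(0, 1.5, 60) > 0).astype(int)
        a = roc_analysis(scores, y, n_boot=300, seed=5)
        b = roc_analysis(scores, y, n_boot=300, seed=5)
        assert a.ci == b.ci
        assert a.ci[0] <= a.auc <= a.ci[1]

    def test_single_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_analysis([1, 2, 3], [1, 1, 1], n_boot=100)


class TestClassifyAtCutoff:
    def test_perfect_threshold(self):
        sens, spec, counts = classify_at_cutoff(
            [1, 2, 8, 9], [0, 0, 1, 1], 5.0, "higher"
        )
        assert sens == 1.0 and spec == 1.0

    def test_cutoff_below_everything(self):
        sens, spec, _ = classify_at_cutoff([1, 2, 8, 9], [0, 0, 1, 1], -1.0, "higher")
        assert sens == 1.0 and spec == 0.0

    def test_counts_conserve(self):
        rng = np.random.default_rng(2)
        scores = rng.normal(0, 1, 50)
        y = rng.integers(0, 2, 50)
        y[0], y[1] = 0, 1
        _, _, c = classify_at_cutoff(scores, y, 0.3, "higher")
        assert c["tp"] + c["fn"] == y.sum()
        assert c["tn"] + c["fp"] == (1 - y).sum()

    def test_benign_range_cohort_specificity_bound(self):
        """A benign cohort spanning 0.0002-0.0246 ml/g/min is entirely below
        the 0.0250 decision threshold."""
        ben = benign_ki_range_cohort(23)
        mal = simulate_cohort(seed=5)
        mk = mal[mal.malignancy == "malignant"].ki.to_numpy()
        scores = np.concatenate([ben, mk])
        labels = np.concatenate([np.zeros(ben.size), np.ones(mk.size)])
        _, spec, _ = classify_at_cutoff(scores, labels, 0.0250, "higher")
        assert spec >= 0.999


class TestCohortReport:
    def test_identical_groups_null(self):
        df = simulate_cohort(seed=3)
        half = df[df.malignancy == "malignant"].copy()
        half.loc[half.index[:62], "malignancy"] = "benign"
        half_b = half.copy()
        # duplicate one group into the other so distributions coincide
        a = half[half.malignancy == "benign"].copy()
        b = a.copy()
        b["malignancy"] = "malignant"
        both = __import__("pandas").concat([a, b], ignore_index=True)
        rep = cohort_report(both, "malignancy", n_boot=150)
        assert (rep.p_value > 0.9).all()
        assert ((rep.auc - 0.5).abs() < 0.05).all()

    def test_report_schema(self):
        rep = cohort_report(simulate_cohort(seed=1), "malignancy", n_boot=150)
        assert list(rep.columns) == [
            "parameter", "group_a", "group_b", "summary_a", "summary_b",
            "test", "p_value", "sensitivity", "specificity", "cutoff",
            "auc", "ci_low", "ci_high",
        ]
        assert list(rep.parameter) == ["suv_max", "k1", "k2", "k3", "ki"]

    def test_calibrated_cohort_signals(self):
        """Calibrated benign/malignant marginals separate on Ki and k2 but
        not on K1, echoing the clinical pattern."""
        rep = cohort_report(simulate_cohort(seed=1), "malignancy", n_boot=150)
        p = rep.set_index("parameter").p_value
        assert p["ki"] < 0.05 and p["k2"] < 0.05
        assert p["k1"] > 0.05
        auc = rep.set_index("parameter").auc
        assert 0.5 < auc["ki"] < 1.0

    def test_missing_labels_listed(self):
        df = simulate_cohort(seed=0)
        with pytest.raises(ValidationError, match="L0001"):
            cohort_report(df, "egfr", n_boot=150)
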