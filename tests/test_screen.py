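"""Distance statistic, threshold fitting, metrics, ROC AUC, pipeline."""

import itertools
import math

import numpy as np
import pytest

import gastrolayer as gl
from gastrolayer.errors import GastrolayerError
from gastrolayer.screen import ABNORMAL, NORMAL, ConfusionCounts


# Reference worked-example inputs: a stratified wall's proportion vector
# and the standard (normal-average) vector.
X_EXAMPLE = (0.358, 0.189, 0.116, 0.2, 0.137)


class TestStandardVector:
    def test_single_vector(self):
        x = np.array([0.3, 0.2, 0.2, 0.2, 0.1])
        assert gl.estimate_standard_vector([x]) == pytest.approx(x)

    def test_componentwise_mean_without_renormalization(self):
        a = [0.2] * 5
        b = [0.4, 0.2, 0.1, 0.2, 0.1]
        s = gl.estimate_standard_vector([a, b])
        assert s == pytest.approx([0.3, 0.2, 0.15, 0.2, 0.15])
        # means of vectors not summing to 1 are not rescaled
        s2 = gl.estimate_standard_vector([gl.STANDARD_VECTOR])
        assert s2.sum() == pytest.approx(0.999)

    def test_empty_rejected(self):
        with pytest.raises(GastrolayerError):
            gl.estimate_standard_vector([])


class TestDistance:
    def test_zero_at_standard(self):
        assert gl.distance(gl.STANDARD_VECTOR, gl.STANDARD_VECTOR) == 0.0

    def test_fifth_coordinate_degenerate(self):
        s = np.asarray(gl.STANDARD_VECTOR)
        x = s.copy()
        x[4] += 0.05
        assert gl.distance(x, s) == 0.0
        assert gl.distance(x, s, include_fifth_term=True) > 0.0

    def test_worked_example_matches_brute_force(self):
        d = gl.distance(X_EXAMPLE, gl.STANDARD_VECTOR)
        brute = math.sqrt(sum((x - s) ** 2
                              for x, s in zip(X_EXAMPLE[:4], gl.STANDARD_VECTOR[:4])))
        assert d == pytest.approx(brute, abs=1e-12)
        assert d == pytest.approx(0.1144, abs=5e-4)

    def test_pseudometric_properties(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            x, y, z = (rng.dirichlet(np.ones(5)) for _ in range(3))
            assert gl.distance(x, y) == pytest.approx(gl.distance(y, x), abs=1e-14)
            assert gl.distance(x, x) == 0.0
            assert gl.distance(x, z) <= gl.distance(x, y) + gl.distance(y, z) + 1e-14


class TestSplitCohort:
    class Rec:
        def __init__(self, label):
            self.label = label

    def make(self, n_norm, n_abn):
        return [self.Rec(NORMAL)] * 0 + [self.Rec(NORMAL) for _ in range(n_norm)] + \
               [self.Rec(ABNORMAL) for _ in range(n_abn)]

    def test_seventy_thirty(self):
        records = self.make(6, 4)
        train, test = gl.split_cohort(records, 0.7, seed=1)
        assert len(train) == 7 and len(test) == 3

    def test_deterministic_partition(self):
        records = self.make(8, 6)
        a = gl.split_cohort(records, 0.7, seed=5)
        b = gl.split_cohort(records, 0.7, seed=5)
        assert [id(r) for r in a[0]] == [id(r) for r in b[0]]
        ids = {id(r) for r in records}
        assert {id(r) for r in a[0]} | {id(r) for r in a[1]} == ids
        assert {id(r) for r in a[0]} & {id(r) for r in a[1]} == set()

    def test_class_must_survive_split(self):
        with pytest.raises(GastrolayerError):
            gl.split_cohort(self.make(9, 1), 0.7, seed=0)


def sweep_accuracy(d, labels, thresholds):
    """Brute-force accuracy of "abnormal iff d >= t" over given thresholds."""
    y = np.array([1 if l == ABNORMAL else 0 for l in labels])
    d = np.asarray(d)
    return max(float(((d >= t).astype(int) == y).mean()) for t in thresholds)


class TestFitThreshold:
    def test_separable_example(self):
        t = gl.fit_threshold([0.01, 0.02, 0.5, 0.6], [NORMAL, NORMAL, ABNORMAL, ABNORMAL])
        assert t == pytest.approx(0.26)

    def test_interleaved_gives_majority_accuracy(self):
        d = [0.1, 0.2, 0.3, 0.4, 0.5, 0.6]
        labels = [ABNORMAL, NORMAL, ABNORMAL, NORMAL, ABNORMAL, NORMAL]
        t = gl.fit_threshold(d, labels)
        y = np.array([1, 0, 1, 0, 1, 0])
        acc = (((np.array(d) >= t).astype(int)) == y).mean()
        assert acc == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(GastrolayerError):
            gl.fit_threshold([0.1, 0.2], [NORMAL, NORMAL])

    def test_matches_exhaustive_sweep(self):
        """Chosen accuracy equals a 1000-point brute-force sweep (oracle)."""
        rng = np.random.default_rng(42)
        for _ in range(100):
            n = int(rng.integers(2, 31))
            d = np.round(rng.random(n), 2)
            labels = [ABNORMAL if v else NORMAL for v in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                labels[0] = NORMAL if labels[0] == ABNORMAL else ABNORMAL
            t = gl.fit_threshold(d, labels)
            y = np.array([1 if l == ABNORMAL else 0 for l in labels])
            acc = float(((d >= t).astype(int) == y).mean())
            sweep = sweep_accuracy(d, labels, np.linspace(-0.1, 1.1, 1000))
            assert acc == pytest.approx(sweep, abs=1e-12)


class TestClassify:
    def setup_method(self):
        self.model = gl.ScreeningModel(threshold=0.1)

    def test_small_d_normal(self):
        assert gl.classify(0.0, self.model) == NORMAL

    def test_boundary_goes_to_abnormal(self):
        assert gl.classify(0.1, self.model) == ABNORMAL

    def test_large_d_abnormal(self):
        assert gl.classify(1.0, self.model) == ABNORMAL


def metrics_direct(tp, tn, fp, fn):
    """Straight transcription of the metric formulas (test oracle)."""
    out = {}
    out["ACC"] = (tp + tn) / (tp + tn + fp + fn)
    out["SENS"] = tp / (tp + fn) if tp + fn else None
    out["SPEC"] = tn / (tn + fp) if tn + fp else None
    out["PPV"] = tp / (tp + fp) if tp + fp else None
    out["NPV"] = tn / (tn + fn) if tn + fn else None
    den = math.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    out["MCC"] = (tp * tn - fp * fn) / den if den else None
    p, r = out["PPV"], out["SENS"]
    out["F1"] = 2 * p * r / (p + r) if p is not None and r is not None and p + r else None
    return out


class TestComputeMetrics:
    def test_perfect_classifier(self):
        m = gl.compute_metrics(ConfusionCounts(tp=5, tn=5, fp=0, fn=0))
        assert m["ACC"] == m["MCC"] == m["F1"] == 1.0

    def test_balanced_coin_flip(self):
        m = gl.compute_metrics(ConfusionCounts(tp=1, tn=1, fp=1, fn=1))
        assert m["ACC"] == 0.5 and m["MCC"] == 0.0 and m["F1"] == 0.5

    def test_zero_denominator_flagged_not_zero(self):
        m = gl.compute_metrics(ConfusionCounts(tp=0, tn=3, fp=0, fn=2))
        assert m["PPV"] is None
        assert m["SPEC"] == 1.0

    def test_empty_table_rejected(self):
        with pytest.raises(GastrolayerError):
            gl.compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_agrees_with_direct_evaluation_on_random_tables(self):
        rng = np.random.default_rng(7)
        for _ in range(200):
            tp, tn, fp, fn = (int(v) for v in rng.integers(0, 20, 4))
            if tp + tn + fp + fn == 0:
                continue
            got = gl.compute_metrics(ConfusionCounts(tp, tn, fp, fn))
            want = metrics_direct(tp, tn, fp, fn)
            for key, val in want.items():
                if val is None:
                    assert got[key] is None
                else:
                    assert got[key] == pytest.approx(val, abs=1e-12)


def auc_pair_counting(d, labels):
    """Mann-Whitney oracle: correctly ordered pairs, half credit for ties."""
    pos = [v for v, l in zip(d, labels) if l == ABNORMAL]
    neg = [v for v, l in zip(d, labels) if l == NORMAL]
    total = 0.0
    for p, n in itertools.product(pos, neg):
        total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_separation(self):
        assert gl.roc_auc([0.1, 0.2, 0.8, 0.9],
                          [NORMAL, NORMAL, ABNORMAL, ABNORMAL]) == 1.0

    def test_all_ties_is_chance(self):
        assert gl.roc_auc([0.3] * 6, [NORMAL, ABNORMAL] * 3) == 0.5

    def test_three_of_four_pairs(self):
        assert gl.roc_auc([1, 2, 3, 4], [NORMAL, ABNORMAL, NORMAL, ABNORMAL]) == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(GastrolayerError):
            gl.roc_auc([0.1, 0.2], [NORMAL, NORMAL])

    def test_matches_pair_counting_oracle_up_to_n12(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            n = int(rng.integers(2, 13))
            d = rng.integers(0, 5, n).astype(float)  # integer grid forces ties
            labels = [ABNORMAL if v else NORMAL for v in rng.integers(0, 2, n)]
            if len(set(labels)) < 2:
                labels[0] = NORMAL if labels[0] == ABNORMAL else ABNORMAL
            assert gl.roc_auc(d, labels) == pytest.approx(
                auc_pair_counting(d, labels), abs=1e-12
            )


class TestEvaluatePipeline:
    def test_oracle_mode_distinct_templates_perfect(self):
        """Noise-free phantoms with well separated class templates are
        classified perfectly from truth masks."""
        base = gl.PhantomSpec(speckle_looks=None)
        cohort = gl.generate_cohort(8, 8, gl.AbnormalEffect((2, 1, 1, 1, 1)),
                                    seed=3, base_spec=base, jitter_scale=1e-4)
        report = gl.evaluate_pipeline(cohort, gl.PipelineConfig(seed=3))
        assert report.metrics["ACC"] == 1.0
        assert report.auc == 1.0
        assert report.n_excluded == 0

    def test_deterministic_given_seed(self):
        cohort = gl.generate_cohort(6, 6, seed=2)
        a = gl.evaluate_pipeline(cohort, gl.PipelineConfig(seed=2))
        b = gl.evaluate_pipeline(cohort, gl.PipelineConfig(seed=2))
        assert a.model.threshold == b.model.threshold
        assert a.metrics == b.metrics
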