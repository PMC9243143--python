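import itertools
import math

import numpy as np
import pytest

from eegsonify.evaluation import (bootstrap_kappa_ci, confusion_metrics,
                                  fleiss_kappa, kappa_ttest,
                                  labels_from_annotations, majority_vote,
                                  ratings_from_labels, roc_auc)
from eegsonify.io_formats import SeizureAnnotation


def _brute_force_kappa(ratings):
    """Independent oracle: expand each subject's votes into explicit labels
    and count agreeing rater pairs directly."""
    ratings = np.asarray(ratings, dtype=int)
    n, k = ratings.shape
    N = ratings[0].sum()
    agree = []
    for row in ratings:
        labels = [j for j in range(k) for _ in range(row[j])]
        pairs = list(itertools.combinations(labels, 2))
        agree.append(sum(a == b for a, b in pairs) / len(pairs))
    p = sum(agree) / n
    marg = ratings.sum(axis=0) / (n * N)
    pe = sum(m ** 2 for m in marg)
    if pe >= 1.0:
        return None
    return (p - pe) / (1 - pe)


class TestFleissKappa:
    def test_perfect_agreement(self):
        ratings = np.array([[3, 0], [0, 3], [3, 0], [0, 3]])
        assert fleiss_kappa(ratings).kappa == pytest.approx(1.0)

    def test_worked_binary_example(self):
        """3 raters, 4 subjects, votes (2,1,2,1) for category 1:
        p = 1/3, p_e = 1/2, kappa = -1/3."""
        ratings = np.array([[2, 1], [1, 2], [2, 1], [1, 2]])
        res = fleiss_kappa(ratings)
        assert res.p_obs == pytest.approx(1 / 3)
        assert res.p_exp == pytest.approx(1 / 2)
        assert res.kappa == pytest.approx(-1 / 3)

    def test_sd_and_ci_closed_form(self):
        """p = 0.8, p_e = 0.5, n = 79: SD = 0.8, half-width ~ 0.176."""
        p, pe, n = 0.8, 0.5, 79
        sd = math.sqrt(p * (1 - p)) / (1 - pe)
        assert sd == pytest.approx(0.8)
        half = 1.959963984540054 * sd / math.sqrt(n)
        assert half == pytest.approx(0.176, abs=5e-4)

    def test_ci_brackets_kappa(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, size=(40, 3))
        res = fleiss_kappa(ratings_from_labels(labels))
        assert res.ci_low <= res.kappa <= res.ci_high
        assert res.ci_high - res.kappa == pytest.approx(
            res.z * res.sd / math.sqrt(res.n))

    def test_degenerate_single_category(self):
        res = fleiss_kappa(np.array([[3, 0], [3, 0]]))
        assert not res.defined
        assert math.isnan(res.kappa)

    @pytest.mark.parametrize("n_subjects,n_raters", [(2, 2), (3, 3), (4, 4),
                                                     (6, 3)])
    def test_exhaustive_small_binary_matrices(self, n_subjects, n_raters):
        """Implementation equals the pair-enumeration oracle on every
        binary vote matrix of the given size."""
        for votes in itertools.product(range(n_raters + 1),
                                       repeat=n_subjects):
            ratings = np.array([[v, n_raters - v] for v in votes])
            oracle = _brute_force_kappa(ratings)
            res = fleiss_kappa(ratings)
            if oracle is None:
                assert not res.defined
            else:
                assert res.kappa == pytest.approx(oracle, abs=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.inter_rater import fleiss_kappa as sm_kappa
        rng = np.random.default_rng(4)
        labels = rng.integers(0, 2, size=(60, 4))
        ratings = ratings_from_labels(labels)
        assert fleiss_kappa(ratings).kappa == pytest.approx(
            sm_kappa(ratings), abs=1e-12)

    def test_bootstrap_overlaps_asymptotic(self):
        rng = np.random.default_rng(9)
        truth = rng.integers(0, 2, 120)
        noisy = [(truth ^ (rng.random(120) < 0.15)).astype(int)
                 for _ in range(3)]
        ratings = ratings_from_labels(np.column_stack(noisy))
        res = fleiss_kappa(ratings)
        lo, hi = bootstrap_kappa_ci(ratings, n_boot=2000, seed=2)
        assert lo <= res.ci_high and res.ci_low <= hi  # intervals overlap
        assert lo <= res.kappa <= hi


class TestKappaTtest:
    def test_equal_kappas(self):
        t, p = kappa_ttest(0.6, 0.5, 0.6, 0.7, 79)
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_worked_example(self):
        """kappa difference 0.1, SDs 0.8, n = 79: t ~ 0.786."""
        t, p = kappa_ttest(0.7, 0.8, 0.6, 0.8, 79)
        assert t == pytest.approx(0.1 / math.sqrt(1.28 / 79), abs=1e-12)
        assert t == pytest.approx(0.786, abs=5e-4)
        assert 0 < p < 1

    def test_antisymmetry(self):
        t1, p1 = kappa_ttest(0.8, 0.4, 0.5, 0.6, 50)
        t2, p2 = kappa_ttest(0.5, 0.6, 0.8, 0.4, 50)
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)


class TestConfusionMetrics:
    def test_survey_confusion_counts(self):
        """tp=42, fn=5, fp=7, tn=25 gives sensitivity 0.8936, specificity
        0.78125."""
        sens, spec = confusion_metrics(tp=42, fp=7, fn=5, tn=25)
        assert sens == pytest.approx(42 / 47)
        assert spec == pytest.approx(25 / 32)
        assert round(sens, 2) == 0.89
        assert round(spec, 2) == 0.78

    def test_perfect(self):
        assert confusion_metrics(10, 0, 0, 10) == (1.0, 1.0)

    def test_balanced_half(self):
        assert confusion_metrics(1, 1, 1, 1) == (0.5, 0.5)

    def test_missing_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(0, 3, 0, 5)


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0]) == 1.0

    def test_worked_pair_count(self):
        """scores (0.9, 0.8, 0.4, 0.3), labels (1, 0, 1, 0): 3 of 4
        positive-negative pairs correctly ranked."""
        assert roc_auc([0.9, 0.8, 0.4, 0.3], [1, 0, 1, 0]) == pytest.approx(0.75)

    def test_all_ties(self):
        assert roc_auc([0.5] * 6, [1, 1, 1, 0, 0, 0]) == pytest.approx(0.5)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])

    def test_equals_brute_force_pairs(self, rng):
        scores = rng.uniform(size=50)
        labels = rng.integers(0, 2, 50)
        labels[0], labels[1] = 0, 1
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        brute = np.mean([(1.0 if s > t else 0.5 if s == t else 0.0)
                         for s in pos for t in neg])
        assert roc_auc(scores, labels) == pytest.approx(brute, abs=1e-12)

    def test_equals_trapezoidal_roc_area(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = np.round(rng.uniform(size=200), 2)  # force ties
        labels = rng.integers(0, 2, 200)
        labels[:2] = [0, 1]
        assert roc_auc(scores, labels) == pytest.approx(
            roc_auc_score(labels, scores), abs=1e-12)


class TestMajorityVote:
    def test_all_empty(self):
        assert majority_vote(np.zeros((5, 3), dtype=int)).tolist() == [0] * 5

    def test_two_of_three(self):
        assert majority_vote(np.array([[1, 1, 0]])).tolist() == [1]
        assert majority_vote(np.array([[1, 0, 0]])).tolist() == [0]

    def test_from_annotation_objects(self):
        anns = []
        for rid, events_by_ann in [("r1", [[(5.0, 12.0)], [(5.0, 12.0)], []]),
                                   ("r2", [[], [], []])]:
            for i, evs in enumerate(events_by_ann):
                anns.append(SeizureAnnotation(rid, f"A{i}", evs))
        records, annotators, labels = labels_from_annotations(anns)
        assert records == ["r1", "r2"]
        assert majority_vote(labels).tolist() == [1, 0]
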