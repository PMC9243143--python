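"""Inter-rater agreement and classification metrics.

Implements the record-level evaluation machinery for seizure-presence
ratings: Fleiss' kappa with its asymptotic standard deviation and
confidence interval, a t-test for comparing two kappa distributions on
equally sized samples, sensitivity/specificity from a confusion matrix,
the rank (Mann-Whitney) ROC AUC, and majority-vote ground-truth pooling.

Kappa definitions
-----------------
For n subjects rated by N raters into k categories, with vote counts
n_ij, the chance-corrected agreement is

    kappa = (p - p_e) / (1 - p_e)

where p is the mean per-subject pairwise agreement
p_i = sum_j n_ij (n_ij - 1) / (N (N - 1)) and p_e = sum_j p_j^2 over the
category marginals p_j. The asymptotic standard deviation used for the
confidence interval is SD_kappa = sqrt(p (1 - p)) / (1 - p_e) and the
CI at level alpha is kappa ± z_(1-alpha/2) * SD_kappa / sqrt(n).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sstats

from .io_formats import SeizureAnnotation

__all__ = [
    "KappaResult",
    "ratings_from_labels",
    "fleiss_kappa",
    "bootstrap_kappa_ci",
    "kappa_ttest",
    "confusion_metrics",
    "roc_auc",
    "majority_vote",
    "labels_from_annotations",
]


@dataclass
class KappaResult:
    kappa: float
    p_obs: float
    p_exp: float
    sd: float
    ci_low: float
    ci_high: float
    n: int
    alpha: float = 0.05
    z: float = 1.959963984540054

    @property
    def defined(self) -> bool:
        return not math.isnan(self.kappa)


def ratings_from_labels(labels: np.ndarray, k: int = 2) -> np.ndarray:
    """Subjects x categories vote-count matrix from a subjects x raters
    array of integer category labels in [0, k)."""
    labels = np.asarray(labels, dtype=int)
    if labels.ndim != 2:
        raise ValueError("labels must be subjects x raters")
    n, N = labels.shape
    counts = np.zeros((n, k), dtype=int)
    for j in range(k):
        counts[:, j] = (labels == j).sum(axis=1)
    return counts


def fleiss_kappa(ratings: np.ndarray, alpha: float = 0.05) -> KappaResult:
    """Fleiss' kappa with asymptotic SD and CI from a vote-count matrix.

    ``ratings`` is subjects x categories; every row must sum to the same
    number of raters N >= 2. When all votes fall in one category the
    chance agreement p_e is 1 and kappa is undefined: the result carries
    NaN statistics rather than a misleading 0.
    """
    ratings = np.asarray(ratings, dtype=float)
    if ratings.ndim != 2 or ratings.shape[0] < 1:
        raise ValueError("ratings must be a non-empty 2-D count matrix")
    if np.any(ratings < 0) or np.any(ratings != np.round(ratings)):
        raise ValueError("ratings must be non-negative integer counts")
    row_sums = ratings.sum(axis=1)
    N = row_sums[0]
    if N < 2 or not np.all(row_sums == N):
        raise ValueError("every subject needs the same number (>=2) of raters")
    n = ratings.shape[0]

    p_i = (ratings * (ratings - 1)).sum(axis=1) / (N * (N - 1))
    p_obs = float(p_i.mean())
    marginals = ratings.sum(axis=0) / (n * N)
    p_exp = float(np.sum(marginals ** 2))

    z = float(sstats.norm.ppf(1 - alpha / 2))
    if p_exp >= 1.0:
        nan = float("nan")
        return KappaResult(nan, p_obs, p_exp, nan, nan, nan, n, alpha, z)
    kappa = (p_obs - p_exp) / (1.0 - p_exp)
    sd = math.sqrt(p_obs * (1.0 - p_obs)) / (1.0 - p_exp)
    half = z * sd / math.sqrt(n)
    return KappaResult(kappa, p_obs, p_exp, sd, kappa - half, kappa + half,
                       n, alpha, z)


def bootstrap_kappa_ci(ratings: np.ndarray, alpha: float = 0.05,
                       n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Percentile bootstrap CI for kappa, resampling subjects."""
    ratings = np.asarray(ratings)
    rng = np.random.default_rng(seed)
    n = ratings.shape[0]
    stats = []
    for _ in range(n_boot):
        sample = ratings[rng.integers(0, n, n)]
        res = fleiss_kappa(sample, alpha)
        if res.defined:
            stats.append(res.kappa)
    lo, hi = np.percentile(stats, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    return float(lo), float(hi)


def kappa_ttest(kappa1: float, sd1: float, kappa2: float, sd2: float,
                n: int) -> tuple[float, float]:
    """t-statistic and two-sided p-value for two kappas on n subjects each:

        t = (kappa1 - kappa2) / sqrt((SD1^2 + SD2^2) / n)

    referred to a Student t distribution with n degrees of freedom.
    """
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be non-negative")
    if n < 2:
        raise ValueError("need n >= 2")
    denom = math.sqrt((sd1 ** 2 + sd2 ** 2) / n)
    if denom == 0:
        t = 0.0 if kappa1 == kappa2 else math.copysign(math.inf, kappa1 - kappa2)
    else:
        t = (kappa1 - kappa2) / denom
    p = float(2 * sstats.t.sf(abs(t), df=n))
    return float(t), p


def confusion_metrics(tp: int, fp: int, fn: int, tn: int) -> tuple[float, float]:
    """(sensitivity, specificity) from confusion-matrix counts."""
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0 or tn + fp == 0:
        raise ValueError("both classes must be present")
    return tp / (tp + fn), tn / (tn + fp)


def roc_auc(scores, labels) -> float:
    """ROC AUC as the Mann-Whitney statistic: the fraction of
    (positive, negative) pairs ranked correctly, ties counting 0.5."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length vectors")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = sstats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)
    return float(auc)


def labels_from_annotations(annotations: list[SeizureAnnotation]
                            ) -> tuple[list[str], list[str], np.ndarray]:
    """Records x annotators binary seizure-presence labels.

    Returns (record_ids, annotator_ids, labels). Every record must be
    covered by every annotator (an event-free reading is an annotation
    with zero events).
    """
    records = sorted({a.record_id for a in annotations})
    annotators = sorted({a.annotator_id for a in annotations})
    labels = np.full((len(records), len(annotators)), -1, dtype=int)
    for a in annotations:
        labels[records.index(a.record_id),
               annotators.index(a.annotator_id)] = int(a.has_seizure)
    if np.any(labels < 0):
        raise ValueError("every annotator must cover every record")
    return records, annotators, labels


def majority_vote(labels: np.ndarray) -> np.ndarray:
    """Per-record majority label from a records x annotators binary matrix:
    1 iff at least ceil(N/2) annotators marked an event."""
    labels = np.asarray(labels, dtype=int)
    N = labels.shape[1]
    return (labels.sum(axis=1) >= math.ceil(N / 2)).astype(int)
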