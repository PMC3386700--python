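"""Significance of classifier performance: exact binomial tail and shuffle null.

Whether an observed test-set accuracy beats chance is quantified two ways:

* **Exact binomial tail.**  Under the chance model, each test sample is
  classified correctly with probability ``p0`` equal to the majority-class
  proportion of the test set (always guessing the majority class is the best
  label-blind strategy).  The probability of ``k`` or more correct out of
  ``n`` is the exact upper tail of Binomial(n, p0), computed in exact
  rational arithmetic for n <= 64 and by log-space summation otherwise —
  never by a normal approximation.

* **Label-shuffle null.**  Clinical group labels are permuted uniformly at
  random (count-preserving) across all sera, and the *entire* classification
  procedure — partitioning, exhaustive subset selection on the training set,
  evaluation on the test set — is re-run on the shuffled data.  The best
  models found under shuffled labels should perform like guessing (test MCC
  near 0); systematic departure would indicate information leakage in the
  pipeline rather than biological signal.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .chromatic import FeatureMatrix
from .classify import run_repeated_experiment
from .plate_model import ReactomicsError

logger = logging.getLogger("reactomics")

_EXACT_N_MAX = 64


@dataclass(frozen=True)
class SignificanceResult:
    """Exact binomial assessment of one test-set accuracy."""

    n_test: int
    k_correct: int
    chance_p: float
    p_value: float
    method: str = "exact_binomial"


@dataclass
class ShuffleReport:
    """Best-model test MCCs obtained under label-shuffled re-runs."""

    n_shuffles: int
    mcc_values: list[float]
    accuracy_values: list[float]

    @property
    def mean_mcc(self) -> float:
        return float(np.mean(self.mcc_values))

    @property
    def sd_mcc(self) -> float:
        return float(np.std(self.mcc_values, ddof=1)) if len(self.mcc_values) > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "shuffle": range(1, len(self.mcc_values) + 1),
                "test_mcc": self.mcc_values,
                "test_accuracy": self.accuracy_values,
            }
        )


def chance_probability(labels: Sequence) -> float:
    """Majority-class proportion of a test-label multiset.

    This is the expected per-sample success rate of the best label-blind
    guesser and serves as ``p0`` of the binomial chance model.
    """
    values, counts = np.unique(np.asarray(labels), return_counts=True)
    if len(values) < 2:
        raise ReactomicsError("chance probability needs two classes in the test set")
    return float(counts.max() / counts.sum())


def binomial_tail_p(k: int, n: int, p0: float) -> float:
    """Exact upper tail P(X >= k) for X ~ Binomial(n, p0).

    Exact rational summation for ``n <= 64``; stable log-space summation of
    binomial terms above that.  ``P(X >= 0) = 1`` and ``P(X >= n) = p0**n``
    hold exactly.
    """
    if not (0 <= k <= n) or n < 1:
        raise ReactomicsError(f"invalid binomial arguments k={k}, n={n}")
    if not (0.0 < p0 < 1.0):
        raise ReactomicsError(f"chance probability must be in (0, 1); got {p0}")
    if k == 0:
        return 1.0
    if n <= _EXACT_N_MAX:
        p = Fraction(p0)
        q = 1 - p
        tail = sum(
            Fraction(math.comb(n, i)) * p**i * q**(n - i) for i in range(k, n + 1)
        )
        return float(tail)
    log_p, log_q = math.log(p0), math.log1p(-p0)
    i = np.arange(k, n + 1)
    log_terms = (
        gammaln(n + 1) - gammaln(i + 1) - gammaln(n - i + 1)
        + i * log_p + (n - i) * log_q
    )
    return float(min(1.0, math.exp(logsumexp(log_terms))))


def accuracy_significance(cm) -> SignificanceResult:
    """Binomial significance of one confusion matrix's accuracy.

    The chance probability is derived from the matrix's own test-label
    composition (tp+fn positives, tn+fp negatives).
    """
    n_pos, n_neg = cm.tp + cm.fn, cm.tn + cm.fp
    p0 = max(n_pos, n_neg) / (n_pos + n_neg)
    k = cm.tp + cm.tn
    return SignificanceResult(
        n_test=cm.n,
        k_correct=k,
        chance_p=p0,
        p_value=binomial_tail_p(k, cm.n, p0),
    )


def run_shuffle_null(
    matrix: FeatureMatrix,
    positive_group: str,
    negative_group: str,
    seeds: Sequence[int],
    n_repeats_per_shuffle: int = 1,
    sizing: str | tuple[int, int, int, int] = "balanced-25",
    c_param: float = 1.0,
) -> ShuffleReport:
    """Re-run the full experiment under count-preserving label shuffles.

    For each seed: all group labels of ``matrix`` (including groups outside
    the compared pair, mirroring a three-group cohort shuffle) are permuted,
    then the complete repeated experiment is run for the compared pair and
    the best models' test MCC and accuracy recorded.  Deterministic given
    ``seeds``; an identity permutation, should one be drawn, is kept.
    """
    if len(seeds) < 1:
        raise ReactomicsError("need at least one shuffle seed")
    mccs: list[float] = []
    accs: list[float] = []
    for seed in seeds:
        rng = np.random.default_rng(int(seed))
        labels = matrix.groups.to_numpy()
        shuffled = pd.Series(
            labels[rng.permutation(len(labels))],
            index=matrix.groups.index,
            name="group",
        )
        shuffled_matrix = FeatureMatrix(values=matrix.values, groups=shuffled)
        partition_seeds = rng.integers(0, 2**31 - 1, size=n_repeats_per_shuffle)
        report = run_repeated_experiment(
            shuffled_matrix,
            positive_group,
            negative_group,
            seeds=[int(s) for s in partition_seeds],
            sizing=sizing,
            c_param=c_param,
        )
        for r in report.results:
            mccs.append(r.test_cm.mcc)
            accs.append(r.test_cm.accuracy)
    return ShuffleReport(
        n_shuffles=len(seeds), mcc_values=mccs, accuracy_values=accs
    )
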