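"""Binary classification by exhaustive feature-subset search with a linear SVM.

One *experiment* compares two clinical groups: samples of each group are
randomly split into balanced training and test sets; for every non-empty
subset of the detector-vesicle features a linear-kernel SVM (LIBSVM, as
wrapped by scikit-learn's ``SVC``) is fitted on the training set; the subset
whose model best classifies the *training* samples (resubstitution) is
selected, and only that one model is evaluated on the held-out test set.
The whole procedure is repeated over several random partitions; features
selected in every repeat form the *consensus* set.

Model quality is summarized by a confusion matrix and the derived Accuracy,
Sensitivity, Specificity (percentages) and the Matthews correlation
coefficient

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)),

with the convention MCC = 0 whenever a marginal factor vanishes.

Selection is fully deterministic: subsets are enumerated in a canonical
order (cardinality ascending, then lexicographic), and ties are broken by
training accuracy, then training MCC, then smaller subset, then canonical
order.  With ten features the search space is 2^10 - 1 = 1,023 subsets,
small enough for exhaustive enumeration; the enumerator refuses panels
beyond 20 features.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.svm import SVC

from .chromatic import FeatureMatrix
from .plate_model import ReactomicsError

logger = logging.getLogger("reactomics")

MAX_EXHAUSTIVE_FEATURES = 20


class SizingError(ReactomicsError):
    """A partition asks for more samples than a group provides."""


class FitError(ReactomicsError):
    """The SVM could not be fitted (e.g. single-class training set)."""


@dataclass(frozen=True)
class PartitionSpec:
    """Sizing and seed of one random balanced train/test partition."""

    positive_group: str
    negative_group: str
    n_train_pos: int = 25
    n_train_neg: int = 25
    n_test_pos: int = 25
    n_test_neg: int = 25
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train_pos", "n_train_neg", "n_test_pos", "n_test_neg"):
            if getattr(self, name) < 1:
                raise SizingError(f"{name} must be >= 1")


@dataclass(frozen=True)
class ConfusionMatrix:
    """Binary confusion counts and the derived quality measures."""

    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ReactomicsError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def accuracy(self) -> float:
        """Percent of correct predictions."""
        return 100.0 * (self.tp + self.tn) / self.n

    @property
    def sensitivity(self) -> float:
        """Percent of actual positives correctly identified."""
        return 100.0 * self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        """Percent of actual negatives correctly identified."""
        return 100.0 * self.tn / (self.tn + self.fp)

    @property
    def mcc(self) -> float:
        """Matthews correlation coefficient; 0 when a marginal is empty."""
        denom = (
            (self.tp + self.fp) * (self.tp + self.fn)
            * (self.tn + self.fp) * (self.tn + self.fn)
        )
        if denom == 0:
            logger.debug("degenerate confusion marginal; MCC set to 0 by convention")
            return 0.0
        return (self.tp * self.tn - self.fp * self.fn) / math.sqrt(denom)


def confusion_from_rates(
    sensitivity_pct: float, specificity_pct: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Reconstruct integer confusion counts from printed sensitivity and
    specificity percentages and the test-set composition."""
    tp = round(sensitivity_pct / 100.0 * n_pos)
    tn = round(specificity_pct / 100.0 * n_neg)
    return ConfusionMatrix(tp=tp, fp=n_neg - tn, tn=tn, fn=n_pos - tp)


@dataclass
class ExperimentResult:
    """One repeat of a classification experiment (one report-table row)."""

    repeat_index: int
    selected_subset: tuple[str, ...]
    train_cm: ConfusionMatrix
    test_cm: ConfusionMatrix
    model: SVC
    n_subsets_scanned: int


@dataclass
class ExperimentReport:
    """All repeats of one pairwise comparison plus the consensus features."""

    positive_group: str
    negative_group: str
    results: list[ExperimentResult]
    consensus_features: tuple[str, ...]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            cm = r.test_cm
            rows.append(
                {
                    "repeat": r.repeat_index,
                    "selected_features": "+".join(r.selected_subset),
                    "accuracy": cm.accuracy,
                    "sensitivity": cm.sensitivity,
                    "specificity": cm.specificity,
                    "mcc": cm.mcc,
                    "tp": cm.tp,
                    "fp": cm.fp,
                    "tn": cm.tn,
                    "fn": cm.fn,
                }
            )
        return pd.DataFrame(rows)


def partition(
    matrix: FeatureMatrix, spec: PartitionSpec
) -> tuple[FeatureMatrix, FeatureMatrix]:
    """Seeded random balanced split into disjoint train and test matrices."""
    rng = np.random.default_rng(spec.seed)
    train_ids: list = []
    test_ids: list = []
    for group, n_train, n_test in (
        (spec.positive_group, spec.n_train_pos, spec.n_test_pos),
        (spec.negative_group, spec.n_train_neg, spec.n_test_neg),
    ):
        ids = matrix.groups.index[matrix.groups == group].to_numpy()
        if len(ids) < n_train + n_test:
            raise SizingError(
                f"group {group!r} has {len(ids)} samples; "
                f"{n_train}+{n_test} requested"
            )
        perm = ids[rng.permutation(len(ids))]
        train_ids.extend(perm[:n_train])
        test_ids.extend(perm[n_train:n_train + n_test])
    train = FeatureMatrix(matrix.values.loc[train_ids], matrix.groups.loc[train_ids])
    test = FeatureMatrix(matrix.values.loc[test_ids], matrix.groups.loc[test_ids])
    return train, test


def enumerate_subsets(n_features: int) -> list[tuple[int, ...]]:
    """All non-empty feature-index subsets in canonical order.

    Canonical order is cardinality ascending, then lexicographic; with
    ``n_features = 10`` this yields the full 1,023-subset search space.
    """
    if not 1 <= n_features <= MAX_EXHAUSTIVE_FEATURES:
        raise ReactomicsError(
            f"exhaustive search supports 1..{MAX_EXHAUSTIVE_FEATURES} features "
            f"(got {n_features}); use a heuristic selector for larger panels"
        )
    subsets: list[tuple[int, ...]] = []
    for k in range(1, n_features + 1):
        subsets.extend(combinations(range(n_features), k))
    return subsets


def _encode(matrix: FeatureMatrix, positive_group: str) -> tuple[np.ndarray, np.ndarray]:
    X = matrix.values.to_numpy(dtype=float)
    y = np.where(matrix.groups.to_numpy() == positive_group, 1, -1)
    return X, y


def fit_linear_classifier(
    X: np.ndarray, y: np.ndarray, subset: Sequence[int], c_param: float = 1.0
) -> SVC:
    """Fit a linear-kernel SVM (LIBSVM) on the given feature subset.

    ``y`` must contain both classes (+1/-1).  The dual solver is
    deterministic for fixed inputs; features enter as-is, with no further
    scaling beyond the upstream normalization.
    """
    if len(np.unique(y)) < 2:
        raise FitError("training set contains a single class")
    model = SVC(kernel="linear", C=c_param)
    model.fit(X[:, list(subset)], y)
    return model


def evaluate(
    model: SVC, X: np.ndarray, y: np.ndarray, subset: Sequence[int]
) -> ConfusionMatrix:
    """Confusion matrix of ``model`` on labeled rows restricted to ``subset``."""
    if len(X) == 0:
        raise ReactomicsError("cannot evaluate on an empty data set")
    pred = model.predict(X[:, list(subset)])
    return ConfusionMatrix(
        tp=int(np.sum((pred == 1) & (y == 1))),
        fp=int(np.sum((pred == 1) & (y == -1))),
        tn=int(np.sum((pred == -1) & (y == -1))),
        fn=int(np.sum((pred == -1) & (y == 1))),
    )


def select_best_subset(
    X: np.ndarray,
    y: np.ndarray,
    subsets: Sequence[tuple[int, ...]],
    c_param: float = 1.0,
) -> tuple[tuple[int, ...], SVC, ConfusionMatrix]:
    """Exhaustive search for the subset whose SVM best fits the training set.

    Each candidate model is scored on the training samples themselves
    (resubstitution).  The winner maximizes (accuracy, MCC, fewer features),
    with remaining ties resolved by canonical enumeration order, making the
    search a pure function of its inputs.  Subsets whose fit fails are
    skipped with a warning; if every fit fails an error is raised.
    """
    if len(subsets) == 0:
        raise ReactomicsError("no candidate subsets given")
    best: tuple | None = None
    for idx, subset in enumerate(subsets):
        try:
            model = fit_linear_classifier(X, y, subset, c_param)
        except FitError:
            raise
        except Exception as exc:  # solver failure on a pathological subset
            logger.warning("subset %s skipped: %s", subset, exc)
            continue
        cm = evaluate(model, X, y, subset)
        key = (cm.accuracy, cm.mcc, -len(subset))
        if best is None or key > best[0]:
            best = (key, idx, subset, model, cm)
    if best is None:
        raise ReactomicsError("all candidate subsets failed to fit")
    _, _, subset, model, cm = best
    return subset, model, cm


def run_repeated_experiment(
    matrix: FeatureMatrix,
    positive_group: str,
    negative_group: str,
    seeds: Sequence[int],
    sizing: str | tuple[int, int, int, int] = "balanced-25",
    c_param: float = 1.0,
) -> ExperimentReport:
    """Run the full repeated-partition experiment for one pair of groups.

    ``seeds`` supplies one partition seed per repeat.  ``sizing`` is either
    the name of a preset (``"balanced-25"``: 25 train + 25 test per group;
    ``"benchmark-26-25"``: train 24 positives / 25 negatives, test 26 / 25 —
    the composition implied by printed sensitivity and specificity
    denominators of the source study, with 24/24 train and 26/26 test when
    both groups are cancer groups) or an explicit tuple
    ``(n_train_pos, n_train_neg, n_test_pos, n_test_neg)``.
    """
    if len(seeds) < 1:
        raise ReactomicsError("need at least one repeat seed")
    counts = resolve_sizing(sizing, positive_group, negative_group)
    features = matrix.feature_names
    subsets = enumerate_subsets(len(features))
    results: list[ExperimentResult] = []
    for rep, seed in enumerate(seeds, start=1):
        spec = PartitionSpec(
            positive_group, negative_group, *counts, seed=int(seed)
        )
        train, test = partition(matrix.subset_groups(
            (positive_group, negative_group)), spec)
        Xtr, ytr = _encode(train, positive_group)
        Xte, yte = _encode(test, positive_group)
        subset, model, train_cm = select_best_subset(Xtr, ytr, subsets, c_param)
        test_cm = evaluate(model, Xte, yte, subset)
        results.append(
            ExperimentResult(
                repeat_index=rep,
                selected_subset=tuple(features[i] for i in subset),
                train_cm=train_cm,
                test_cm=test_cm,
                model=model,
                n_subsets_scanned=len(subsets),
            )
        )
    consensus = set(results[0].selected_subset)
    for r in results[1:]:
        consensus &= set(r.selected_subset)
    consensus_ordered = tuple(f for f in features if f in consensus)
    return ExperimentReport(
        positive_group=positive_group,
        negative_group=negative_group,
        results=results,
        consensus_features=consensus_ordered,
    )


def resolve_sizing(
    sizing: str | tuple[int, int, int, int],
    positive_group: str,
    negative_group: str,
) -> tuple[int, int, int, int]:
    """Translate a sizing preset into (n_train_pos, n_train_neg, n_test_pos,
    n_test_neg)."""
    if isinstance(sizing, tuple):
        return sizing
    if sizing == "balanced-25":
        return (25, 25, 25, 25)
    if sizing == "benchmark-26-25":
        if "control" in (positive_group, negative_group):
            # cancer group is the positive class: 24 train / 26 test
            return (24, 25, 26, 25)
        return (24, 24, 26, 26)
    raise ReactomicsError(f"unknown sizing preset {sizing!r}")
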