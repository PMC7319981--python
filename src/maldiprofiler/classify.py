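"""Linear SVM spot classification with case-level aggregation.

The classifier is trained on the study cases' spot spectra (one feature
vector per spot, from the peak matrix), with the regularization cost tuned by
5-fold cross-validation. Folds group whole cases by default so no case
contributes spots to both the training and held-out side of a fold.
Validation cases receive a per-spot call, a consistency fraction (share of
spots agreeing with the modal call), and a majority final call.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedGroupKFold, StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .peaks import PeakMatrix
from .spectra_io import ProfileDataset

logger = logging.getLogger(__name__)

DEFAULT_COST_GRID = (0.1, 0.5, 1.0, 5.0, 10.0)


@dataclass
class SvmConfig:
    kernel: str = "linear"
    cost_grid: tuple = DEFAULT_COST_GRID
    cv_folds: int = 5
    fold_unit: str = "case"  # "case" | "spot"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kernel != "linear":
            raise ValueError("only the linear kernel is supported")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not self.cost_grid or any(c <= 0 for c in self.cost_grid):
            raise ValueError("cost_grid must be non-empty with positive costs")
        if self.fold_unit not in ("case", "spot"):
            raise ValueError("fold_unit must be 'case' or 'spot'")


@dataclass
class TrainedModel:
    """A fitted linear SVM plus the standardization learned on the study set."""

    svm: SVC
    scaler: StandardScaler
    peak_mz: np.ndarray
    classes: tuple
    tuned_cost: float
    cv_accuracy_by_cost: dict


@dataclass
class CaseCall:
    """Per-case classification outcome.

    ``consistency`` is the fraction of the case's spots agreeing with the
    modal call; ``final_call`` is the modal class, or ``indeterminate`` on an
    exact tie (scored as incorrect).
    """

    case_id: str
    spot_calls: list  # (spot_id, predicted class)
    consistency: float
    final_call: str
    correct: bool | None = None


def split_dataset(dataset: ProfileDataset, n_study_per_class, seed: int = 0) -> ProfileDataset:
    """Assign whole cases to the study / validation partition.

    ``n_study_per_class`` maps class label -> number of study cases (or a
    pair applied to the sorted class labels). Remaining cases go to
    validation; a case is never split.
    """
    by_class: dict[str, list] = {}
    for case_id in dataset.case_ids:
        by_class.setdefault(dataset.class_of(case_id), []).append(case_id)
    classes = sorted(by_class)
    if not isinstance(n_study_per_class, dict):
        if len(n_study_per_class) != len(classes):
            raise ValueError(f"expected one study count per class {classes}")
        n_study_per_class = dict(zip(classes, n_study_per_class))
    rng = np.random.default_rng(seed)
    partition = {}
    for label in classes:
        cases = sorted(by_class[label])
        n = n_study_per_class[label]
        if n > len(cases):
            raise ValueError(
                f"requested {n} study cases for class {label} but only {len(cases)} exist"
            )
        study = set(rng.choice(cases, size=n, replace=False))
        for c in cases:
            partition[c] = "study" if c in study else "validation"
        if n == len(cases):
            logger.warning("class %s has an empty validation set", label)
    return ProfileDataset(spectra=dataset.spectra, partition=partition)


def _features_labels(matrix: PeakMatrix):
    X = matrix.values
    y = matrix.meta["class_label"].to_numpy()
    groups = matrix.meta["case_id"].to_numpy()
    return X, y, groups


def tune_and_train(matrix: PeakMatrix, config: SvmConfig | None = None) -> TrainedModel:
    """Tune the SVM cost by stratified k-fold CV and refit on all study spots.

    For each cost in the grid, folds are stratified by class and (by default)
    grouped by case; the tuned cost maximizes mean spot-level CV accuracy,
    ties breaking toward the smaller cost (more regularization). Features are
    standardized to zero mean / unit variance on the study data, and the
    learned standardization is stored for reuse at prediction time.
    """
    config = config or SvmConfig()
    X, y, groups = _features_labels(matrix)
    classes = tuple(sorted(set(y)))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes to train; got {classes}")
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)

    if config.fold_unit == "case":
        n_folds = min(config.cv_folds, len(set(groups)))
        if n_folds < config.cv_folds:
            logger.warning("reducing CV folds from %d to %d (only %d cases)",
                           config.cv_folds, n_folds, len(set(groups)))
        splitter = StratifiedGroupKFold(
            n_splits=n_folds, shuffle=True, random_state=config.seed
        )
        folds = list(splitter.split(Xs, y, groups=groups))
    else:
        n_folds = min(config.cv_folds, min(np.bincount(np.searchsorted(classes, y))))
        if n_folds < config.cv_folds:
            logger.warning("reducing CV folds from %d to %d (small class)",
                           config.cv_folds, n_folds)
        splitter = StratifiedKFold(
            n_splits=n_folds, shuffle=True, random_state=config.seed
        )
        folds = list(splitter.split(Xs, y))

    cv_acc: dict[float, float] = {}
    for cost in config.cost_grid:
        accs = []
        for train_idx, test_idx in folds:
            clf = SVC(kernel="linear", C=cost)
            clf.fit(Xs[train_idx], y[train_idx])
            accs.append(float(np.mean(clf.predict(Xs[test_idx]) == y[test_idx])))
        cv_acc[float(cost)] = float(np.mean(accs))
    best = max(cv_acc.items(), key=lambda kv: (kv[1], -kv[0]))[0]
    final = SVC(kernel="linear", C=best)
    final.fit(Xs, y)
    return TrainedModel(
        svm=final,
        scaler=scaler,
        peak_mz=matrix.mz.copy(),
        classes=classes,
        tuned_cost=best,
        cv_accuracy_by_cost=cv_acc,
    )


def predict_spots(model: TrainedModel, matrix: PeakMatrix) -> list:
    """Predict a class for every spot (row); no abstentions at spot level."""
    if len(model.peak_mz) != len(matrix.mz) or not np.allclose(model.peak_mz, matrix.mz):
        trained = set(np.round(model.peak_mz, 4))
        given = set(np.round(matrix.mz, 4))
        raise ValueError(
            "peak columns do not match the training matrix; "
            f"missing={sorted(trained - given)} extra={sorted(given - trained)}"
        )
    preds = model.svm.predict(model.scaler.transform(matrix.values))
    return [
        (row, str(pred))
        for row, pred in zip(matrix.meta.itertuples(index=False), preds)
    ]


def aggregate_cases(spot_predictions: list, truth: dict | None = None) -> list:
    """Fold spot calls into per-case majority calls with consistency shares.

    An exact tie yields ``final_call='indeterminate'`` (scored incorrect when
    truth is available). Cases with zero spots never arise here since calls
    are keyed by spot rows.
    """
    by_case: dict[str, list] = {}
    for row, pred in spot_predictions:
        by_case.setdefault(row.case_id, []).append((row.spot_id, pred))
    calls = []
    for case_id, spots in by_case.items():
        counts: dict[str, int] = {}
        for _, pred in spots:
            counts[pred] = counts.get(pred, 0) + 1
        top = max(counts.values())
        winners = sorted(c for c, n in counts.items() if n == top)
        final = winners[0] if len(winners) == 1 else "indeterminate"
        consistency = top / len(spots)
        correct = None
        if truth is not None:
            correct = final == truth.get(case_id)
        calls.append(
            CaseCall(
                case_id=case_id,
                spot_calls=spots,
                consistency=consistency,
                final_call=final,
                correct=correct,
            )
        )
    return calls


def evaluate(case_calls: list, truth: dict) -> dict:
    """Score case calls against the truth.

    Returns overall accuracy, per-class (correct, total) counts, the number
    of fully consistent cases (consistency == 1.0), and the mean consistency.
    Indeterminate calls count as incorrect.
    """
    per_class: dict[str, list] = {}
    n_correct = 0
    n_consistent = 0
    for call in case_calls:
        true = truth[call.case_id]
        ok = call.final_call == true
        n_correct += ok
        n_consistent += call.consistency == 1.0
        bucket = per_class.setdefault(true, [0, 0])
        bucket[0] += ok
        bucket[1] += 1
    n = len(case_calls)
    return {
        "overall_accuracy": n_correct / n if n else float("nan"),
        "per_class": {k: tuple(v) for k, v in sorted(per_class.items())},
        "n_cases": n,
        "n_fully_consistent": n_consistent,
        "mean_consistency": float(np.mean([c.consistency for c in case_calls])) if n else float("nan"),
    }


def classify_validation(
    matrix: PeakMatrix,
    partition: dict,
    truth: dict,
    config: SvmConfig | None = None,
    compartment: str | None = None,
) -> dict:
    """Convenience wrapper: train on study rows, evaluate on validation cases.

    ``compartment`` restricts both training and evaluation to one tissue
    compartment (the study design trains epithelial and stromal models
    separately). Returns the evaluation report plus the tuned cost, CV table,
    and the per-case calls.
    """
    study_cases = [c for c, p in partition.items() if p == "study"]
    valid_cases = [c for c, p in partition.items() if p == "validation"]
    study = matrix.subset(matrix.rows_for(case_ids=study_cases, compartment=compartment))
    valid = matrix.subset(matrix.rows_for(case_ids=valid_cases, compartment=compartment))
    model = tune_and_train(study, config)
    preds = predict_spots(model, valid)
    calls = aggregate_cases(preds, truth)
    report = evaluate(calls, truth)
    report.update(
        tuned_cost=model.tuned_cost,
        cv_accuracy_by_cost=model.cv_accuracy_by_cost,
        compartment=compartment,
        case_calls={
            c.case_id: {"final_call": c.final_call, "consistency": c.consistency, "correct": c.correct}
            for c in calls
        },
    )
    return report
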