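"""The classifier grid: seven algorithms evaluated under pooled 5-fold CV.

Seven standard algorithms (SVM, LR, kNN, ANN, NB, RF, DT) are trained per
fingerprint type; the random forest is fixed at 20 trees with maximum depth
15, all other hyperparameters keep their backend defaults and are recorded
in the run manifest.  Cross-validation pools the out-of-fold predictions of
the stratified folds into a single confusion table, so the training-set
counts sum to the full training-set size.

By default, when balancing is requested the SMOTE+Tomek hybrid is applied to
the whole training set *before* cross-validation.  That order leaks
synthetic neighbors across folds and optimistically biases the CV estimate;
it is the default because it is the protocol the benchmark tables follow
(their balanced training rows sum to the post-balance size).
``balance_within_folds=True`` instead rebalances each fold's training
portion only — the statistically sound variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np

from .balancing import smote_tomek
from .dataset_core import DatasetSplit, FingerprintMatrix, POTENT
from .metrics import ConfusionTable, MetricsBundle, roc_auc

ALGORITHM_NAMES = ("SVM", "LR", "kNN", "ANN", "NB", "RF", "DT")

#: fixed hyperparameters; everything else is the backend default
RF_N_TREES = 20
RF_MAX_DEPTH = 15


@dataclass(frozen=True)
class AlgorithmSpec:
    name: str
    hyperparameters: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self):
        if self.name not in ALGORITHM_NAMES:
            raise ValueError(
                f"unknown algorithm {self.name!r}; valid names: {ALGORITHM_NAMES}"
            )


def default_specs() -> List[AlgorithmSpec]:
    return [AlgorithmSpec(n) for n in ALGORITHM_NAMES]


def make_model(spec: AlgorithmSpec, seed: int = 0):
    """A fresh scikit-learn estimator for ``spec``, fully seeded.

    Every model exposes a potent-class ranking score: class probabilities
    where available, the signed margin for the SVM.
    """
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import BernoulliNB
    from sklearn.neighbors import KNeighborsClassifier
    from sklearn.neural_network import MLPClassifier
    from sklearn.svm import SVC
    from sklearn.tree import DecisionTreeClassifier
    from sklearn.ensemble import RandomForestClassifier

    hp = dict(spec.hyperparameters)
    if spec.name == "SVM":
        # margin distances serve as ranking scores; no Platt calibration
        return SVC(random_state=seed, **hp)
    if spec.name == "LR":
        return LogisticRegression(max_iter=1000, random_state=seed, **hp)
    if spec.name == "kNN":
        return KNeighborsClassifier(**hp)
    if spec.name == "ANN":
        hp.setdefault("max_iter", 600)
        return MLPClassifier(random_state=seed, **hp)
    if spec.name == "NB":
        return BernoulliNB(**hp)
    if spec.name == "RF":
        hp.setdefault("n_estimators", RF_N_TREES)
        hp.setdefault("max_depth", RF_MAX_DEPTH)
        return RandomForestClassifier(random_state=seed, **hp)
    if spec.name == "DT":
        return DecisionTreeClassifier(random_state=seed, **hp)
    raise AssertionError(spec.name)


def _scores(model, x: np.ndarray) -> np.ndarray:
    """Probability-like score for the potent class."""
    if hasattr(model, "predict_proba"):
        classes = list(model.classes_)
        return model.predict_proba(x)[:, classes.index(POTENT)]
    s = model.decision_function(x)
    return s if model.classes_[1] == POTENT else -s


@dataclass
class CVResult:
    oof_pred: np.ndarray
    oof_score: np.ndarray
    fold_assignment: np.ndarray
    models: List[object]


def cross_validate(
    spec: AlgorithmSpec,
    matrix: np.ndarray,
    labels: Sequence[str],
    folds: int = 5,
    seed: int = 0,
    balance_within_folds: bool = False,
    balance_seed: Optional[int] = None,
) -> CVResult:
    """Pooled out-of-fold predictions under seeded stratified k-fold CV.

    Every sample is predicted exactly once, by a model that never saw it;
    ``folds == n`` degenerates to leave-one-out.  Raises when a class has
    fewer members than ``folds``.
    """
    from sklearn.model_selection import KFold, StratifiedKFold

    x = np.asarray(matrix, dtype=float)
    y = np.asarray(labels)
    n = len(y)
    if folds == n:
        splitter = KFold(n_splits=n)
    else:
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < folds:
            raise ValueError(
                f"smallest class has {counts.min()} members, fewer than {folds} folds"
            )
        splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_pred = np.empty(n, dtype=y.dtype)
    oof_score = np.empty(n)
    fold_assignment = np.empty(n, dtype=int)
    models = []
    for f, (tr, te) in enumerate(splitter.split(x, y)):
        x_tr, y_tr = x[tr], y[tr]
        if balance_within_folds:
            res = smote_tomek(x_tr, y_tr.tolist(), seed=balance_seed or seed)
            x_tr, y_tr = res.matrix, np.asarray(res.labels)
        model = make_model(spec, seed=seed)
        model.fit(x_tr, y_tr)
        oof_pred[te] = model.predict(x[te])
        oof_score[te] = _scores(model, x[te])
        fold_assignment[te] = f
        models.append(model)
    return CVResult(oof_pred, oof_score, fold_assignment, models)


@dataclass(frozen=True)
class EvaluationRow:
    fingerprint_name: str
    algorithm_name: str
    split: str  # cv_train | test | external
    confusion: ConfusionTable
    metrics: MetricsBundle

    @property
    def model_name(self) -> str:
        return f"{self.fingerprint_name}-{self.algorithm_name}"


def evaluate_on_split(
    model, test_matrix: np.ndarray, test_labels: Sequence[str],
    fingerprint_name: str = "", algorithm_name: str = "", split: str = "test",
) -> EvaluationRow:
    """Confusion + metric suite for a trained model on untouched data."""
    x = np.asarray(test_matrix, dtype=float)
    if hasattr(model, "n_features_in_") and x.shape[1] != model.n_features_in_:
        raise ValueError(
            f"feature mismatch: model expects {model.n_features_in_} bit columns, "
            f"got {x.shape[1]}"
        )
    y = np.asarray(test_labels)
    pred = model.predict(x)
    ct = ConfusionTable.from_predictions(y, pred, positive=POTENT)
    auc = None
    if len(np.unique(y)) == 2:
        auc = roc_auc(_scores(model, x), y, positive=POTENT)
    return EvaluationRow(
        fingerprint_name, algorithm_name, split, ct,
        MetricsBundle.from_confusion(ct, auc=auc),
    )


def run_grid(
    fingerprints: Mapping[str, FingerprintMatrix],
    labels: Mapping[str, str],
    split: DatasetSplit,
    specs: Optional[Sequence[AlgorithmSpec]] = None,
    balance: bool = False,
    balance_within_folds: bool = False,
    folds: int = 5,
    seed: int = 0,
) -> List[EvaluationRow]:
    """Evaluate every (fingerprint, algorithm) pair; rank by AUC then CA.

    Produces one ``cv_train`` row (pooled CV confusion on the training set)
    and one ``test`` row per pair.  With ``balance``, SMOTE+Tomek is applied
    to the training set (before CV unless ``balance_within_folds``); the
    test set is never balanced.
    """
    specs = list(specs) if specs is not None else default_specs()
    all_ids = set(split.train_ids) | set(split.test_ids)
    for name, fm in fingerprints.items():
        missing = all_ids - set(fm.compound_ids)
        if missing:
            raise ValueError(f"fingerprint {name!r} missing ids: {sorted(missing)[:5]}")
    rows: List[EvaluationRow] = []
    for fp_name, fm in fingerprints.items():
        x_train = fm.subset(split.train_ids).values
        y_train = [labels[i] for i in split.train_ids]
        x_test = fm.subset(split.test_ids).values if split.test_ids else None
        y_test = [labels[i] for i in split.test_ids]
        if balance and not balance_within_folds:
            res = smote_tomek(x_train, y_train, seed=seed, ids=list(split.train_ids))
            x_cv, y_cv = res.matrix, res.labels
        else:
            x_cv, y_cv = x_train, y_train
        for spec in specs:
            cv = cross_validate(
                spec, x_cv, y_cv, folds=folds, seed=seed,
                balance_within_folds=balance and balance_within_folds,
            )
            ct = ConfusionTable.from_predictions(y_cv, cv.oof_pred, positive=POTENT)
            auc = roc_auc(cv.oof_score, y_cv, positive=POTENT)
            rows.append(
                EvaluationRow(
                    fp_name, spec.name, "cv_train", ct,
                    MetricsBundle.from_confusion(ct, auc=auc),
                )
            )
            if x_test is not None and len(y_test):
                final = make_model(spec, seed=seed)
                final.fit(np.asarray(x_cv, dtype=float), np.asarray(y_cv))
                rows.append(
                    evaluate_on_split(
                        final, x_test, y_test,
                        fingerprint_name=fp_name, algorithm_name=spec.name,
                        split="test",
                    )
                )
    def rank_key(r: EvaluationRow):
        return (-(r.metrics.auc if r.metrics.auc is not None else -1.0), -r.metrics.ca)
    rows.sort(key=rank_key)
    return rows
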