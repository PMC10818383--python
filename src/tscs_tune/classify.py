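"""Leave-one-subject-out classification of MMG events.

Each subject's events form one test fold; the model is trained on all other
subjects, so no subject contributes to both sides of a split. Performance is
the balanced accuracy (mean per-class recall over the classes present in the
fold's ground truth), which is robust to the strong class imbalance of
calibration data (no-response events dominate).

Hyperparameters are tuned per outer fold by random search: candidate
settings are sampled from documented distributions and scored by an *inner*
leave-one-subject-out loop over the n-1 training subjects only. Tuning is
performed on the 3-class problem and the chosen setting reused for the
2-class problem. Class weights are balanced for SVM and RF; LDA, which has
no class-weight parameter, uses uniform class priors instead. Features are
standardized (train-fold statistics only) for SVM and LDA and passed raw to
the random forest.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FEATURE_SETS, select_feature_set

DATASETS = ("ALL", "HEALTHY", "PATIENTS")
MODEL_FAMILIES = ("SVM", "RF", "LDA")


@dataclass(frozen=True)
class ExperimentConfig:
    """One cell of the dataset x feature-set x classes x model grid."""

    dataset: str = "ALL"
    feature_set: str = "SET-OBSERVE"
    n_classes: int = 3
    model_family: str = "RF"
    search_iterations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dataset not in DATASETS:
            raise ValueError(f"unknown dataset {self.dataset!r}")
        if self.feature_set not in FEATURE_SETS:
            raise ValueError(f"unknown feature set {self.feature_set!r}")
        if self.n_classes not in (2, 3):
            raise ValueError("n_classes must be 2 or 3")
        if self.model_family not in MODEL_FAMILIES:
            raise ValueError(f"unknown model family {self.model_family!r}")

    @property
    def config_id(self) -> str:
        fs = "observe" if self.feature_set == "SET-OBSERVE" else "predict"
        return (f"{self.dataset}_{fs}_{self.n_classes}class_"
                f"{self.model_family}")

    @property
    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha1(blob.encode()).hexdigest()[:10]


@dataclass
class FoldResult:
    """Outcome of one LOSO fold (one test subject)."""

    test_subject: str
    balanced_accuracy: float
    predictions: pd.Series  # indexed like the feature table
    confusion: np.ndarray  # K x K counts over the experiment's class list
    best_params: dict = field(default_factory=dict)
    train_subjects: tuple[str, ...] = ()


@dataclass
class ExperimentSummary:
    mean_balanced_accuracy: float
    std_balanced_accuracy: float
    per_subject: dict[str, float]
    confusion_sum: np.ndarray
    confusion_rowratio: np.ndarray
    classes: tuple[int, ...]

    def to_dict(self) -> dict:
        return {
            "mean_balanced_accuracy": self.mean_balanced_accuracy,
            "std_balanced_accuracy": self.std_balanced_accuracy,
            "per_subject": self.per_subject,
            "confusion_sum": self.confusion_sum.tolist(),
            "confusion_rowratio": self.confusion_rowratio.tolist(),
            "classes": list(self.classes),
        }


# ---------------------------------------------------------------------------
# balanced accuracy
# ---------------------------------------------------------------------------

def balanced_accuracy(y_true, y_pred) -> float:
    """Mean per-class recall over the classes present in ``y_true``."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0 or y_true.shape != y_pred.shape:
        raise ValueError("label vectors must be non-empty and equal length")
    recalls = [np.mean(y_pred[y_true == c] == c) for c in np.unique(y_true)]
    return float(np.mean(recalls))


# ---------------------------------------------------------------------------
# classifiers and search distributions
# ---------------------------------------------------------------------------

class _UniformPriorLDA(LinearDiscriminantAnalysis):
    """LDA with uniform class priors fixed at fit time.

    sklearn's LDA has no ``class_weight``; uniform priors are the balanced
    analogue and adapt to the classes actually present in the training fold.
    """

    def fit(self, X, y):
        k = np.unique(y).size
        self.priors = np.full(k, 1.0 / k)
        return super().fit(X, y)


def sample_params(model_family: str, rng: np.random.Generator) -> dict:
    """Draw one hyperparameter setting from the search distributions.

    SVM: C and gamma log-uniform on [1e-3, 1e3]. RF: min_samples_split
    2..20, min_samples_leaf 1..10, max_depth 3..30 or unlimited,
    max_samples uniform [0.3, 1]. LDA: solver in {svd, lsqr, eigen}, tol
    log-uniform [1e-6, 1e-2], n_components 1 or K-1 (None).
    """
    if model_family == "SVM":
        return {"C": float(10 ** rng.uniform(-3, 3)),
                "gamma": float(10 ** rng.uniform(-3, 3))}
    if model_family == "RF":
        depth_choices = [None] + list(range(3, 31))
        return {"min_samples_split": int(rng.integers(2, 21)),
                "min_samples_leaf": int(rng.integers(1, 11)),
                "max_depth": depth_choices[int(rng.integers(len(depth_choices)))],
                "max_samples": float(rng.uniform(0.3, 1.0))}
    if model_family == "LDA":
        return {"solver": ["svd", "lsqr", "eigen"][int(rng.integers(3))],
                "tol": float(10 ** rng.uniform(-6, -2)),
                "n_components": [1, None][int(rng.integers(2))]}
    raise ValueError(f"unknown model family {model_family!r}")


def make_classifier(model_family: str, params: dict, n_classes: int,
                    random_state: int = 0):
    """Instantiate the classifier (with standardization where needed)."""
    if model_family == "SVM":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", SVC(kernel="rbf", class_weight="balanced", **params)),
        ])
    if model_family == "RF":
        return RandomForestClassifier(
            n_estimators=100, class_weight="balanced",
            random_state=random_state, **params)
    if model_family == "LDA":
        return Pipeline([
            ("scale", StandardScaler()),
            ("clf", _UniformPriorLDA(**params)),
        ])
    raise ValueError(f"unknown model family {model_family!r}")


def _fit_score(model_family: str, params: dict, n_classes: int,
               X_tr, y_tr, X_te, y_te, random_state: int) -> float:
    """Balanced accuracy of one fit, 0 when the fit fails (e.g. singular
    covariance for LDA's eigen solver)."""
    clf = make_classifier(model_family, params, n_classes, random_state)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X_tr, y_tr)
            return balanced_accuracy(y_te, clf.predict(X_te))
    except (np.linalg.LinAlgError, ValueError):
        return 0.0


def tune_hyperparameters(X: pd.DataFrame, y: np.ndarray,
                         subject_ids: np.ndarray, model_family: str,
                         n_iter: int, seed: int) -> dict:
    """Random search scored by inner LOSO over the training subjects.

    Only the n-1 training subjects of the outer fold may be passed here;
    the outer test subject never enters. Returns the sampled setting with
    the highest inner mean balanced accuracy (first on ties).
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    n_classes = int(np.unique(y).size)
    subjects = pd.unique(subject_ids)
    candidates = [sample_params(model_family, rng) for _ in range(n_iter)]
    best_params, best_score = candidates[0], -np.inf
    for params in candidates:
        scores = []
        for subj in subjects:
            te = subject_ids == subj
            scores.append(_fit_score(model_family, params, n_classes,
                                     X[~te], y[~te], X[te], y[te],
                                     random_state=seed % (2**31)))
        score = float(np.mean(scores))
        if score > best_score:
            best_params, best_score = params, score
    return best_params


# ---------------------------------------------------------------------------
# outer LOSO
# ---------------------------------------------------------------------------

def loso_cross_validate(X: pd.DataFrame, y: pd.Series,
                        subject_ids: pd.Series, config: ExperimentConfig,
                        y_tune: pd.Series | None = None,
                        fixed_params: dict | None = None
                        ) -> list[FoldResult]:
    """Leave-one-subject-out cross-validation with per-fold tuning.

    ``y`` carries the labels of the experiment's class scheme; ``y_tune``
    (default: ``y``) carries the 3-class labels used for hyperparameter
    search. ``fixed_params`` bypasses the search (used for controls).
    """
    y = np.asarray(y)
    groups = np.asarray(subject_ids)
    subjects = pd.unique(groups)
    if subjects.size < 2:
        raise ValueError("LOSO needs at least two subjects")
    y_tune_arr = y if y_tune is None else np.asarray(y_tune)
    classes = tuple(int(c) for c in np.unique(y))
    folds: list[FoldResult] = []
    for fold_idx, subj in enumerate(subjects):
        te = groups == subj
        if not te.any():
            warnings.warn(f"subject {subj} has no events; skipped")
            continue
        tr = ~te
        fold_seed = int(np.random.SeedSequence(
            [config.seed, fold_idx]).generate_state(1)[0] % (2**31))
        if fixed_params is not None:
            params = dict(fixed_params)
        else:
            params = tune_hyperparameters(
                X[tr], y_tune_arr[tr], groups[tr], config.model_family,
                config.search_iterations, fold_seed)
        clf = make_classifier(config.model_family, params,
                              n_classes=len(classes), random_state=fold_seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X[tr], y[tr])
            pred = clf.predict(X[te])
        folds.append(FoldResult(
            test_subject=str(subj),
            balanced_accuracy=balanced_accuracy(y[te], pred),
            predictions=pd.Series(pred, index=X.index[te]),
            confusion=confusion_matrix(y[te], pred, labels=list(classes)),
            best_params=params,
            train_subjects=tuple(str(s) for s in pd.unique(groups[tr])),
        ))
    return folds


def summarize_experiments(folds: list[FoldResult],
                          classes: tuple[int, ...]) -> ExperimentSummary:
    """Mean/std balanced accuracy across subjects plus pooled confusions."""
    accs = np.array([f.balanced_accuracy for f in folds])
    conf = np.sum([f.confusion for f in folds], axis=0)
    rowsum = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.where(rowsum > 0, conf / rowsum, 0.0)
    return ExperimentSummary(
        mean_balanced_accuracy=float(accs.mean()),
        std_balanced_accuracy=float(accs.std()),
        per_subject={f.test_subject: f.balanced_accuracy for f in folds},
        confusion_sum=conf,
        confusion_rowratio=ratio,
        classes=classes,
    )


def run_experiment(table: pd.DataFrame, config: ExperimentConfig
                   ) -> tuple[list[FoldResult], ExperimentSummary]:
    """Run one grid cell on an assembled feature table."""
    df = table
    if config.dataset == "HEALTHY":
        df = df[df.group == "healthy"]
    elif config.dataset == "PATIENTS":
        df = df[df.group == "patient"]
    if df.empty:
        raise ValueError(f"dataset {config.dataset} selects no events")
    X, y3, subjects = select_feature_set(df, config.feature_set)
    y = df[f"label_{config.n_classes}"]
    folds = loso_cross_validate(X, y, subjects, config, y_tune=y3)
    classes = tuple(int(c) for c in np.unique(y))
    return folds, summarize_experiments(folds, classes)


def experiment_grid(datasets=DATASETS,
                    feature_sets=("SET-OBSERVE", "SET-PREDICT"),
                    class_counts=(2, 3), models=MODEL_FAMILIES,
                    search_iterations: int = 50,
                    seed: int = 0) -> list[ExperimentConfig]:
    """Enumerate the experiment grid (3 x 2 x 2 x 3 = 36 cells by default)."""
    return [
        ExperimentConfig(dataset=d, feature_set=f, n_classes=k,
                         model_family=m, search_iterations=search_iterations,
                         seed=seed)
        for d in datasets for f in feature_sets for k in class_counts
        for m in models
    ]
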