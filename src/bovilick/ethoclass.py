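"""Ethogram mapping, data splitting, feature ranking/selection and the four
classifiers (DT, RF, kNN, SVM).

The three ethograms collapse the four base behaviours into progressively
coarser targets:

1. licking / eating / standing / lying (identity),
2. licking / eating / inactive (standing + lying),
3. licking / non-licking (eating + standing + lying).

Data are pooled across animals, split 70/30 stratified by class, features
are ranked by random-forest Gini importance on the training set
(ntree = 500, mtry = 5), and models are trained with 10-fold
cross-validated hyperparameter tuning where the algorithm has free
hyperparameters. RF and SVM consume all twenty features; DT and kNN consume
only the top three ranked features. kNN and SVM inputs are standardised
with training-set statistics only; tree models use raw features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .core import BEHAVIOURS
from .featex import FEATURE_COLUMNS

__all__ = [
    "ETHOGRAMS",
    "ALGORITHMS",
    "EthogramSpec",
    "ModelSpec",
    "TrainedClassifier",
    "apply_ethogram",
    "stratified_split",
    "rank_features_gini",
    "select_features",
    "train_model",
    "predict",
]

ALGORITHMS = ("DT", "RF", "kNN", "SVM")

#: Algorithms restricted to the top-3 Gini-ranked features.
TOP3_ALGORITHMS = ("DT", "kNN")


@dataclass(frozen=True)
class EthogramSpec:
    """A total mapping from the four base behaviours onto class labels."""

    id: int
    mapping: dict[str, str]

    def __post_init__(self) -> None:
        missing = set(BEHAVIOURS) - set(self.mapping)
        if missing:
            raise ValueError(f"ethogram {self.id} missing behaviours {sorted(missing)}")

    @property
    def classes(self) -> list[str]:
        return sorted(set(self.mapping.values()))


ETHOGRAMS: dict[int, EthogramSpec] = {
    1: EthogramSpec(1, {b: b for b in BEHAVIOURS}),
    2: EthogramSpec(
        2,
        {"licking": "licking", "eating": "eating",
         "standing": "inactive", "lying": "inactive"},
    ),
    3: EthogramSpec(
        3,
        {"licking": "licking", "eating": "non-licking",
         "standing": "non-licking", "lying": "non-licking"},
    ),
}


def apply_ethogram(table: pd.DataFrame, spec: EthogramSpec | int) -> pd.DataFrame:
    """Relabel a feature table according to an ethogram; row count unchanged."""
    if isinstance(spec, int):
        spec = ETHOGRAMS[spec]
    unknown = set(table["label"].unique()) - set(spec.mapping)
    if unknown:
        raise ValueError(f"labels not in the base ethogram: {sorted(unknown)}")
    out = table.copy()
    out["label"] = out["label"].map(spec.mapping)
    return out


def stratified_split(
    table: pd.DataFrame,
    train_fraction: float = 0.70,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class proportional split into training and testing tables.

    Each class contributes ``floor(train_fraction * n + 0.5)`` rows to the
    training set; the remainder goes to testing. The partition is disjoint,
    exhaustive and deterministic given the seed.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    train_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    for cls, group in table.groupby("label", sort=True):
        n = len(group)
        if n < 2:
            raise ValueError(f"class {cls!r} has {n} row(s); need at least 2 to split")
        n_train = int(np.floor(train_fraction * n + 0.5))
        n_train = min(max(n_train, 1), n - 1)  # both sides nonempty
        perm = rng.permutation(group.index.to_numpy())
        train_idx.append(perm[:n_train])
        test_idx.append(perm[n_train:])
    train = table.loc[np.sort(np.concatenate(train_idx))].reset_index(drop=True)
    test = table.loc[np.sort(np.concatenate(test_idx))].reset_index(drop=True)
    return train, test


def rank_features_gini(
    train: pd.DataFrame,
    ntree: int = 500,
    mtry: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Rank the twenty features by random-forest Gini importance.

    Grows a forest with ``ntree`` trees, ``mtry`` candidate features per
    split, and returns a two-column frame (``feature``, ``mgv``) in
    descending importance; ties break by canonical feature order.
    Importances are scikit-learn's mean decrease in impurity, normalised to
    sum to one (the ordering, not the scale, is meaningful).
    """
    if train["label"].nunique() < 2:
        raise ValueError("need at least 2 classes to rank features")
    forest = RandomForestClassifier(
        n_estimators=ntree,
        max_features=mtry,
        criterion="gini",
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(train[FEATURE_COLUMNS].to_numpy(), train["label"].to_numpy())
    ranking = pd.DataFrame(
        {"feature": FEATURE_COLUMNS, "mgv": forest.feature_importances_}
    )
    # stable sort on -mgv keeps canonical order among exact ties
    ranking = ranking.sort_values(
        "mgv", ascending=False, kind="mergesort"
    ).reset_index(drop=True)
    return ranking


def select_features(ranking: pd.DataFrame, algorithm: str) -> list[str]:
    """All twenty features for RF/SVM; the top three ranked for DT/kNN."""
    if algorithm not in ALGORITHMS:
        raise ValueError(f"unknown algorithm {algorithm!r}; expected one of {ALGORITHMS}")
    if algorithm in TOP3_ALGORITHMS:
        return ranking["feature"].head(3).tolist()
    return list(FEATURE_COLUMNS)


@dataclass
class ModelSpec:
    """What to train: algorithm, features, tuning protocol."""

    algorithm: str
    features: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))
    cv_folds: int = 10
    seed: int = 0
    ntree: int = 500
    mtry: int = 5

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"unknown algorithm {self.algorithm!r}")


@dataclass
class TrainedClassifier:
    """A fitted model plus the metadata needed to reapply it."""

    algorithm: str
    estimator: object
    features: list[str]
    classes: list[str]
    seed: int
    cv_folds: int
    tuned_params: dict
    cv_accuracy: float | None = None


# CV tuning grids; RF is fixed (ntree/mtry prescribed, no tuning step).
_DT_GRID = {"ccp_alpha": [0.0, 1e-4, 5e-4, 1e-3, 5e-3, 1e-2]}
_KNN_GRID = {"knn__n_neighbors": [3, 5, 7, 9, 11, 13, 15]}
_SVM_GRID = {"svm__C": [1.0, 10.0, 100.0], "svm__gamma": ["scale", 0.01, 0.1]}


def train_model(train: pd.DataFrame, spec: ModelSpec) -> TrainedClassifier:
    """Fit one classifier according to its spec.

    DT (cost-complexity pruning), kNN (k over odd 3-15) and SVM (RBF cost
    and width) are tuned by stratified ``cv_folds``-fold cross-validation
    maximising accuracy; RF uses the fixed forest settings. kNN and SVM sit
    behind a training-set StandardScaler.
    """
    if len(train) == 0:
        raise ValueError("training table is empty")
    missing = [f for f in spec.features if f not in train.columns]
    if missing:
        raise KeyError(f"training table missing feature column(s) {missing}")
    y = train["label"].to_numpy()
    classes = sorted(pd.unique(y))
    if len(classes) < 2:
        raise ValueError(f"training set has a single class {classes[0]!r}")
    X = train[spec.features].to_numpy()
    cv = StratifiedKFold(n_splits=spec.cv_folds, shuffle=True, random_state=spec.seed)

    tuned: dict = {}
    cv_acc: float | None = None
    if spec.algorithm == "RF":
        est = RandomForestClassifier(
            n_estimators=spec.ntree,
            max_features=min(spec.mtry, len(spec.features)),
            criterion="gini",
            random_state=spec.seed,
            n_jobs=1,
        )
        est.fit(X, y)
        tuned = {"ntree": spec.ntree, "mtry": min(spec.mtry, len(spec.features))}
    else:
        if spec.algorithm == "DT":
            base = DecisionTreeClassifier(random_state=spec.seed)
            grid = _DT_GRID
        elif spec.algorithm == "kNN":
            base = Pipeline(
                [("scale", StandardScaler()), ("knn", KNeighborsClassifier())]
            )
            grid = _KNN_GRID
        else:  # SVM
            base = Pipeline(
                [
                    ("scale", StandardScaler()),
                    ("svm", SVC(kernel="rbf", random_state=spec.seed)),
                ]
            )
            grid = _SVM_GRID
        search = GridSearchCV(base, grid, scoring="accuracy", cv=cv, n_jobs=1)
        search.fit(X, y)
        est = search.best_estimator_
        tuned = dict(search.best_params_)
        cv_acc = float(search.best_score_)
    return TrainedClassifier(
        algorithm=spec.algorithm,
        estimator=est,
        features=list(spec.features),
        classes=classes,
        seed=spec.seed,
        cv_folds=spec.cv_folds,
        tuned_params=tuned,
        cv_accuracy=cv_acc,
    )


def cross_validated_accuracy(model: TrainedClassifier, train: pd.DataFrame) -> float:
    """Stratified k-fold CV accuracy of a model's configuration on a table."""
    from sklearn.base import clone
    from sklearn.model_selection import cross_val_score

    cv = StratifiedKFold(n_splits=model.cv_folds, shuffle=True, random_state=model.seed)
    scores = cross_val_score(
        clone(model.estimator),
        train[model.features].to_numpy(),
        train["label"].to_numpy(),
        scoring="accuracy",
        cv=cv,
        n_jobs=1,
    )
    return float(scores.mean())


def predict(model: TrainedClassifier, test: pd.DataFrame) -> np.ndarray:
    """Apply a trained classifier to a feature table; one label per row."""
    missing = [f for f in model.features if f not in test.columns]
    if missing:
        raise KeyError(f"test table missing feature column(s) {missing}")
    if len(test) == 0:
        return np.array([], dtype=object)
    return np.asarray(model.estimator.predict(test[model.features].to_numpy()), dtype=object)
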