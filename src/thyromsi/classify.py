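"""Three-class L1-penalized multinomial classification of MSI units.

The model is a multinomial logistic regression with a pure Lasso penalty,
fit on ROI-average feature matrices of the training set.  The penalty is
chosen by stratified k-fold cross-validation (default 5-fold) maximizing
mean CV accuracy, with ties resolved toward the larger penalty (sparser
model).  Features are standardized to unit variance internally; the
coefficients are stored on the standardized scale together with the
standardization parameters.  Class imbalance is deliberately left
unweighted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from thyromsi.errors import ParameterError
from thyromsi.model import CLASS_LABELS
from thyromsi.preprocess import FeatureMatrix

#: Tie-break priority on exact probability ties (never silently benign).
_TIE_PRIORITY = ("PTC", "HT", "HP")


@dataclass
class ClassifierModel:
    """Fitted 3-class Lasso multinomial model.

    ``coefficients`` has shape (3, n_features) on the standardized feature
    scale (class order HP, HT, PTC); ``lambda_`` is the selected penalty
    (inverse of scikit-learn's C).
    """

    classes: tuple = CLASS_LABELS
    feature_mzs: np.ndarray = field(default_factory=lambda: np.empty(0))
    coefficients: np.ndarray = field(default_factory=lambda: np.zeros((3, 0)))
    intercepts: np.ndarray = field(default_factory=lambda: np.zeros(3))
    scaler_mean: np.ndarray = field(default_factory=lambda: np.empty(0))
    scaler_scale: np.ndarray = field(default_factory=lambda: np.empty(0))
    lambda_: float = 0.0
    cv_folds: int = 5
    cv_accuracy: float = float("nan")
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.feature_mzs = np.asarray(self.feature_mzs, dtype=np.float64)
        self.coefficients = np.asarray(self.coefficients, dtype=np.float64)
        self.intercepts = np.asarray(self.intercepts, dtype=np.float64)
        self.scaler_mean = np.asarray(self.scaler_mean, dtype=np.float64)
        self.scaler_scale = np.asarray(self.scaler_scale, dtype=np.float64)
        if self.coefficients.shape != (len(self.classes), self.feature_mzs.size):
            raise ParameterError(
                f"coefficient shape {self.coefficients.shape} does not match "
                f"{len(self.classes)} classes x {self.feature_mzs.size} features"
            )
        if self.lambda_ < 0:
            raise ParameterError("lambda must be nonnegative")

    @property
    def selected_features(self) -> np.ndarray:
        """Feature m/z values with any nonzero class coefficient."""
        return self.feature_mzs[np.any(self.coefficients != 0, axis=0)]

    @property
    def effective_intercepts(self) -> np.ndarray:
        """Intercepts on the raw feature scale (score of an all-zero unit)."""
        return self.intercepts - self.coefficients @ (self.scaler_mean / self.scaler_scale)

    def scores(self, X: np.ndarray) -> np.ndarray:
        Z = (X - self.scaler_mean) / self.scaler_scale
        return Z @ self.coefficients.T + self.intercepts

    # -- persistence --------------------------------------------------------

    def to_json(self, path: str) -> None:
        payload = {
            "classes": list(self.classes),
            "feature_mzs": self.feature_mzs.tolist(),
            "coefficients": self.coefficients.tolist(),
            "intercepts": self.intercepts.tolist(),
            "scaler_mean": self.scaler_mean.tolist(),
            "scaler_scale": self.scaler_scale.tolist(),
            "lambda": self.lambda_,
            "cv_folds": self.cv_folds,
            "cv_accuracy": self.cv_accuracy,
            "rng_seed": self.rng_seed,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "ClassifierModel":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            classes=tuple(d["classes"]),
            feature_mzs=np.array(d["feature_mzs"]),
            coefficients=np.array(d["coefficients"]),
            intercepts=np.array(d["intercepts"]),
            scaler_mean=np.array(d["scaler_mean"]),
            scaler_scale=np.array(d["scaler_scale"]),
            lambda_=d["lambda"],
            cv_folds=d["cv_folds"],
            cv_accuracy=d["cv_accuracy"],
            rng_seed=d["rng_seed"],
        )


def _fit_l1(X: np.ndarray, y: np.ndarray, lam: float, seed: int) -> LogisticRegression:
    clf = LogisticRegression(
        penalty="l1",
        C=1.0 / lam,
        solver="saga",
        max_iter=1000,
        tol=1e-3,
        random_state=seed,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # saga convergence chatter on tiny folds
        clf.fit(X, y)
    return clf


def fit_lasso_multinomial(
    roi_matrix: FeatureMatrix,
    roi_labels: Sequence[str],
    cv_folds: int = 5,
    rng_seed: int = 0,
    lambda_grid: Optional[np.ndarray] = None,
) -> ClassifierModel:
    """Fit the Lasso multinomial model with CV-selected penalty.

    The lambda grid is log-spaced; mean CV accuracy picks the penalty, ties
    going to the larger lambda.  Constant features are dropped with a
    warning (their coefficients are reported as zero).
    """
    y = np.asarray(roi_labels)
    X = roi_matrix.values
    if len(y) != X.shape[0]:
        raise ParameterError("labels do not align with matrix rows")
    present = set(y)
    missing = [c for c in CLASS_LABELS if c not in present]
    if missing:
        raise ParameterError(f"class absent from training labels: {missing}")
    if X.shape[0] < cv_folds:
        raise ParameterError("fewer rows than CV folds")

    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn(
            f"dropping {int((~keep).sum())} constant feature(s) before fitting",
            stacklevel=2,
        )
    Xk = X[:, keep]
    if Xk.shape[1] == 0:
        raise ParameterError("no non-constant features to fit on")
    mean = Xk.mean(axis=0)
    scale = Xk.std(axis=0)
    Z = (Xk - mean) / scale

    if lambda_grid is None:
        lambda_grid = np.logspace(-3.0, 1.5, 16)
    lambda_grid = np.sort(np.asarray(lambda_grid, dtype=float))

    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=rng_seed)
    folds = list(skf.split(Z, y))
    mean_acc = np.empty(lambda_grid.size)
    for i, lam in enumerate(lambda_grid):
        accs = []
        for tr, te in folds:
            clf = _fit_l1(Z[tr], y[tr], lam, rng_seed)
            accs.append(float(np.mean(clf.predict(Z[te]) == y[te])))
        mean_acc[i] = float(np.mean(accs))

    best_acc = mean_acc.max()
    # ties -> larger lambda (sparser); grid is ascending so take the last
    best_i = int(np.flatnonzero(mean_acc >= best_acc - 1e-12)[-1])
    lam = float(lambda_grid[best_i])

    clf = _fit_l1(Z, y, lam, rng_seed)
    order = [list(clf.classes_).index(c) for c in CLASS_LABELS]
    coef_k = clf.coef_[order]
    intercepts = clf.intercept_[order]

    coefficients = np.zeros((3, X.shape[1]))
    coefficients[:, keep] = coef_k
    full_mean = np.zeros(X.shape[1])
    full_scale = np.ones(X.shape[1])
    full_mean[keep] = mean
    full_scale[keep] = scale

    return ClassifierModel(
        classes=CLASS_LABELS,
        feature_mzs=roi_matrix.feature_mzs,
        coefficients=coefficients,
        intercepts=intercepts,
        scaler_mean=full_mean,
        scaler_scale=full_scale,
        lambda_=lam,
        cv_folds=cv_folds,
        cv_accuracy=best_acc,
        rng_seed=rng_seed,
    )


def _map_features(model: ClassifierModel, matrix: FeatureMatrix) -> np.ndarray:
    """Project a feature matrix onto the model's feature axis.

    Features are matched by m/z within a relative tolerance of 1e-6 (the
    pipeline shares frozen bins, so matches are exact); model features
    absent from the matrix contribute zero intensity.
    """
    if matrix.feature_mzs.size == model.feature_mzs.size and np.allclose(
        matrix.feature_mzs, model.feature_mzs
    ):
        return matrix.values
    X = np.zeros((matrix.n_units, model.feature_mzs.size))
    n_matched = 0
    for j, mz in enumerate(model.feature_mzs):
        k = int(np.searchsorted(matrix.feature_mzs, mz))
        for cand in (k - 1, k):
            if 0 <= cand < matrix.feature_mzs.size and abs(
                matrix.feature_mzs[cand] - mz
            ) <= 1e-6 * mz:
                X[:, j] = matrix.values[:, cand]
                n_matched += 1
                break
    if n_matched == 0:
        raise ParameterError("no overlap between matrix features and model features")
    return X


def predict_probs(model: ClassifierModel, matrix: FeatureMatrix) -> np.ndarray:
    """Class probabilities (rows x [HP, HT, PTC]) via softmax of the scores."""
    X = _map_features(model, matrix)
    s = model.scores(X)
    s = s - s.max(axis=1, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=1, keepdims=True)


def classify_units(model: ClassifierModel, matrix: FeatureMatrix) -> list[str]:
    """Argmax class call per row with a fixed PTC > HT > HP tie-break."""
    probs = predict_probs(model, matrix)
    return classify_probs(probs, model.classes)


def classify_probs(probs: np.ndarray, classes: Sequence[str] = CLASS_LABELS) -> list[str]:
    probs = np.atleast_2d(probs)
    calls = []
    pri = [list(classes).index(c) for c in _TIE_PRIORITY if c in classes]
    for row in probs:
        best = pri[0]
        for j in pri[1:]:
            if row[j] > row[best]:
                best = j
        calls.append(classes[best])
    return calls
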