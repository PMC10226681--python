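"""Classifier registry: binary and one-class learners, grids, and naming.

Binary detectors (guided / semi-guided schemes): decision tree (DT),
random forest (RF), Bernoulli naive Bayes (NB), gradient boosting (GB),
k-nearest neighbour (kNN), and support vector machines with polynomial
kernel K(y_i, y_j) = (1 + g y_i^T y_j)^d or RBF kernel.  One-class
detectors (unguided scheme): nu-parameterized one-class SVMs with the
same two kernels, trained on cough feature vectors only.

Class 1 = cough is the positive class everywhere; one-class inliers map
to cough.  Model names follow the compound convention
"scheme-model-type  classifier-r (category)", e.g. "G-B RF-5 (M)" for a
guided binary random forest whose non-cough class holds the five
human-made sound types.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.naive_bayes import BernoulliNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC, OneClassSVM
from sklearn.tree import DecisionTreeClassifier

BINARY_CLASSIFIERS = ("DT", "RF", "NB_bernoulli", "GB", "kNN", "SVM_poly", "SVM_rbf")
UNARY_CLASSIFIERS = ("USVM_poly", "USVM_rbf")
SCHEMES = ("unguided", "guided", "semi_guided")
CATEGORIES = ("animal", "human_made", "hardware")

_CATEGORY_LETTER = {"animal": "A", "human_made": "M", "hardware": "H"}
_LETTER_CATEGORY = {v: k for k, v in _CATEGORY_LETTER.items()}

_FAMILY_ABBR = {
    "DT": "DT", "RF": "RF", "NB_bernoulli": "NB", "GB": "GB", "kNN": "kNN",
    "SVM_poly": "SVM", "SVM_rbf": "SVM", "USVM_poly": "SVM", "USVM_rbf": "SVM",
}

#: Default hyperparameter grids, one sub-grid per classifier.
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "DT": {"min_split": list(range(39, 50)), "max_depth": list(range(10, 21))},
    "RF": {"n_estimators": [100, 200, 300]},
    "GB": {"n_estimators": [100, 200, 300]},
    "NB_bernoulli": {},
    "kNN": {"k": [1, 2, 3]},
    "SVM_poly": {"d": [1, 2, 3], "C": [1, 2, 3]},
    "SVM_rbf": {"gamma": [0.0001, 0.001, 0.01, 0.09], "C": [1, 2, 3]},
    "USVM_poly": {"d": [1, 2, 3], "nu": [0.0001, 0.001, 0.01, 0.1]},
    "USVM_rbf": {"gamma": [0.0001, 0.001, 0.01, 0.09], "nu": [0.0001, 0.001, 0.01, 0.1]},
}


@dataclass(frozen=True)
class ModelSpec:
    """A detector configuration: scheme, classifier, category, parameters."""

    scheme: str
    classifier: str
    category: str | None = None
    selection: object | None = None  # features.SelectionSpec or None (all 120)
    hyperparameters: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.scheme == "unguided":
            if self.classifier not in UNARY_CLASSIFIERS:
                raise ValueError("unguided scheme requires a one-class SVM classifier")
            if self.category is not None:
                raise ValueError("unguided models take no noise category")
        else:
            if self.classifier not in BINARY_CLASSIFIERS:
                raise ValueError(f"unknown binary classifier {self.classifier!r}")
            if self.scheme == "guided" and self.category not in CATEGORIES:
                raise ValueError("guided scheme requires a noise category")
            if self.scheme == "semi_guided" and self.category is not None:
                raise ValueError("semi-guided models take no single category")

    @property
    def r(self) -> int:
        return {"unguided": 0, "guided": 5, "semi_guided": 15}[self.scheme]


class _MedianBernoulliNB:
    """Bernoulli naive Bayes on features binarized at the training median.

    Real-valued cepstral features are thresholded per feature at their
    training-set median, which keeps both binary outcomes populated.
    """

    def __init__(self):
        self._nb = BernoulliNB()
        self._median: np.ndarray | None = None

    def fit(self, X, y):
        self._median = np.median(X, axis=0)
        self._nb.fit((X > self._median).astype(float), y)
        return self

    def _bin(self, X):
        return (X > self._median).astype(float)

    def predict(self, X):
        return self._nb.predict(self._bin(X))

    def predict_proba(self, X):
        return self._nb.predict_proba(self._bin(X))


@dataclass
class FittedModel:
    """A trained detector handle: estimator + spec + feature indices."""

    spec: ModelSpec
    estimator: object
    n_features: int
    feature_idx: np.ndarray | None = None  # indices into the 120-vector, or None
    decision_tol: float = 0.0  # one-class boundary tolerance (train-scale)


def _build_binary(classifier: str, hp: dict, seed: int):
    if classifier == "DT":
        return DecisionTreeClassifier(
            min_samples_split=int(hp.get("min_split", 39)),
            max_depth=int(hp.get("max_depth", 10)),
            random_state=seed,
        )
    if classifier == "RF":
        return RandomForestClassifier(
            n_estimators=int(hp.get("n_estimators", 100)), random_state=seed, n_jobs=1
        )
    if classifier == "GB":
        return GradientBoostingClassifier(
            n_estimators=int(hp.get("n_estimators", 100)), random_state=seed
        )
    if classifier == "NB_bernoulli":
        return _MedianBernoulliNB()
    if classifier == "kNN":
        return KNeighborsClassifier(n_neighbors=int(hp.get("k", 1)), metric="euclidean")
    if classifier == "SVM_poly":
        return SVC(
            kernel="poly", degree=int(hp.get("d", 2)), C=float(hp.get("C", 1)),
            gamma=hp.get("gamma", "scale"), coef0=1.0,
        )
    if classifier == "SVM_rbf":
        return SVC(kernel="rbf", gamma=float(hp.get("gamma", 0.0001)), C=float(hp.get("C", 1)))
    raise ValueError(f"unknown binary classifier {classifier!r}")


def fit_binary(spec: ModelSpec, X: np.ndarray, y: np.ndarray, seed: int = 0,
               feature_idx: np.ndarray | None = None) -> FittedModel:
    """Train a binary detector; deterministic given a fixed seed.

    ``y`` is binary with 1 = cough.  Columns of ``X`` are assumed already
    selection-filtered; ``feature_idx`` records the provenance of those
    columns for serialization.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be 2-D with one label per row")
    if len(np.unique(y)) < 2:
        raise ValueError("binary training requires both classes present")
    est = _build_binary(spec.classifier, spec.hyperparameters, seed)
    est.fit(X, y)
    return FittedModel(spec=spec, estimator=est, n_features=X.shape[1], feature_idx=feature_idx)


def fit_unary(spec: ModelSpec, X_cough: np.ndarray,
              feature_idx: np.ndarray | None = None) -> FittedModel:
    """Train a one-class detector on cough rows only.

    With outlier rate ``nu``, roughly a fraction nu of the training rows
    fall outside the learned margin.
    """
    if spec.classifier not in UNARY_CLASSIFIERS:
        raise ValueError("fit_unary requires a one-class SVM classifier")
    X = np.asarray(X_cough, dtype=float)
    if X.ndim != 2 or X.shape[0] < 10:
        raise ValueError("one-class training requires at least 10 rows")
    hp = spec.hyperparameters
    nu = float(hp.get("nu", 0.1))
    # tight solver tolerance: at small nu the default tolerance leaves the
    # margin under-optimized and the outlier fraction far off nu
    if spec.classifier == "USVM_poly":
        est = OneClassSVM(kernel="poly", degree=int(hp.get("d", 2)), nu=nu,
                          gamma=hp.get("gamma", "scale"), coef0=1.0, tol=1e-8)
    else:
        est = OneClassSVM(kernel="rbf", gamma=float(hp.get("gamma", 0.0001)), nu=nu, tol=1e-8)
    est.fit(X)
    # boundary support vectors sit at decision value ~0 with sign decided by
    # solver noise; classify with a tolerance tied to the training scale so
    # they count as inliers (they are not margin errors in the nu sense)
    d_train = est.decision_function(X)
    tol = 1e-6 * float(np.abs(d_train).max()) if d_train.size else 0.0
    return FittedModel(spec=spec, estimator=est, n_features=X.shape[1],
                       feature_idx=feature_idx, decision_tol=tol)


def predict(handle: FittedModel, X: np.ndarray) -> np.ndarray:
    """Predict labels in {0, 1}; one-class inliers map to 1 (cough)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0, dtype=int)
    if X.ndim != 2 or X.shape[1] != handle.n_features:
        raise ValueError("column count does not match training")
    if isinstance(handle.estimator, OneClassSVM):
        d = handle.estimator.decision_function(X)
        return (d >= -handle.decision_tol).astype(int)
    if handle.spec.classifier == "kNN":
        # neighbour-vote ties break toward the cough class
        return (handle.estimator.predict_proba(X)[:, 1] >= 0.5).astype(int)
    return handle.estimator.predict(X).astype(int)


def score(handle: FittedModel, X: np.ndarray) -> np.ndarray:
    """Real-valued scores monotone in cough-likelihood (for ROC curves)."""
    X = np.asarray(X, dtype=float)
    if X.size == 0:
        return np.zeros(0, dtype=float)
    if X.ndim != 2 or X.shape[1] != handle.n_features:
        raise ValueError("column count does not match training")
    est = handle.estimator
    if isinstance(est, OneClassSVM):
        return est.decision_function(X)
    if hasattr(est, "decision_function"):
        return np.asarray(est.decision_function(X), dtype=float)
    return est.predict_proba(X)[:, 1]


def model_name(spec: ModelSpec) -> str:
    """The compound display name for a detector configuration."""
    abbr = _FAMILY_ABBR[spec.classifier]
    if spec.scheme == "unguided":
        return f"U-U {abbr}"
    if spec.scheme == "guided":
        return f"G-B {abbr}-5 ({_CATEGORY_LETTER[spec.category]})"
    return f"S-B {abbr}-15"


_NAME_RE = re.compile(
    r"^(?P<sch>[UGS])-(?P<mt>[UB])\s+(?P<abbr>DT|RF|NB|GB|kNN|SVM)"
    r"(?:-(?P<r>\d+))?(?:\s+\((?P<cat>[AMH])\))?$"
)


def parse_model_name(name: str) -> dict:
    """Invert :func:`model_name` to (scheme, family, r, category).

    The printed name carries the classifier family only (both SVM kernels
    print "SVM"), so the kernel is not recovered.
    """
    m = _NAME_RE.match(name.strip())
    if not m:
        raise ValueError(f"unparseable model name {name!r}")
    scheme = {"U": "unguided", "G": "guided", "S": "semi_guided"}[m.group("sch")]
    r = int(m.group("r")) if m.group("r") else 0
    category = _LETTER_CATEGORY[m.group("cat")] if m.group("cat") else None
    expected_r = {"unguided": 0, "guided": 5, "semi_guided": 15}[scheme]
    if r != expected_r:
        raise ValueError(f"inconsistent name {name!r}: r={r} for scheme {scheme}")
    return {"scheme": scheme, "family": m.group("abbr"), "r": r, "category": category}
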