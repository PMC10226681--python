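"""Experimental protocol: composition, splits, grid search, evaluation.

The central objects follow the model/results idiom: a
:class:`CoughDetector` is configured with a scheme (unguided one-class,
guided binary, or semi-guided binary), a classifier, and a feature
selection recipe; ``fit(corpus)`` executes the full protocol — compose
the non-cough class, split the m original coughs (and the m composed
non-coughs) 10 times 90/10, expand every original event to 18 instances
(original + 17 augmentations) on its own side of the split, select
features, train, and evaluate on one or more test environments — and
returns a :class:`DetectorResults` carrying per-split metrics, their
mean±std, and a ``summary()`` table.

Class composition follows the per-type quota n' = m/r: the guided
scheme draws from the 5 types of one category (quotas of, e.g., 21–22
for m=106), the semi-guided scheme from all 15 types (7–8), and the
unguided scheme trains on coughs alone.  Train/test exclusivity is
enforced at the original-event level, so no waveform (in any augmented
variant) appears on both sides of a split.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from coughkit.audio_core import CATEGORY_TYPES, stream_rng
from coughkit.augmentation import augment_event
from coughkit.features import SelectionSpec, extract_features, select_by_variance, select_k_best
from coughkit.models import (
    DEFAULT_GRIDS,
    FittedModel,
    ModelSpec,
    UNARY_CLASSIFIERS,
    fit_binary,
    fit_unary,
    model_name,
    predict,
    score,
)
from coughkit.segmentation import SoundEvent

ENVIRONMENTS = ("animal", "human_made", "hardware", "all")


class PoolExhaustedError(RuntimeError):
    """Raised when a sound-type pool cannot supply its per-type quota."""


@dataclass
class ClassComposition:
    """The recipe actually used to build the non-cough class."""

    scheme: str
    m: int
    r: int
    per_type_counts: dict[str, int]

    def __post_init__(self) -> None:
        if self.r and sum(self.per_type_counts.values()) != self.m:
            raise ValueError("per-type counts must sum to m")


def compose_class0(scheme: str, category: str | None, pool: dict[str, list[SoundEvent]],
                   m: int, rng: np.random.Generator):
    """Sample the m-event non-cough class according to the scheme.

    Per-type counts are floor(m/r) or ceil(m/r); which types receive the
    remainder is a uniform draw.  Sampling within a type is without
    replacement.  Returns ``(ClassComposition, list_of_events)``.
    """
    if scheme == "unguided":
        return ClassComposition(scheme, m, 0, {}), []
    if scheme == "guided":
        if category not in CATEGORY_TYPES:
            raise ValueError("guided composition requires a noise category")
        types = list(CATEGORY_TYPES[category])
    elif scheme == "semi_guided":
        types = [t for cat in CATEGORY_TYPES.values() for t in cat]
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    r = len(types)
    base, rem = divmod(m, r)
    counts = {t: base for t in types}
    for t in rng.choice(types, size=rem, replace=False):
        counts[t] += 1
    deficient = [t for t in types if len(pool.get(t, [])) < counts[t]]
    if deficient:
        raise PoolExhaustedError(f"insufficient events for types: {deficient}")
    sampled: list[SoundEvent] = []
    for t in types:
        idx = rng.choice(len(pool[t]), size=counts[t], replace=False)
        sampled.extend(pool[t][i] for i in sorted(idx))
    return ClassComposition(scheme, m, r, counts), sampled


@dataclass
class Split:
    """Index sets for one round: coughs and (optionally) composed class-0."""

    cough_train: np.ndarray
    cough_test: np.ndarray
    class0_train: np.ndarray
    class0_test: np.ndarray


@dataclass
class SplitPlan:
    n_splits: int
    test_frac: float
    splits: list[Split]


def _partition(m: int, test_frac: float, rng) -> tuple[np.ndarray, np.ndarray]:
    n_train = math.ceil((1.0 - test_frac) * m)
    if not (1 <= n_train < m):
        raise ValueError("degenerate split sizes")
    perm = rng.permutation(m)
    return np.sort(perm[:n_train]), np.sort(perm[n_train:])


def make_splits(m: int, n_splits: int = 10, test_frac: float = 0.1,
                rng: np.random.Generator | None = None, m_class0: int | None = None) -> SplitPlan:
    """Draw independent random train/test partitions of m original events.

    Each split partitions {0..m-1} with ceil((1-test_frac)*m) training
    indices.  When ``m_class0`` is non-zero (default m), an independent
    partition of the composed non-cough events with the same proportions
    is drawn per split.
    """
    if m < 2:
        raise ValueError("m must be at least 2")
    if not (0 < test_frac < 1):
        raise ValueError("test_frac must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng(0)
    if m_class0 is None:
        m_class0 = m
    splits = []
    for _ in range(n_splits):
        ctr, cte = _partition(m, test_frac, rng)
        if m_class0:
            ztr, zte = _partition(m_class0, test_frac, rng)
        else:
            ztr = zte = np.zeros(0, dtype=int)
        splits.append(Split(ctr, cte, ztr, zte))
    return SplitPlan(n_splits=n_splits, test_frac=test_frac, splits=splits)


class FeatureCache:
    """Lazy per-event feature blocks: 18 x 120 (original + 17 variants).

    Augmentation and extraction are deterministic, so blocks are keyed by
    a digest of the waveform itself and reused across splits, schemes and
    seeds.
    """

    def __init__(self):
        self._blocks: dict[bytes, np.ndarray] = {}

    def block(self, event: SoundEvent) -> np.ndarray:
        key = _event_key(event)
        if key not in self._blocks:
            self._blocks[key] = np.vstack(
                [extract_features(v) for v in augment_event(event)]
            )
        return self._blocks[key]


def _event_key(ev: SoundEvent) -> bytes:
    import hashlib

    return hashlib.sha1(np.ascontiguousarray(ev.clip.samples).tobytes()).digest()


def attach_augmentations(split: Split, cough_events: list[SoundEvent],
                         class0_events: list[SoundEvent], cache: FeatureCache | None = None):
    """Expand a split into augmented train/test instance sets.

    Every original event contributes its 18 instances (original + 17
    deterministic variants) to its own side of the split only.  Returns
    ``(X_train, y_train, X_test, y_test)`` feature matrices/labels with
    1 = cough.  Raises on any train/test overlap of original events.
    """
    cache = cache or FeatureCache()
    if set(split.cough_train) & set(split.cough_test):
        raise RuntimeError("train/test cough indices overlap")
    if set(split.class0_train) & set(split.class0_test):
        raise RuntimeError("train/test class-0 indices overlap")
    tr_keys = {_event_key(cough_events[i]) for i in split.cough_train}
    te_keys = {_event_key(cough_events[i]) for i in split.cough_test}
    if tr_keys & te_keys:
        raise RuntimeError("an original cough event appears on both split sides")

    def stack(events, idx):
        if len(idx) == 0:
            return np.zeros((0, 120))
        return np.vstack([cache.block(events[i]) for i in idx])

    Xtr_c = stack(cough_events, split.cough_train)
    Xte_c = stack(cough_events, split.cough_test)
    Xtr_0 = stack(class0_events, split.class0_train)
    Xte_0 = stack(class0_events, split.class0_test)
    X_train = np.vstack([Xtr_c, Xtr_0])
    y_train = np.r_[np.ones(len(Xtr_c), dtype=int), np.zeros(len(Xtr_0), dtype=int)]
    X_test = np.vstack([Xte_c, Xte_0])
    y_test = np.r_[np.ones(len(Xte_c), dtype=int), np.zeros(len(Xte_0), dtype=int)]
    return X_train, y_train, X_test, y_test


METRIC_COLUMNS = ("ACC", "FPR", "FNR", "precision", "recall", "F1", "AUC_ROC", "SEN", "SPE")


def confusion_metrics(tp: int, fn: int, fp: int, tn: int) -> dict:
    """All rate metrics from one confusion table (exact identities).

    SEN = 1 - FNR and SPE = 1 - FPR hold exactly; undefined ratios are NaN.
    """
    n = tp + fn + fp + tn
    if n == 0:
        raise ValueError("empty confusion table")
    acc = (tp + tn) / n
    fpr = fp / (fp + tn) if (fp + tn) else float("nan")
    fnr = fn / (fn + tp) if (fn + tp) else float("nan")
    prec = tp / (tp + fp) if (tp + fp) else float("nan")
    rec = tp / (tp + fn) if (tp + fn) else float("nan")
    f1 = (2 * prec * rec / (prec + rec)) if (prec + rec) else 0.0
    return {
        "ACC": acc, "FPR": fpr, "FNR": fnr, "precision": prec, "recall": rec,
        "F1": f1, "SEN": 1.0 - fnr, "SPE": 1.0 - fpr,
    }


def evaluate(handle: FittedModel, X: np.ndarray, y: np.ndarray) -> dict:
    """One evaluation row for a fitted detector on a labeled test set.

    For a cough-only test set (all labels 1, the applicability setting)
    accuracy equals the fraction predicted cough (= recall of class 1)
    and the negative-class rates are undefined (NaN).  AUC-ROC is
    reported for binary detectors only.
    """
    y = np.asarray(y).astype(int)
    if y.size == 0:
        raise ValueError("empty test set")
    if not np.isin(y, (0, 1)).all():
        raise ValueError("labels must be binary 0/1")
    yhat = predict(handle, X)
    tp = int(np.sum((y == 1) & (yhat == 1)))
    fn = int(np.sum((y == 1) & (yhat == 0)))
    fp = int(np.sum((y == 0) & (yhat == 1)))
    tn = int(np.sum((y == 0) & (yhat == 0)))
    row = confusion_metrics(tp, fn, fp, tn)
    binary = handle.spec.classifier not in UNARY_CLASSIFIERS
    if binary and len(np.unique(y)) == 2:
        row["AUC_ROC"] = float(roc_auc_score(y, score(handle, X)))
    else:
        row["AUC_ROC"] = float("nan")
    return row


def _apply_selection(selection: SelectionSpec | None, X_train, y_train):
    """Feature indices chosen on training data, per the selection recipe."""
    if selection is None:
        return np.arange(X_train.shape[1])
    if selection.method == "k_best":
        return select_k_best(X_train, y_train, selection.k)
    cough_rows = X_train[np.asarray(y_train) == 1]
    return select_by_variance(cough_rows, selection.k, selection.variance_mode)


def _fit_on_split(spec: ModelSpec, X_train, y_train, seed: int) -> FittedModel:
    idx = _apply_selection(spec.selection, X_train, y_train)
    if spec.classifier in UNARY_CLASSIFIERS:
        handle = fit_unary(spec, X_train[np.asarray(y_train) == 1][:, idx], feature_idx=idx)
    else:
        handle = fit_binary(spec, X_train[:, idx], y_train, seed=seed, feature_idx=idx)
    return handle


def grid_search(template: ModelSpec, grid: dict[str, list] | None,
                split_data: list[tuple], k_values: list[int] | None = None,
                selection_method: str = "k_best", variance_mode: str = "smallest",
                seed: int = 0):
    """Exhaustive search over a hyperparameter grid (and optionally K).

    ``split_data`` is a list of ``(X_train, y_train)`` pairs, one per
    split; each grid point is scored by its mean training-set ACC over
    the splits (ties: higher mean F1, then first in enumeration order).
    Returns ``(best_hyperparameters, best_selection, table)``.
    """
    if grid is None:
        grid = DEFAULT_GRIDS[template.classifier]
    keys = sorted(grid)
    combos = [dict(zip(keys, vals)) for vals in itertools.product(*(grid[k] for k in keys))]
    if not combos:
        raise ValueError("empty hyperparameter grid")
    if k_values is None:
        selections: list[SelectionSpec | None] = [template.selection]
    else:
        selections = [
            SelectionSpec(selection_method, k,
                          variance_mode if selection_method == "variance" else None)
            for k in k_values
        ]
    rows = []
    best = None
    for sel in selections:
        for hp in combos:
            spec = ModelSpec(template.scheme, template.classifier, template.category,
                             selection=sel, hyperparameters=hp)
            accs, f1s = [], []
            for X_train, y_train in split_data:
                handle = _fit_on_split(spec, X_train, y_train, seed)
                idx = handle.feature_idx
                row = evaluate(handle, X_train[:, idx], y_train)
                accs.append(row["ACC"])
                f1s.append(row["F1"])
            mean_acc, mean_f1 = float(np.mean(accs)), float(np.nanmean(f1s))
            rows.append({"hyperparameters": hp, "selection": sel,
                         "mean_ACC": mean_acc, "mean_F1": mean_f1})
            if best is None or (mean_acc, mean_f1) > (best[0], best[1]):
                best = (mean_acc, mean_f1, hp, sel)
    table = pd.DataFrame(rows)
    return best[2], best[3], table


def _compose_env(env: str, pool, m: int, rng):
    """Class-0 events for a test environment name (a category or 'all')."""
    if env == "all":
        return compose_class0("semi_guided", None, pool, m, rng)
    return compose_class0("guided", env, pool, m, rng)


class DetectorResults:
    """Per-split metrics of a fitted detector, with aggregation.

    Attributes
    ----------
    per_split : DataFrame
        One row per (split, environment) with all metric columns.
    name : str
        The detector's display name.
    """

    def __init__(self, name: str, spec: ModelSpec, per_split: pd.DataFrame,
                 composition: ClassComposition | None):
        self.name = name
        self.spec = spec
        self.per_split = per_split
        self.composition = composition

    def aggregate(self, environment: str | None = None) -> pd.DataFrame:
        """mean±std of each metric over splits, per environment."""
        df = self.per_split
        if environment is not None:
            df = df[df["environment"] == environment]
        g = df.groupby("environment")[list(METRIC_COLUMNS)]
        mean, std = g.mean(), g.std(ddof=1)
        out = pd.concat({"mean": mean, "std": std}, axis=1)
        return out.swaplevel(axis=1).sort_index(axis=1)

    @property
    def mean(self) -> pd.Series:
        env = self.per_split["environment"].iloc[0]
        return self.per_split[self.per_split["environment"] == env][list(METRIC_COLUMNS)].mean()

    def summary(self) -> str:
        """A compact mean±std table across environments."""
        lines = [f"Detector: {self.name}"]
        if self.composition is not None and self.composition.r:
            lines.append(
                f"class-0 composition (r={self.composition.r}): "
                + ", ".join(f"{t}={c}" for t, c in self.composition.per_type_counts.items())
            )
        agg = self.aggregate()
        for env in agg.index:
            parts = []
            for mcol in ("ACC", "FPR", "FNR", "F1", "AUC_ROC", "precision", "recall"):
                mu = agg.loc[env, (mcol, "mean")]
                sd = agg.loc[env, (mcol, "std")]
                if np.isnan(mu):
                    parts.append(f"{mcol}=--")
                else:
                    parts.append(f"{mcol}={mu:.2f}±{sd:.2f}")
            lines.append(f"  test env {env}: " + "  ".join(parts))
        return "\n".join(lines)


class CoughDetector:
    """A cough-detection model: scheme + classifier + selection recipe.

    Parameters
    ----------
    scheme : str
        ``"unguided"`` (one-class, trained on coughs only), ``"guided"``
        (binary, non-cough class from one 5-type category) or
        ``"semi_guided"`` (binary, all 15 non-cough types).
    classifier : str
        One of the registry keys (DT, RF, NB_bernoulli, GB, kNN,
        SVM_poly, SVM_rbf for binary; USVM_poly, USVM_rbf for unguided).
    category : str, optional
        Noise category for the guided scheme.
    selection : SelectionSpec, optional
        Feature-selection recipe.  Defaults: all 120 features for binary
        schemes; the 70 smallest-variance features for the unguided
        scheme.
    hyperparameters : dict, optional
    n_splits, test_frac : protocol shape (default 10 rounds of 90/10).
    seed : int
        Master seed; named streams derive splits, composition, and
        classifier initialization from it.
    """

    def __init__(self, scheme: str, classifier: str, category: str | None = None,
                 selection: SelectionSpec | None = None, hyperparameters: dict | None = None,
                 n_splits: int = 10, test_frac: float = 0.1, seed: int = 0):
        if selection is None and scheme == "unguided":
            selection = SelectionSpec("variance", 70, "smallest")
        if hyperparameters is None:
            hyperparameters = {"nu": 0.1, "d": 2} if classifier == "USVM_poly" else (
                {"nu": 0.1, "gamma": 0.0001} if classifier == "USVM_rbf" else {})
        self.spec = ModelSpec(scheme, classifier, category,
                              selection=selection, hyperparameters=hyperparameters)
        self.n_splits = n_splits
        self.test_frac = test_frac
        self.seed = seed

    @classmethod
    def from_spec(cls, spec: ModelSpec, **kw) -> "CoughDetector":
        det = cls(spec.scheme, spec.classifier, spec.category,
                  selection=spec.selection,
                  hyperparameters=dict(spec.hyperparameters), **kw)
        return det

    @property
    def name(self) -> str:
        return model_name(self.spec)

    def fit(self, corpus, test_environments: list[str] | None = None,
            cache: FeatureCache | None = None) -> DetectorResults:
        """Run the full protocol on a corpus and return results.

        ``test_environments`` lists the class-0 sources for evaluation: a
        category name, or ``"all"`` for the 15-type mix.  Default: the
        matched environment (the guided scheme's own category; ``"all"``
        otherwise).  Pass ``"cough_only"`` to evaluate applicability on
        the cough test instances alone.
        """
        spec = self.spec
        cache = cache or FeatureCache()
        coughs = corpus.coughs
        m = len(coughs)
        pool = corpus.pool()
        matched = spec.category if spec.scheme == "guided" else "all"
        if test_environments is None:
            test_environments = [matched]

        # class-0 used for *training* (empty for unguided)
        comp_rng = stream_rng(self.seed, "compose/train")
        composition, train_class0 = compose_class0(spec.scheme, spec.category, pool, m, comp_rng)

        # class-0 per test environment (the matched one reuses the training draw)
        env_class0: dict[str, list[SoundEvent]] = {}
        for env in test_environments:
            if env == "cough_only":
                env_class0[env] = []
            elif env == matched and spec.scheme != "unguided":
                env_class0[env] = train_class0
            else:
                # unguided detectors have no training class-0, so even the
                # matched environment draws its own composition here
                _, evs = _compose_env(env, pool, m, stream_rng(self.seed, f"compose/test/{env}"))
                env_class0[env] = evs

        plan = make_splits(m, self.n_splits, self.test_frac,
                           stream_rng(self.seed, "splits"))
        empty = np.zeros(0, dtype=int)
        rows = []
        for si, split in enumerate(plan.splits):
            if train_class0:
                train_split = split
            else:  # one-class training: no composed class-0 on the train side
                train_split = Split(split.cough_train, split.cough_test, empty, empty)
            X_train, y_train, _, _ = attach_augmentations(train_split, coughs, train_class0, cache)
            handle = _fit_on_split(spec, X_train, y_train, seed=self.seed)
            idx = handle.feature_idx
            for env, class0 in env_class0.items():
                _, _, X_test, y_test = attach_augmentations(split, coughs, class0, cache)
                if env == "cough_only":
                    keep = y_test == 1
                    X_test, y_test = X_test[keep], y_test[keep]
                row = evaluate(handle, X_test[:, idx], y_test)
                row.update(split=si, environment=env)
                rows.append(row)
        per_split = pd.DataFrame(rows)
        return DetectorResults(self.name, spec, per_split, composition)

    def tune(self, corpus, grid: dict | None = None, k_values: list[int] | None = None,
             cache: FeatureCache | None = None):
        """Grid-search hyperparameters (and K) on the training sides.

        Returns ``(best_hyperparameters, best_selection, table)``; apply
        them by constructing a new detector.
        """
        spec = self.spec
        cache = cache or FeatureCache()
        coughs = corpus.coughs
        m = len(coughs)
        comp_rng = stream_rng(self.seed, "compose/train")
        _, train_class0 = compose_class0(spec.scheme, spec.category, corpus.pool(), m, comp_rng)
        plan = make_splits(m, self.n_splits, self.test_frac, stream_rng(self.seed, "splits"))
        split_data = []
        for split in plan.splits:
            X_train, y_train, _, _ = attach_augmentations(split, coughs, train_class0, cache)
            split_data.append((X_train, y_train))
        method = "variance" if spec.scheme == "unguided" else "k_best"
        mode = spec.selection.variance_mode if (
            spec.selection is not None and spec.selection.method == "variance") else "smallest"
        return grid_search(spec, grid, split_data, k_values=k_values,
                           selection_method=method, variance_mode=mode, seed=self.seed)


def run_protocol(corpus, seed: int = 0, schemes=("unguided", "guided", "semi_guided"),
                 classifiers: dict[str, list[str]] | None = None,
                 n_splits: int = 10, cross_environment: bool = False,
                 cache: FeatureCache | None = None) -> pd.DataFrame:
    """Train and evaluate a family of detectors; return a mean±std table.

    One row per (model, test environment) with mean and std of every
    metric over splits.  With ``cross_environment``, each guided detector
    is additionally tested against the other two categories' class-0.
    """
    if classifiers is None:
        classifiers = {"unguided": ["USVM_poly"], "guided": ["RF"], "semi_guided": ["RF"]}
    cache = cache or FeatureCache()
    rows = []
    for scheme in schemes:
        cats = list(CATEGORY_TYPES) if scheme == "guided" else [None]
        for category in cats:
            for clf in classifiers[scheme]:
                det = CoughDetector(scheme, clf, category, n_splits=n_splits, seed=seed)
                matched = category if scheme == "guided" else "all"
                envs = [matched]
                if cross_environment and scheme == "guided":
                    envs += [c for c in CATEGORY_TYPES if c != category]
                res = det.fit(corpus, test_environments=envs, cache=cache)
                agg = res.aggregate()
                for env in agg.index:
                    row = {"model": res.name, "scheme": scheme, "classifier": clf,
                           "train_category": category, "test_environment": env}
                    for mcol in METRIC_COLUMNS:
                        row[f"{mcol}_mean"] = agg.loc[env, (mcol, "mean")]
                        row[f"{mcol}_std"] = agg.loc[env, (mcol, "std")]
                    rows.append(row)
    return pd.DataFrame(rows)
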