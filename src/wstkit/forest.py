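"""Random-forest severity modelling with out-of-bag evaluation.

The forest is a seeded bagging layer over scikit-learn CART trees so that
per-tree bootstrap membership is known exactly.  That bookkeeping drives
everything the analysis needs from the model: per-participant out-of-bag
(OOB) vote fractions, the OOB confusion matrix and error rates, and
permutation importance measured as the mean decrease in OOB accuracy when
one feature is shuffled (alongside mean-decrease-Gini importance).

"Correctly predicted" always means OOB-correct: the model never sees a
held-out split, matching the convention of reporting OOB error rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import (
    AdaBoostClassifier,
    GradientBoostingClassifier,
    RandomForestClassifier,
)
from sklearn.model_selection import RepeatedStratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier


@dataclass
class RFParams:
    """Forest settings; defaults follow the reference analysis."""

    mtry: int = 4
    ntree: int = 5000
    replace: bool = True
    permutation_importance: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.mtry < 1:
            raise ValueError("mtry must be >= 1")
        if self.ntree < 1:
            raise ValueError("ntree must be >= 1")


@dataclass
class TreeParams:
    """Single CART settings: minimum node size to split, and a pruning
    strength ``cp`` expressed relative to the root's misclassification risk
    (a split survives only if it removes at least ``cp`` of the root risk)."""

    minsplit: int = 20
    cp: float = 0.01
    seed: int = 0

    def __post_init__(self):
        if self.cp <= 0:
            raise ValueError("cp must be positive")
        if self.minsplit < 2:
            raise ValueError("minsplit must be >= 2")


@dataclass
class RFModelResult:
    feature_names: list[str]
    classes: np.ndarray
    labels: np.ndarray                 # true labels, fit order
    oob_votes: np.ndarray              # n x k vote fractions, rows sum to 1
    oob_predictions: np.ndarray        # argmax votes, ties -> lowest class
    oob_confusion: np.ndarray          # k x k counts, rows = true class
    oob_error_overall: float
    oob_error_per_class: np.ndarray
    importance_gini: pd.Series         # descending
    importance_permutation: pd.Series | None  # descending, None if disabled
    params: RFParams = field(repr=False, default=None)

    @property
    def correct_mask(self) -> np.ndarray:
        return self.oob_predictions == self.labels

    def ranking(self, kind: str = "permutation") -> list[str]:
        s = self.importance_permutation if kind == "permutation" else self.importance_gini
        if s is None:
            raise ValueError("permutation importance was not computed")
        return list(s.index)

    def to_json(self) -> str:
        payload = {
            "feature_names": self.feature_names,
            "classes": [int(c) for c in self.classes],
            "oob_error_overall": self.oob_error_overall,
            "oob_error_per_class": self.oob_error_per_class.tolist(),
            "oob_confusion": self.oob_confusion.tolist(),
            "oob_predictions": self.oob_predictions.tolist(),
            "oob_votes": np.round(self.oob_votes, 6).tolist(),
            "importance_gini": {k: float(v) for k, v in self.importance_gini.items()},
            "importance_permutation": (
                {k: float(v) for k, v in self.importance_permutation.items()}
                if self.importance_permutation is not None else None
            ),
            "params": {
                "mtry": self.params.mtry, "ntree": self.params.ntree,
                "replace": self.params.replace, "seed": self.params.seed,
            },
        }
        return json.dumps(payload, indent=2)


def _validate_features(features: pd.DataFrame, labels) -> tuple[pd.DataFrame, np.ndarray]:
    if isinstance(features, pd.DataFrame):
        X = features
    else:
        X = pd.DataFrame(np.asarray(features))
    y = np.asarray(labels)
    if len(X) != len(y):
        raise ValueError("features and labels disagree in length")
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"features contain missing values (impute first): {bad}")
    if X.shape[1] == 0:
        raise ValueError("feature table has no columns")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes to fit a severity model")
    small = classes[counts < 2]
    if small.size:
        raise ValueError(f"class imbalance: class(es) {small.tolist()} have n < 2")
    return X, y


def fit_rf(features: pd.DataFrame, labels, params: RFParams | None = None) -> RFModelResult:
    """Fit a seeded bootstrap forest and evaluate it out-of-bag.

    Each tree is grown on a bootstrap sample (with replacement by default)
    considering ``mtry`` features per split; every participant's class
    votes are aggregated over the trees whose bootstrap missed them.
    Returns vote fractions, OOB confusion/error, and both importance
    rankings (Gini and permutation mean-decrease-OOB-accuracy).
    """
    params = params or RFParams()
    X, y = _validate_features(features, labels)
    n, p = X.shape
    mtry = min(params.mtry, p)
    classes = np.unique(y)
    k = classes.size
    class_index = {c: i for i, c in enumerate(classes)}
    y_idx = np.array([class_index[v] for v in y])
    Xv = X.to_numpy(dtype=float)

    rng = np.random.default_rng(params.seed)
    votes = np.zeros((n, k))
    gini = np.zeros(p)
    perm_acc_drop = np.zeros(p)
    perm_tree_count = 0

    for _ in range(params.ntree):
        if params.replace:
            boot = rng.integers(0, n, size=n)
        else:
            boot = rng.permutation(n)[: int(np.ceil(0.632 * n))]
        oob = np.setdiff1d(np.arange(n), boot, assume_unique=False)
        tree = DecisionTreeClassifier(
            max_features=mtry,
            criterion="gini",
            random_state=int(rng.integers(2**31)),
        )
        tree.fit(Xv[boot], y_idx[boot])
        gini += _padded_importances(tree, p, k)
        if oob.size == 0:
            continue
        pred = tree.predict(Xv[oob])
        votes[oob, pred] += 1
        if params.permutation_importance:
            base_acc = float(np.mean(pred == y_idx[oob]))
            Xoob = Xv[oob]
            for f in range(p):
                col = Xoob[:, f].copy()
                Xoob[:, f] = col[rng.permutation(oob.size)]
                acc = float(np.mean(tree.predict(Xoob) == y_idx[oob]))
                Xoob[:, f] = col
                perm_acc_drop[f] += base_acc - acc
            perm_tree_count += 1

    uncovered = votes.sum(axis=1) == 0
    if uncovered.any():
        warnings.warn(
            f"{int(uncovered.sum())} case(s) never out-of-bag; defaulting their "
            "prediction to the lowest class",
            stacklevel=2,
        )
        votes[uncovered, 0] = 1.0
    vote_frac = votes / votes.sum(axis=1, keepdims=True)
    pred_idx = np.argmax(vote_frac, axis=1)  # argmax ties -> lowest class index
    predictions = classes[pred_idx]

    confusion = np.zeros((k, k), dtype=int)
    np.add.at(confusion, (y_idx, pred_idx), 1)
    overall_err = 1.0 - confusion.trace() / n
    with np.errstate(invalid="ignore"):
        per_class_err = 1.0 - np.diag(confusion) / confusion.sum(axis=1)

    gini_series = pd.Series(gini / params.ntree, index=list(X.columns)).sort_values(
        ascending=False
    )
    perm_series = None
    if params.permutation_importance and perm_tree_count:
        perm_series = pd.Series(
            perm_acc_drop / perm_tree_count, index=list(X.columns)
        ).sort_values(ascending=False)

    return RFModelResult(
        feature_names=list(X.columns),
        classes=classes,
        labels=y,
        oob_votes=vote_frac,
        oob_predictions=predictions,
        oob_confusion=confusion,
        oob_error_overall=float(overall_err),
        oob_error_per_class=per_class_err,
        importance_gini=gini_series,
        importance_permutation=perm_series,
        params=params,
    )


def _padded_importances(tree: DecisionTreeClassifier, p: int, k: int) -> np.ndarray:
    """Per-tree impurity-decrease importances (already normalised per tree)."""
    imp = tree.feature_importances_
    if imp.size != p:  # cannot happen with dense input; defensive
        out = np.zeros(p)
        out[: imp.size] = imp
        return out
    return imp


def correctly_predicted_subset(model: RFModelResult, table: pd.DataFrame) -> pd.DataFrame:
    """Rows whose OOB prediction equals their true class.

    ``table`` must be row-aligned with the data the model was fitted on.
    Classes that lose all their members are reported with a warning; an
    empty result is allowed.
    """
    if len(table) != len(model.labels):
        raise ValueError("table is not row-aligned with the fitted model")
    mask = model.correct_mask
    kept = table.loc[np.asarray(mask)]
    for cls in model.classes:
        n_kept = int(np.sum(mask & (model.labels == cls)))
        if n_kept == 0:
            warnings.warn(
                f"class {cls}: no correctly predicted cases retained", stacklevel=2
            )
    return kept


@dataclass
class TreeRule:
    path: str            # human-readable conjunction of threshold conditions
    predicted_class: object
    n: int
    accuracy: float      # fraction of training cases in the leaf with that class


@dataclass
class DecisionTreeResult:
    tree: DecisionTreeClassifier
    rules: list[TreeRule]
    params: TreeParams
    feature_names: list[str]

    @property
    def n_leaves(self) -> int:
        return len(self.rules)


def fit_decision_tree(
    features: pd.DataFrame, labels, params: TreeParams | None = None
) -> DecisionTreeResult:
    """Grow one Gini CART, pruned by root-relative complexity, and read off
    its threshold rules.

    ``cp`` is mapped onto scikit-learn's cost-complexity pruning by scaling
    it with the root node's misclassification risk, so a split survives
    only if it removes at least ``cp`` of the root risk.  If pruning leaves
    a bare root, the single-leaf tree is returned with a warning.
    """
    params = params or TreeParams()
    X, y = _validate_features(features, labels)
    classes, counts = np.unique(y, return_counts=True)
    root_risk = 1.0 - counts.max() / len(y)
    tree = DecisionTreeClassifier(
        criterion="gini",
        min_samples_split=params.minsplit,
        ccp_alpha=params.cp * root_risk,
        random_state=params.seed,
    )
    tree.fit(X.to_numpy(dtype=float), y)
    rules = _extract_rules(tree, list(X.columns))
    if len(rules) == 1:
        warnings.warn(
            "pruning removed every split; returning a single-leaf tree", stacklevel=2
        )
    return DecisionTreeResult(tree=tree, rules=rules, params=params,
                              feature_names=list(X.columns))


def _extract_rules(tree: DecisionTreeClassifier, names: list[str]) -> list[TreeRule]:
    t = tree.tree_
    rules: list[TreeRule] = []

    def walk(node: int, conds: list[str]):
        if t.children_left[node] == -1:
            frac = t.value[node][0]  # per-class fractions within the node
            n = int(round(t.weighted_n_node_samples[node]))
            best = int(np.argmax(frac))
            acc = float(frac[best] / frac.sum())
            rules.append(
                TreeRule(
                    path=" AND ".join(conds) if conds else "(root)",
                    predicted_class=tree.classes_[best],
                    n=n,
                    accuracy=acc,
                )
            )
            return
        f, thr = names[t.feature[node]], t.threshold[node]
        walk(t.children_left[node], conds + [f"{f} <= {thr:.4g}"])
        walk(t.children_right[node], conds + [f"{f} > {thr:.4g}"])

    walk(0, [])
    return rules


def cohen_kappa(confusion) -> float:
    """Cohen's kappa from a k x k confusion-count matrix."""
    c = np.asarray(confusion, dtype=float)
    total = c.sum()
    if total <= 0:
        raise ValueError("confusion matrix must contain counts")
    p_obs = c.trace() / total
    p_exp = float(np.sum(c.sum(axis=0) * c.sum(axis=1)) / total**2)
    if p_exp >= 1.0:
        raise ValueError("degenerate marginals: expected agreement is 1, kappa undefined")
    return float((p_obs - p_exp) / (1.0 - p_exp))


_ENSEMBLE_FACTORIES = {
    "rf": lambda seed: RandomForestClassifier(
        n_estimators=300, max_features=4, random_state=seed
    ),
    "gradient_boosting": lambda seed: GradientBoostingClassifier(random_state=seed),
    "svm": lambda seed: make_pipeline(StandardScaler(), SVC(random_state=seed)),
    "tree_boosting": lambda seed: AdaBoostClassifier(
        estimator=DecisionTreeClassifier(max_depth=3),
        n_estimators=100,
        random_state=seed,
    ),
}


def compare_ensembles(
    features: pd.DataFrame,
    labels,
    methods=("rf", "gradient_boosting", "svm", "tree_boosting"),
    cv_folds: int = 5,
    n_repeats: int = 3,
    seed: int = 0,
) -> dict[str, dict[str, np.ndarray]]:
    """Repeated stratified CV comparison of classifier families.

    Returns, per method, the per-fold accuracy and Cohen-kappa arrays —
    the raw material of an accuracy/kappa comparison plot.
    """
    X, y = _validate_features(features, labels)
    unknown = [m for m in methods if m not in _ENSEMBLE_FACTORIES]
    if unknown:
        raise ValueError(
            f"unknown method(s) {unknown}; choose from {sorted(_ENSEMBLE_FACTORIES)}"
        )
    Xv = X.to_numpy(dtype=float)
    classes = np.unique(y)
    cv = RepeatedStratifiedKFold(n_splits=cv_folds, n_repeats=n_repeats, random_state=seed)
    out: dict[str, dict[str, np.ndarray]] = {}
    for m in methods:
        accs, kappas = [], []
        for fold_i, (tr, te) in enumerate(cv.split(Xv, y)):
            clf = _ENSEMBLE_FACTORIES[m](seed + fold_i)
            clf.fit(Xv[tr], y[tr])
            pred = clf.predict(Xv[te])
            accs.append(float(np.mean(pred == y[te])))
            conf = np.zeros((classes.size, classes.size))
            for t_, p_ in zip(y[te], pred):
                conf[np.searchsorted(classes, t_), np.searchsorted(classes, p_)] += 1
            try:
                kappas.append(cohen_kappa(conf))
            except ValueError:
                kappas.append(np.nan)
        out[m] = {"accuracy": np.array(accs), "kappa": np.array(kappas)}
    return out
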