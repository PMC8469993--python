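"""Classifier training, evaluation and threshold calibration.

The predictor is a random forest over the 60 features, but six algorithm
families can be trained and compared on identical cross-validation folds:
random forest (rf), Gaussian naive Bayes (nb), logistic regression (lr),
multilayer perceptron (mlp), AdaBoost over decision stumps (ada) and
extreme gradient boosting (xgb). Hyperparameters are pinned explicitly so
results are stable across library versions.

Evaluation follows two protocols: stratified 10-fold cross-validation with
pooled out-of-fold propensities, and repeated stratified 80/20 independent
tests summarised by median ACC/AUC/MCC. The decision cutoff is calibrated
to equalise the false-positive and false-negative rates.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold, StratifiedShuffleSplit
from sklearn.naive_bayes import GaussianNB
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier

from .features import BINDING_BLOCK_NAMES, FEATURE_NAMES, MSA_BLOCK_NAMES, ContractError

ALGORITHMS: tuple[str, ...] = ("rf", "nb", "lr", "mlp", "ada", "xgb")

VARIANTS: dict[str, list[str]] = {
    "full": list(FEATURE_NAMES),
    "msa_only": list(MSA_BLOCK_NAMES),
    "br_only": list(BINDING_BLOCK_NAMES),
}


def _xgb_available() -> bool:
    try:
        import xgboost  # noqa: F401
        return True
    except ImportError:
        return False


def make_classifier(algorithm: str, seed: int):
    """Instantiate one of the six algorithm families with pinned hyperparameters."""
    if algorithm == "rf":
        return RandomForestClassifier(
            n_estimators=100, criterion="gini", max_features="sqrt",
            random_state=seed, n_jobs=1,
        )
    if algorithm == "nb":
        return GaussianNB()
    if algorithm == "lr":
        return Pipeline([
            ("scale", StandardScaler()),
            ("lr", LogisticRegression(max_iter=1000, random_state=seed)),
        ])
    if algorithm == "mlp":
        return Pipeline([
            ("scale", StandardScaler()),
            ("mlp", MLPClassifier(hidden_layer_sizes=(100,), max_iter=300,
                                  random_state=seed)),
        ])
    if algorithm == "ada":
        return AdaBoostClassifier(
            estimator=DecisionTreeClassifier(max_depth=1, random_state=seed),
            n_estimators=100, random_state=seed,
        )
    if algorithm == "xgb":
        from xgboost import XGBClassifier
        return XGBClassifier(
            n_estimators=100, random_state=seed, n_jobs=1,
            eval_metric="logloss", verbosity=0,
        )
    raise ContractError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


# --------------------------------------------------------------------------
# Metrics
# --------------------------------------------------------------------------

def auc_score(propensities: np.ndarray, labels: np.ndarray) -> float:
    """Rank-based AUC with average-rank tie handling (Mann-Whitney form)."""
    y = np.asarray(labels)
    s = np.asarray(propensities, dtype=float)
    if y.shape != s.shape:
        raise ContractError("labels and propensities must align")
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("AUC requires both classes")
    ranks = rankdata(s)
    u = ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def mcc_score(predicted: np.ndarray, labels: np.ndarray) -> float:
    """Matthews correlation coefficient; 0 when any confusion-matrix marginal is 0."""
    yp = np.asarray(predicted)
    y = np.asarray(labels)
    if yp.shape != y.shape:
        raise ContractError("labels and predictions must align")
    tp = int(((yp == 1) & (y == 1)).sum())
    tn = int(((yp == 0) & (y == 0)).sum())
    fp = int(((yp == 1) & (y == 0)).sum())
    fn = int(((yp == 0) & (y == 1)).sum())
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return float((tp * tn - fp * fn) / np.sqrt(denom))


def metrics(
    predicted: np.ndarray, propensities: np.ndarray, labels: np.ndarray
) -> tuple[float, float, float]:
    """(AUC, ACC, MCC) for binary predictions with their underlying propensities."""
    y = np.asarray(labels)
    yp = np.asarray(predicted)
    if len(y) == 0:
        raise ContractError("empty input")
    if yp.shape != y.shape:
        raise ContractError("labels and predictions must align")
    auc = auc_score(propensities, y)
    acc = float((yp == y).mean())
    mcc = mcc_score(yp, y)
    return auc, acc, mcc


def calibrate_threshold(propensities: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff that equalises false-positive and false-negative rates.

    Candidate cutoffs are the midpoints between consecutive sorted unique
    propensities plus the endpoints 0 and 1; the cutoff minimising
    |FPR - FNR| is returned, with ties broken toward 0.5.
    """
    s = np.asarray(propensities, dtype=float)
    y = np.asarray(labels)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("threshold calibration requires both classes")
    uniq = np.unique(s)
    candidates = np.concatenate(([0.0], (uniq[:-1] + uniq[1:]) / 2.0, [1.0]))
    best_cut, best_gap = 0.5, np.inf
    for cut in candidates:
        calls = (s > cut).astype(int)
        fpr = ((calls == 1) & (y == 0)).sum() / n_neg
        fnr = ((calls == 0) & (y == 1)).sum() / n_pos
        gap = abs(fpr - fnr)
        if gap < best_gap - 1e-15 or (
            abs(gap - best_gap) <= 1e-15 and abs(cut - 0.5) < abs(best_cut - 0.5)
        ):
            best_cut, best_gap = float(cut), gap
    return best_cut


# --------------------------------------------------------------------------
# Bundles and protocols
# --------------------------------------------------------------------------

@dataclass
class EvaluationResult:
    """Pooled AUC/ACC/MCC with the per-fold (or per-repeat) breakdown."""

    auc: float
    acc: float
    mcc: float
    n_pos: int
    n_neg: int
    per_fold: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc, "acc": self.acc, "mcc": self.mcc,
            "n_pos": self.n_pos, "n_neg": self.n_neg, "per_fold": self.per_fold,
        }


@dataclass
class ModelBundle:
    """A fitted classifier plus its feature schema and calibrated cutoff."""

    algorithm: str
    model: object
    schema: list[str]
    threshold: float
    metadata: dict = field(default_factory=dict)

    def predict_propensity(self, features: pd.DataFrame) -> np.ndarray:
        if list(features.columns) != self.schema:
            missing = set(self.schema) - set(features.columns)
            if missing:
                raise ContractError(f"feature table is missing columns {sorted(missing)}")
            features = features[self.schema]
        return self.model.predict_proba(features.to_numpy())[:, 1]

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        return (self.predict_propensity(features) > self.threshold).astype(int)

    def save(self, path) -> None:
        joblib.dump(
            {"format_version": 1, "algorithm": self.algorithm, "model": self.model,
             "schema": self.schema, "threshold": self.threshold,
             "metadata": self.metadata},
            path,
        )

    @classmethod
    def load(cls, path) -> "ModelBundle":
        payload = joblib.load(path)
        return cls(
            algorithm=payload["algorithm"], model=payload["model"],
            schema=payload["schema"], threshold=payload["threshold"],
            metadata=payload.get("metadata", {}),
        )


def _select_variant(features: pd.DataFrame, variant: str) -> pd.DataFrame:
    if variant not in VARIANTS:
        raise ContractError(f"unknown variant {variant!r}; choose from {sorted(VARIANTS)}")
    if variant == "full":
        # every numeric column; lets toy tables and ablation-ready tables alike train
        return features
    missing = set(VARIANTS[variant]) - set(features.columns)
    if missing:
        raise ContractError(f"feature table is missing columns {sorted(missing)}")
    return features[VARIANTS[variant]]


def _check_training_inputs(features: pd.DataFrame, labels: np.ndarray) -> np.ndarray:
    y = np.asarray(labels).astype(int)
    if len(features) != len(y):
        raise ContractError("features and labels must align")
    if features.isna().any().any():
        raise ContractError("feature table contains missing values")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ContractError("training requires both classes")
    if counts.min() < 2:
        raise ContractError("training requires at least 2 records per class")
    return y


def train(
    features: pd.DataFrame,
    labels: np.ndarray,
    algorithm: str = "rf",
    variant: str = "full",
    seed: int = 0,
    calibrate: bool = True,
) -> ModelBundle:
    """Fit one classifier on a feature table; deterministic given the seed.

    The decision threshold is calibrated on the training propensities
    (FPR = FNR) unless ``calibrate`` is off, in which case it defaults to 0.5.
    """
    y = _check_training_inputs(features, labels)
    X = _select_variant(features, variant)
    clf = make_classifier(algorithm, seed)
    clf.fit(X.to_numpy(), y)
    threshold = 0.5
    if calibrate:
        threshold = calibrate_threshold(clf.predict_proba(X.to_numpy())[:, 1], y)
    return ModelBundle(
        algorithm=algorithm, model=clf, schema=list(X.columns), threshold=threshold,
        metadata={"seed": seed, "n_records": len(y), "variant": variant},
    )


def cross_validate(
    features: pd.DataFrame,
    labels: np.ndarray,
    algorithm: str = "rf",
    k_folds: int = 10,
    seed: int = 0,
    variant: str = "full",
    folds: Optional[list[tuple[np.ndarray, np.ndarray]]] = None,
) -> EvaluationResult:
    """Stratified k-fold cross-validation; the headline metrics score the pooled
    out-of-fold propensities, per-fold metrics are retained.

    ``folds`` overrides the fold assignment so several algorithms can be
    compared on identical partitions.
    """
    y = _check_training_inputs(features, labels)
    if len(y) < k_folds:
        raise ContractError(f"need at least {k_folds} records for {k_folds}-fold CV")
    X = _select_variant(features, variant)
    if folds is None:
        skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
        folds = list(skf.split(X, y))
    oof = np.full(len(y), np.nan)
    per_fold = []
    for fold_idx, (tr, te) in enumerate(folds):
        clf = make_classifier(algorithm, seed)
        clf.fit(X.iloc[tr].to_numpy(), y[tr])
        prop = clf.predict_proba(X.iloc[te].to_numpy())[:, 1]
        oof[te] = prop
        fold_auc = auc_score(prop, y[te])
        per_fold.append({"fold": fold_idx, "auc": fold_auc, "n": len(te)})
    assert not np.isnan(oof).any(), "folds must partition the records"
    calls = (oof > 0.5).astype(int)
    auc, acc, mcc = metrics(calls, oof, y)
    return EvaluationResult(
        auc=auc, acc=acc, mcc=mcc,
        n_pos=int((y == 1).sum()), n_neg=int((y == 0).sum()), per_fold=per_fold,
    )


def independent_test(
    features: pd.DataFrame,
    labels: np.ndarray,
    algorithm: str = "rf",
    train_frac: float = 0.8,
    n_repeats: int = 20,
    seed: int = 0,
    variant: str = "full",
) -> tuple[list[EvaluationResult], dict[str, float]]:
    """Repeated stratified train/test splits; returns every repeat plus the
    median ACC, AUC and MCC over repeats."""
    y = _check_training_inputs(features, labels)
    X = _select_variant(features, variant)
    splitter = StratifiedShuffleSplit(
        n_splits=n_repeats, train_size=train_frac, random_state=seed
    )
    results: list[EvaluationResult] = []
    for rep, (tr, te) in enumerate(splitter.split(X, y)):
        clf = make_classifier(algorithm, seed + rep)
        clf.fit(X.iloc[tr].to_numpy(), y[tr])
        prop = clf.predict_proba(X.iloc[te].to_numpy())[:, 1]
        cut = calibrate_threshold(clf.predict_proba(X.iloc[tr].to_numpy())[:, 1], y[tr])
        calls = (prop > cut).astype(int)
        auc, acc, mcc = metrics(calls, prop, y[te])
        results.append(EvaluationResult(
            auc=auc, acc=acc, mcc=mcc,
            n_pos=int((y[te] == 1).sum()), n_neg=int((y[te] == 0).sum()),
            per_fold=[{"repeat": rep}],
        ))
    medians = {
        "acc": float(np.median([r.acc for r in results])),
        "auc": float(np.median([r.auc for r in results])),
        "mcc": float(np.median([r.mcc for r in results])),
    }
    return results, medians


def compare_algorithms(
    features: pd.DataFrame,
    labels: np.ndarray,
    seed: int = 0,
    k_folds: int = 10,
    variant: str = "full",
    algorithms: Sequence[str] = ALGORITHMS,
) -> pd.DataFrame:
    """Cross-validate every algorithm on identical stratified folds.

    Returns a table ranked by AUC (descending). An unavailable optional
    backend (xgb) is skipped with a warning rather than failing.
    """
    y = _check_training_inputs(features, labels)
    X = _select_variant(features, variant)
    skf = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(X, y))
    rows = []
    for algo in algorithms:
        if algo == "xgb" and not _xgb_available():
            warnings.warn("xgboost backend unavailable; skipping xgb")
            continue
        res = cross_validate(X, y, algorithm=algo, k_folds=k_folds, seed=seed,
                             variant=variant, folds=folds)
        rows.append({"algorithm": algo, "auc": res.auc, "acc": res.acc, "mcc": res.mcc})
    table = pd.DataFrame(rows).sort_values("auc", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)


def prediction_overlap(
    propensities_a: np.ndarray,
    cutoff_a: float,
    propensities_b: np.ndarray,
    cutoff_b: float,
    labels: np.ndarray,
) -> dict[str, int]:
    """Partition records by which of two thresholded predictors calls them correctly."""
    a = np.asarray(propensities_a, dtype=float)
    b = np.asarray(propensities_b, dtype=float)
    y = np.asarray(labels)
    if a.shape != y.shape or b.shape != y.shape:
        raise ContractError("vectors must align")
    ok_a = (a > cutoff_a).astype(int) == y
    ok_b = (b > cutoff_b).astype(int) == y
    return {
        "both_correct": int((ok_a & ok_b).sum()),
        "only_a": int((ok_a & ~ok_b).sum()),
        "only_b": int((~ok_a & ok_b).sum()),
        "both_wrong": int((~ok_a & ~ok_b).sum()),
    }


def bootstrap_auc_difference(
    propensities_a: np.ndarray,
    propensities_b: np.ndarray,
    labels: np.ndarray,
    n_resamples: int = 10000,
    seed: int = 0,
) -> dict[str, float]:
    """Paired-bootstrap test for the AUC difference between two propensity vectors.

    Resamples records with replacement and reports the two-sided p-value for
    a zero AUC difference. This is the package's own significance procedure.
    """
    a = np.asarray(propensities_a, dtype=float)
    b = np.asarray(propensities_b, dtype=float)
    y = np.asarray(labels)
    rng = np.random.default_rng(seed)
    observed = auc_score(a, y) - auc_score(b, y)
    n = len(y)
    diffs = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.integers(0, n, n)
        yy = y[idx]
        if yy.min() == yy.max():  # degenerate resample: no information
            diffs[i] = 0.0
            continue
        diffs[i] = auc_score(a[idx], yy) - auc_score(b[idx], yy)
    # two-sided p from the bootstrap distribution centred on the observed diff
    p = 2.0 * min((diffs <= 0).mean(), (diffs >= 0).mean())
    return {"auc_diff": float(observed), "p_value": float(min(1.0, max(p, 1.0 / n_resamples)))}


def write_evaluation(result: EvaluationResult, path) -> None:
    """Serialize an evaluation result as JSON."""
    with open(path, "w") as fh:
        json.dump(result.to_dict(), fh, indent=2)
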