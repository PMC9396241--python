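"""Outcome classifiers and their cross-validated evaluation.

A random forest (2000 trees, minimum node size 1, 7 candidate features per
split) predicts the binary outcomes — visual responder status and
extendable treatment interval — from the 50-dimensional predictor vector.
Evaluation follows a stratified 10-fold cross-validation: every eye's
probability of the positive class comes from a forest never trained on it,
and the out-of-bag (OOB) error of each fold's forest is recorded as the
validation error.  Performance is summarised by the pooled out-of-fold ROC
curve, the AUC (Mann-Whitney concordance, ties counted one half), a 95%
percentile-bootstrap confidence interval (1000 case resamples), the
Youden-optimal operating point and the sensitivity at 80% specificity, and
a permutation feature importance (mean out-of-fold accuracy decrease when a
feature's column is shuffled).

Three nested predictor sets are evaluated: all 50 features, baseline-only
(the 15 baseline imaging features + baseline BCVA + age + sex), and the 45
imaging features alone.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold

from .errors import ContractError, MissingDataError
from . import oct_features as of

FEATURE_SET_NAMES = ("all", "baseline_only", "imaging_only")


@dataclass
class RfConfig:
    """Random-forest hyperparameters (held fixed across experiments)."""

    n_trees: int = 2000
    min_node_size: int = 1
    mtry: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ContractError("n_trees must be >= 1")


@dataclass
class CvEvaluation:
    """Pooled out-of-fold predictions and derived performance summaries."""

    probs: np.ndarray  # per-sample out-of-fold P(positive)
    labels: np.ndarray
    folds: np.ndarray
    auc: float
    auc_ci_95: Tuple[float, float]
    roc_points: pd.DataFrame  # columns fpr, tpr, threshold
    operating_points: Dict[str, Tuple[float, float]]  # name -> (sens, spec)
    oob_errors: np.ndarray  # one per fold
    feature_set: str = "all"
    auc_per_fold: np.ndarray = field(default_factory=lambda: np.array([]))
    importances: Optional[pd.Series] = None
    eye_ids: Tuple[str, ...] = ()
    _models: list = field(default_factory=list, repr=False)
    _feature_names: Tuple[str, ...] = ()


def select_features(names: Sequence[str], feature_set: str) -> List[str]:
    """Column subset for one of the nested predictor sets."""
    names = list(names)
    if feature_set == "all":
        return names
    if feature_set == "imaging_only":
        return [n for n in names if not n.startswith(("bcva", "age", "sex"))]
    if feature_set == "baseline_only":
        return [n for n in names if n.endswith("_M0") or n in ("age", "sex")]
    raise ContractError(f"unknown feature set {feature_set!r}")


def stratified_kfold(labels: Sequence, k: int = 10, seed: int = 0) -> np.ndarray:
    """Fold index per sample; per-fold class counts within 1 of proportional."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ContractError("labels must contain at least two classes")
    if counts.min() < k:
        raise ContractError(
            f"smallest class has {counts.min()} samples, fewer than k={k} folds"
        )
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    folds = np.empty(len(y), dtype=int)
    for j, (_, test_idx) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        folds[test_idx] = j
    return folds


def _forest(rf: RfConfig, n_features: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=rf.n_trees,
        min_samples_leaf=rf.min_node_size,
        max_features=min(rf.mtry, n_features),
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )


def roc_auc(probs: Sequence[float], labels: Sequence) -> Tuple[float, pd.DataFrame]:
    """AUC as the Mann-Whitney concordance probability, plus the ROC curve.

    AUC = P(score_pos > score_neg) + 0.5 P(tie), computed from midranks;
    the ROC has one point per distinct threshold.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ContractError("both classes must be present")
    ranks = rankdata(p)  # midranks handle ties at 1/2
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y.astype(int), p, drop_intermediate=False)
    roc = pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})
    return float(auc), roc


def bootstrap_auc_ci(
    probs: Sequence[float],
    labels: Sequence,
    n_boot: int = 1000,
    seed: int = 0,
) -> Tuple[float, float]:
    """95% percentile interval of the AUC over case resamples.

    Resamples containing a single class are redrawn.
    """
    p = np.asarray(probs, dtype=float)
    y = np.asarray(labels).astype(bool)
    rng = np.random.default_rng(seed)
    n = len(p)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if y[idx].any() and (~y[idx]).any():
                break
        yy = y[idx]
        ranks = rankdata(p[idx])
        n_pos = int(yy.sum())
        aucs[b] = (ranks[yy].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * (n - n_pos))
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def operating_points(roc: pd.DataFrame) -> Dict[str, Tuple[float, float]]:
    """Youden-optimal point (ties to higher specificity) and sens at 80% spec."""
    if len(roc) == 0:
        raise ContractError("empty ROC")
    fpr = roc["fpr"].to_numpy()
    tpr = roc["tpr"].to_numpy()
    j = tpr - fpr
    best = np.flatnonzero(j == j.max())
    pick = best[np.argmin(fpr[best])]  # ties: prefer higher specificity
    youden = (float(tpr[pick]), float(1.0 - fpr[pick]))
    ok = np.flatnonzero(1.0 - fpr >= 0.80)
    if len(ok):
        # smallest specificity still >= 0.80, i.e. the largest admissible fpr
        pick80 = ok[np.argmax(fpr[ok])]
        spec80 = (float(tpr[pick80]), float(1.0 - fpr[pick80]))
    else:
        spec80 = (0.0, 1.0)
    return {"youden": youden, "spec80": spec80}


def cv_predict(
    features: pd.DataFrame,
    labels: Sequence,
    rf: Optional[RfConfig] = None,
    k: int = 10,
    feature_set: str = "all",
    n_boot: int = 1000,
    seed: Optional[int] = None,
    keep_models: bool = True,
) -> CvEvaluation:
    """Stratified k-fold cross-validated forest predictions and ROC summary.

    The probability of the positive class is the fraction of trees voting
    positive (with pure leaves, the forest vote share).
    """
    rf = rf or RfConfig()
    seed = rf.seed if seed is None else seed
    X = features.to_numpy(dtype=float) if isinstance(features, pd.DataFrame) else np.asarray(features, float)
    names = list(features.columns) if isinstance(features, pd.DataFrame) else [f"f{i}" for i in range(X.shape[1])]
    cols = select_features(names, feature_set)
    col_idx = [names.index(c) for c in cols]
    X = X[:, col_idx]
    y = np.asarray(labels).astype(int)
    if np.isnan(X).any():
        raise MissingDataError("feature matrix contains missing values")
    folds = stratified_kfold(y, k=k, seed=seed)
    probs = np.full(len(y), np.nan)
    oob = np.empty(k)
    auc_per_fold = np.empty(k)
    models = []
    for j in range(k):
        test = folds == j
        clf = _forest(rf, len(cols), seed=seed + j)
        clf.fit(X[~test], y[~test])
        probs[test] = clf.predict_proba(X[test])[:, list(clf.classes_).index(1)]
        oob[j] = 1.0 - clf.oob_score_
        if len(np.unique(y[test])) == 2:
            auc_per_fold[j], _ = roc_auc(probs[test], y[test])
        else:
            auc_per_fold[j] = np.nan
        if keep_models:
            models.append((clf, np.flatnonzero(test)))
    auc, roc = roc_auc(probs, y)
    ci = bootstrap_auc_ci(probs, y, n_boot=n_boot, seed=seed)
    ops = operating_points(roc)
    eye_ids = tuple(features.index.astype(str)) if isinstance(features, pd.DataFrame) else ()
    return CvEvaluation(
        probs=probs,
        labels=y,
        folds=folds,
        auc=auc,
        auc_ci_95=ci,
        roc_points=roc,
        operating_points=ops,
        oob_errors=oob,
        feature_set=feature_set,
        auc_per_fold=auc_per_fold,
        eye_ids=eye_ids,
        _models=models,
        _feature_names=tuple(cols),
    )


def permutation_importance(
    evaluation: CvEvaluation,
    features: pd.DataFrame,
    seed: int = 0,
    n_perm: int = 10,
) -> pd.Series:
    """Mean out-of-fold accuracy decrease per permuted feature, sorted.

    For each fitted fold model, each feature column of the fold's test block
    is shuffled ``n_perm`` times and the drop in accuracy relative to the
    unpermuted block is averaged.
    """
    if not evaluation._models:
        raise ContractError("cv_predict must be run with keep_models=True first")
    cols = list(evaluation._feature_names)
    X = features[cols].to_numpy(dtype=float)
    y = evaluation.labels
    rng = np.random.default_rng(seed)
    drops = np.zeros(len(cols))
    weight = 0.0
    for clf, test_idx in evaluation._models:
        Xt, yt = X[test_idx], y[test_idx]
        base_acc = float(np.mean(clf.predict(Xt) == yt))
        m = len(test_idx)
        for jf in range(len(cols)):
            # stack the n_perm shuffled copies into one batched prediction
            perms = np.repeat(Xt[None, :, :], n_perm, axis=0).reshape(n_perm * m, -1)
            for r in range(n_perm):
                perms[r * m : (r + 1) * m, jf] = Xt[rng.permutation(m), jf]
            acc = np.mean(
                (clf.predict(perms) == np.tile(yt, n_perm)).reshape(n_perm, m), axis=1
            )
            drops[jf] += m * (base_acc - float(acc.mean()))
        weight += m
    imp = pd.Series(drops / weight, index=cols, name="importance")
    return imp.sort_values(ascending=False)


def run_experiment(
    features: pd.DataFrame,
    labels: pd.Series,
    target: str,
    feature_sets: Sequence[str] = FEATURE_SET_NAMES,
    rf: Optional[RfConfig] = None,
    k: int = 10,
    n_boot: int = 1000,
    seed: int = 0,
    compute_importance: bool = True,
    importance_n_perm: int = 10,
    null_permute: bool = False,
) -> Dict[str, CvEvaluation]:
    """One full prediction experiment: one evaluation per predictor set.

    ``labels`` is joined to ``features`` on eye_id; any mismatch raises with
    the orphan ids listed.  ``null_permute`` shuffles the labels once
    (seeded) before evaluation, severing any label-feature dependence — the
    negative control for the whole pipeline.
    """
    rf = rf or RfConfig(seed=seed)
    feat_ids = set(features.index.astype(str))
    lab_ids = set(labels.index.astype(str))
    if feat_ids != lab_ids:
        orphans = sorted(feat_ids ^ lab_ids)
        raise MissingDataError(f"feature/label eye_id mismatch ({target}): {orphans[:20]}")
    y = labels.loc[features.index].astype(int)
    if null_permute:
        rng = np.random.default_rng(seed + 0x5EED)
        y = pd.Series(rng.permutation(y.to_numpy()), index=y.index)
    results: Dict[str, CvEvaluation] = {}
    for fs in feature_sets:
        ev = cv_predict(
            features, y, rf=rf, k=k, feature_set=fs, n_boot=n_boot, seed=seed,
            keep_models=compute_importance,
        )
        if compute_importance:
            ev.importances = permutation_importance(
                ev, features, seed=seed, n_perm=importance_n_perm
            )
            ev._models = []  # free memory once importances are extracted
        results[fs] = ev
    return results


def experiment_report(results: Dict[str, CvEvaluation], target: str) -> dict:
    """JSON-serialisable summary of one experiment."""
    out = {"target": target, "feature_sets": {}}
    for fs, ev in results.items():
        entry = {
            "auc": ev.auc,
            "auc_ci_95": list(ev.auc_ci_95),
            "auc_per_fold_mean": float(np.nanmean(ev.auc_per_fold)),
            "oob_error_mean": float(ev.oob_errors.mean()),
            "operating_points": {kk: list(vv) for kk, vv in ev.operating_points.items()},
            "n": int(len(ev.labels)),
            "prevalence": float(ev.labels.mean()),
        }
        if ev.importances is not None:
            entry["top10_importances"] = {
                str(kk): float(vv) for kk, vv in ev.importances.head(10).items()
            }
        out["feature_sets"][fs] = entry
    return out


def hanley_mcneil_se(auc: float, n_pos: int, n_neg: int) -> float:
    """Standard error of the AUC under the Hanley-McNeil approximation."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    return float(np.sqrt(var))
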