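"""Treatment-response (pCR) prediction from per-sample CoMi indices.

Each patient is represented by the vector of their per-sample CoMi
statistics over the discovered patterns.  Prediction follows the clinical
protocol the method was designed for: within each training portion the
imbalanced cohort is rebalanced by under-sampling the majority class,
features are ranked by a per-feature Welch t test between responders and
non-responders, and one of three classifiers (logistic regression, Gaussian
naive Bayes, linear SVM) is fit on the top features.  Performance is the
held-out AUC averaged over repeated stratified cross-validation; feature
selection never sees held-out samples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.svm import SVC

from .comi_core import hypergeom_overlap_p
from .data_model import PatternKey

logger = logging.getLogger(__name__)

CLASSIFIERS = ("logistic", "naive_bayes", "svm")


@dataclass
class CohortMatrix:
    """Per-sample CoMi statistics (features × samples) with binary outcomes."""

    feature_keys: list[PatternKey]
    sample_ids: list[str]
    values: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.feature_keys), len(self.sample_ids)):
            raise ValueError("values shape mismatch")
        if self.labels.shape[0] != len(self.sample_ids):
            raise ValueError("label count must equal sample count")
        if set(np.unique(self.labels)) - {0, 1}:
            raise ValueError("labels must be binary 0/1")
        if len(np.unique(self.labels)) < 2:
            raise ValueError("both outcome classes must be present")
        if not np.isfinite(self.values).all():
            raise ValueError("cohort values must be finite")

    def subset_samples(self, idx: Sequence[int]) -> "CohortMatrix":
        idx = list(idx)
        return CohortMatrix(
            feature_keys=list(self.feature_keys),
            sample_ids=[self.sample_ids[i] for i in idx],
            values=self.values[:, idx],
            labels=self.labels[idx],
        )


@dataclass
class PredictionReport:
    mean_auc: float
    auc_per_repeat: list[float]
    roc_points: list[tuple[float, float]]
    selected_features: list[PatternKey]
    classifier_name: str
    n_repeats: int
    n_folds: int
    seed: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.mean_auc <= 1.0):
            raise ValueError("mean AUC outside [0, 1]")


def _welch_t_rows(x0: np.ndarray, x1: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Welch t and two-sided p between two sample groups."""
    n0, n1 = x0.shape[1], x1.shape[1]
    m0, m1 = x0.mean(axis=1), x1.mean(axis=1)
    v0, v1 = x0.var(axis=1, ddof=1), x1.var(axis=1, ddof=1)
    se2 = v0 / n0 + v1 / n1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (m1 - m0) / np.sqrt(se2)
        df = se2**2 / ((v0 / n0) ** 2 / (n0 - 1) + (v1 / n1) ** 2 / (n1 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    # degenerate variance: equal constants carry no evidence, unequal
    # constants are perfectly separated (capped statistic, floor p)
    zero = se2 == 0
    equal = zero & (m0 == m1)
    sep = zero & ~equal
    t[equal], p[equal] = 0.0, 1.0
    t[sep] = np.sign(m1[sep] - m0[sep]) * 1e6
    p[sep] = np.finfo(float).tiny
    return t, np.minimum(p, 1.0)


def select_features(train: CohortMatrix, n_features: int) -> list[PatternKey]:
    """Features ranked by ascending Welch-t p-value between outcome classes.

    Ties are broken lexicographically by pattern key for determinism.
    """
    if n_features < 1 or n_features > len(train.feature_keys):
        raise ValueError("n_features outside 1..|features|")
    mask1 = train.labels == 1
    if mask1.sum() < 2 or (~mask1).sum() < 2:
        raise ValueError("each class needs >= 2 training samples")
    _, p = _welch_t_rows(train.values[:, ~mask1], train.values[:, mask1])
    order = sorted(range(len(train.feature_keys)), key=lambda i: (p[i], train.feature_keys[i]))
    return [train.feature_keys[i] for i in order[:n_features]]


def undersample(labels: Sequence[int], seed: int = 0) -> list[int]:
    """Balanced sample indices: every minority sample + a random equal-size
    subset of the majority class."""
    labels = np.asarray(labels, dtype=int)
    idx0 = np.flatnonzero(labels == 0)
    idx1 = np.flatnonzero(labels == 1)
    if idx0.size == 0 or idx1.size == 0:
        raise ValueError("both classes must be present")
    if idx0.size == idx1.size:
        return list(range(labels.size))
    minority, majority = (idx1, idx0) if idx1.size < idx0.size else (idx0, idx1)
    rng = np.random.default_rng(seed)
    kept_majority = rng.choice(majority, size=minority.size, replace=False)
    return sorted(np.concatenate([minority, kept_majority]).tolist())


def _make_classifier(name: str):
    if name == "logistic":
        return LogisticRegression(max_iter=1000)
    if name == "naive_bayes":
        return GaussianNB()
    if name == "svm":
        return SVC(kernel="linear")
    raise ValueError(f"unknown classifier {name!r}; choose from {CLASSIFIERS}")


def _scores(clf, X: np.ndarray) -> np.ndarray:
    if hasattr(clf, "decision_function"):
        return clf.decision_function(X)
    return clf.predict_proba(X)[:, 1]


def cross_validate(
    cohort: CohortMatrix,
    classifier: str = "logistic",
    n_features: int = 27,
    n_folds: int = 5,
    n_repeats: int = 100,
    seed: int = 0,
) -> PredictionReport:
    """Repeated stratified k-fold cross-validation with in-fold feature
    selection and under-sampling.

    Each repeat shuffles a stratified fold assignment (each fold ~20% test
    for the default 5 folds); within every training portion the majority
    class is under-sampled, the top ``n_features`` features are selected,
    and the classifier is fit on those features only.  Held-out scores are
    pooled per repeat into one AUC; the report averages AUCs over repeats.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n_features = min(n_features, len(cohort.feature_keys))
    minority = min((cohort.labels == 1).sum(), (cohort.labels == 0).sum())
    if minority < n_folds:
        raise ValueError("minority class smaller than the fold count")
    aucs: list[float] = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    last_features: list[PatternKey] = []
    for rep in range(n_repeats):
        rep_seed = (seed + 10007 * rep) % (2**31 - 1)
        skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rep_seed)
        rep_scores = np.empty(len(cohort.sample_ids))
        for fold_i, (train_idx, test_idx) in enumerate(
            skf.split(cohort.values.T, cohort.labels)
        ):
            train = cohort.subset_samples(train_idx)
            balanced = train.subset_samples(
                undersample(train.labels, seed=rep_seed + fold_i)
            )
            feats = select_features(balanced, n_features)
            rows = [cohort.feature_keys.index(f) for f in feats]
            clf = _make_classifier(classifier)
            clf.fit(balanced.values[rows].T, balanced.labels)
            rep_scores[test_idx] = _scores(clf, cohort.values[np.ix_(rows, test_idx)].T)
            last_features = feats
        aucs.append(float(roc_auc_score(cohort.labels, rep_scores)))
        pooled_scores.append(rep_scores)
        pooled_labels.append(cohort.labels)
    all_scores = np.concatenate(pooled_scores)
    all_labels = np.concatenate(pooled_labels)
    fpr, tpr, _ = roc_curve(all_labels, all_scores)
    return PredictionReport(
        mean_auc=float(np.mean(aucs)),
        auc_per_repeat=aucs,
        roc_points=list(zip(fpr.tolist(), tpr.tolist())),
        selected_features=last_features,
        classifier_name=classifier,
        n_repeats=n_repeats,
        n_folds=n_folds,
        seed=seed,
    )


def feature_outcome_correlation(
    cohort: CohortMatrix, features: Sequence[PatternKey]
) -> pd.DataFrame:
    """Pearson r between each feature's values and the 0/1 outcome vector."""
    rows = []
    y = cohort.labels.astype(float)
    yc = y - y.mean()
    for feat in features:
        if feat not in cohort.feature_keys:
            raise ValueError(f"feature {feat} not in cohort")
        x = cohort.values[cohort.feature_keys.index(feat)]
        xc = x - x.mean()
        denom = np.sqrt((xc**2).sum() * (yc**2).sum())
        if denom == 0:
            rows.append({"pattern_key": feat, "pearson_r": 0.0, "constant": True})
        else:
            rows.append(
                {
                    "pattern_key": feat,
                    "pearson_r": float((xc * yc).sum() / denom),
                    "constant": False,
                }
            )
    return pd.DataFrame(rows)


def write_cohort(cohort: CohortMatrix, path, header_extra: str = "") -> None:
    """Cohort TSV: one feature row per pattern key ('mirna|term') plus a
    ``__label__`` row with the 0/1 outcomes."""
    from pathlib import Path

    with open(Path(path), "w") as fh:
        fh.write(f"# comireg-cohort\tversion=1\tn_features={len(cohort.feature_keys)}")
        if header_extra:
            fh.write(f"\t{header_extra}")
        fh.write("\n")
        fh.write("feature\t" + "\t".join(cohort.sample_ids) + "\n")
        fh.write("__label__\t" + "\t".join(str(v) for v in cohort.labels) + "\n")
        for i, key in enumerate(cohort.feature_keys):
            row = "\t".join(f"{v:.17g}" for v in cohort.values[i])
            fh.write(f"{key[0]}|{key[1]}\t{row}\n")


def read_cohort(path) -> CohortMatrix:
    from pathlib import Path

    from .data_model import FormatError

    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header.startswith("# comireg-cohort"):
            raise FormatError(f"{path}: not a comireg cohort file")
        sample_ids = fh.readline().rstrip("\n").split("\t")[1:]
        label_fields = fh.readline().rstrip("\n").split("\t")
        if label_fields[0] != "__label__":
            raise FormatError(f"{path}: missing __label__ row")
        labels = np.array([int(v) for v in label_fields[1:]])
        feature_keys: list[PatternKey] = []
        rows = []
        for lineno, line in enumerate(fh, start=4):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(sample_ids) + 1:
                raise FormatError(f"{path}:{lineno}: wrong field count")
            mirna, _, term = fields[0].partition("|")
            feature_keys.append((mirna, term))
            rows.append([float(v) for v in fields[1:]])
    return CohortMatrix(
        feature_keys=feature_keys,
        sample_ids=sample_ids,
        values=np.array(rows),
        labels=labels,
    )


def feature_list_overlap_p(
    list_a: Sequence[PatternKey],
    list_b: Sequence[PatternKey],
    universe_size: int,
) -> float:
    """Hypergeometric p-value for the overlap of two feature lists.

    The universe size (the number of patterns both lists were drawn from)
    must be declared by the caller.
    """
    a, b = set(list_a), set(list_b)
    if len(a) > universe_size or len(b) > universe_size:
        raise ValueError("list larger than the declared universe")
    overlap = len(a & b)
    return hypergeom_overlap_p(overlap, len(a), len(b), universe_size)
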