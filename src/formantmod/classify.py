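"""Vocal-type separability from formant-modulation features.

Start-vs-end comparison of how well the two vocal types can be told apart
from F1/F3 modulation alone: per vocalization, 18 features ({F1, F3} x
{CV, 4 MD quartiles, 4 SE quartiles}) are embedded in 2-D with UMAP
(fit independently per epoch), a random forest is trained on 70% of the
embedded points, and discriminability is scored on the held-out 30% by
ROC/AUC. The two epochs' AUCs are compared with an unpaired DeLong test;
balanced accuracy, sensitivity and specificity complete the report as
prevalence-independent metrics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_curve
from sklearn.model_selection import train_test_split
from sklearn.preprocessing import StandardScaler

__all__ = [
    "ClassificationReport",
    "FeatureMatrix",
    "auc_mann_whitney",
    "build_features",
    "compare_epochs",
    "confusion_metrics",
    "delong_auc_variance",
    "delong_test",
    "embed",
    "rf_train_test",
]

#: the 18 modulation features used for classification, F1 and F3 only
FEATURE_COLUMNS = [
    f"{m}_{f}"
    for f in ("F1", "F3")
    for m in ("cv", "md_q1", "md_q2", "md_q3", "md_q4", "se_q1", "se_q2", "se_q3", "se_q4")
]

#: BL is scored as the positive class throughout
POSITIVE_CLASS = "BL"


@dataclass
class FeatureMatrix:
    X: np.ndarray  # (n, 18)
    labels: np.ndarray  # vocal_type per row
    epoch: np.ndarray  # "start" | "end"
    voc_ids: np.ndarray
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_COLUMNS))

    def subset(self, epoch: str) -> "FeatureMatrix":
        m = self.epoch == epoch
        return FeatureMatrix(self.X[m], self.labels[m], self.epoch[m], self.voc_ids[m])


def build_features(summaries: pd.DataFrame, min_per_epoch: int = 10) -> FeatureMatrix:
    """Assemble the complete-case 18-feature matrix with epoch labels.

    Epochs follow the quartiles of the sampled-day distribution: rows from
    days at or below the first quartile are "start", at or above the third
    quartile "end"; the middle half is dropped (labelled "mid" internally).
    """
    missing = [c for c in FEATURE_COLUMNS if c not in summaries.columns]
    if missing:
        raise ValueError(f"summary table missing feature columns: {missing}")
    df = summaries.dropna(subset=FEATURE_COLUMNS).reset_index(drop=True)
    days = np.sort(summaries["day"].unique())
    q1, q3 = np.quantile(days, [0.25, 0.75])
    epoch = np.where(df["day"] <= q1, "start", np.where(df["day"] >= q3, "end", "mid"))
    keep = epoch != "mid"
    fm = FeatureMatrix(
        X=df.loc[keep, FEATURE_COLUMNS].to_numpy(dtype=float),
        labels=df.loc[keep, "vocal_type"].to_numpy(),
        epoch=epoch[keep],
        voc_ids=df.loc[keep, "voc_id"].to_numpy(),
    )
    for ep in ("start", "end"):
        if int((fm.epoch == ep).sum()) < min_per_epoch:
            raise ValueError(f"fewer than {min_per_epoch} complete cases in {ep} epoch")
    return fm


def embed(X: np.ndarray, seed: int = 0, n_neighbors: int = 15) -> np.ndarray:
    """2-D UMAP embedding of the standardized feature matrix (fixed seed).

    ``n_neighbors`` is reduced automatically when the sample is small.
    """
    import umap  # deferred: slow import

    n = X.shape[0]
    if n < 3:
        raise ValueError("need at least 3 rows to embed")
    nn = int(min(n_neighbors, n - 1))
    Xs = StandardScaler().fit_transform(X)
    reducer = umap.UMAP(n_components=2, n_neighbors=nn, random_state=int(seed), n_jobs=1)
    return np.asarray(reducer.fit_transform(Xs), dtype=float)


def confusion_metrics(predictions: np.ndarray, labels: np.ndarray) -> dict[str, float]:
    """Balanced accuracy, sensitivity and specificity with BL positive.

    Sensitivity is the recall of BL, specificity the recall of CD; balanced
    accuracy is their mean — all prevalence-independent.
    """
    predictions = np.asarray(predictions)
    labels = np.asarray(labels)
    out: dict[str, float] = {}
    pos = labels == POSITIVE_CLASS
    neg = ~pos
    out["sensitivity"] = (
        float((predictions[pos] == POSITIVE_CLASS).mean()) if pos.any() else float("nan")
    )
    out["specificity"] = (
        float((predictions[neg] != POSITIVE_CLASS).mean()) if neg.any() else float("nan")
    )
    out["balanced_accuracy"] = (out["sensitivity"] + out["specificity"]) / 2.0
    return out


def auc_mann_whitney(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney rank statistic: P(score_pos > score_neg),
    ties counted half."""
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = s[labels == POSITIVE_CLASS]
    neg = s[labels != POSITIVE_CLASS]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("need both classes for an AUC")
    gt = (pos[:, None] > neg[None, :]).sum()
    eq = (pos[:, None] == neg[None, :]).sum()
    return float((gt + 0.5 * eq) / (pos.size * neg.size))


@dataclass
class ClassificationReport:
    epoch: str
    coords: np.ndarray
    labels: np.ndarray
    oob_error: float
    class_errors: dict[str, float]
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    auc: float
    test_scores: np.ndarray  # P(BL) on the held-out split
    test_labels: np.ndarray
    confusion: pd.DataFrame
    metrics: dict[str, float]
    importances: pd.DataFrame

    def to_dict(self) -> dict:
        return {
            "epoch": self.epoch,
            "oob_error": self.oob_error,
            "class_errors": self.class_errors,
            "auc": self.auc,
            **self.metrics,
        }


def rf_train_test(
    coords: np.ndarray,
    labels: np.ndarray,
    train_frac: float = 0.7,
    n_trees: int = 800,
    seed: int = 0,
    epoch: str = "",
) -> ClassificationReport:
    """Random forest on the 2-D embedding with a 70/30 train/test split.

    OOB error and per-class error come from the training forest; ROC, AUC
    and the confusion metrics from held-out class-probability scores.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size != 2:
        raise ValueError("rf_train_test requires exactly two classes")
    Xtr, Xte, ytr, yte = train_test_split(
        coords,
        labels,
        train_size=train_frac,
        random_state=int(seed),
        stratify=labels,
    )
    if np.unique(ytr).size < 2 or np.unique(yte).size < 2:
        raise ValueError("a split ended up single-class; increase the sample")
    rf = RandomForestClassifier(
        n_estimators=int(n_trees), oob_score=True, random_state=int(seed), n_jobs=1
    )
    rf.fit(Xtr, ytr)
    oob_pred = rf.classes_[np.argmax(rf.oob_decision_function_, axis=1)]
    oob_error = float((oob_pred != ytr).mean())
    class_errors = {
        str(c): float((oob_pred[ytr == c] != c).mean()) for c in classes
    }
    pos_col = int(np.where(rf.classes_ == POSITIVE_CLASS)[0][0])
    scores = rf.predict_proba(Xte)[:, pos_col]
    fpr, tpr, _ = roc_curve(yte == POSITIVE_CLASS, scores)
    auc = auc_mann_whitney(scores, yte)
    pred = rf.predict(Xte)
    confusion = pd.crosstab(
        pd.Series(yte, name="truth"), pd.Series(pred, name="predicted"), dropna=False
    )
    importances = pd.DataFrame(
        {"feature": ["V1", "V2"], "mean_decrease_impurity": rf.feature_importances_}
    )
    return ClassificationReport(
        epoch=epoch,
        coords=coords,
        labels=labels,
        oob_error=oob_error,
        class_errors=class_errors,
        roc_fpr=fpr,
        roc_tpr=tpr,
        auc=auc,
        test_scores=scores,
        test_labels=yte,
        confusion=confusion,
        metrics=confusion_metrics(pred, yte),
        importances=importances,
    )


def delong_auc_variance(scores: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    """DeLong estimate of (AUC, var(AUC)) from placement values.

    For positives i: V10_i = mean over negatives of [s_i > s_j] + 0.5[s_i = s_j],
    symmetrically V01 for negatives; var(AUC) = var(V10)/m + var(V01)/n.
    """
    s = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = s[labels == POSITIVE_CLASS]
    neg = s[labels != POSITIVE_CLASS]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("need both classes")
    if np.unique(s).size == 1:
        raise ValueError("degenerate scores: all values tied")
    cmp = (pos[:, None] > neg[None, :]).astype(float) + 0.5 * (pos[:, None] == neg[None, :])
    auc = float(cmp.mean())
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    var = float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)
    return auc, var


def delong_test(
    scores1: np.ndarray,
    labels1: np.ndarray,
    scores2: np.ndarray,
    labels2: np.ndarray,
) -> dict[str, float]:
    """Unpaired DeLong comparison of two ROC curves.

    The two curves must come from independent samples (here: disjoint
    vocalizations at the start vs the end of the experiment). The statistic
    is ``D = (AUC1 - AUC2) / sqrt(var1 + var2)`` with DeLong variances, and
    the two-sided p-value uses a t reference with Welch-Satterthwaite
    degrees of freedom.
    """
    a1, v1 = delong_auc_variance(scores1, labels1)
    a2, v2 = delong_auc_variance(scores2, labels2)
    n1 = np.asarray(scores1).size
    n2 = np.asarray(scores2).size
    denom = np.sqrt(v1 + v2)
    if denom == 0:
        return {"D": 0.0, "df": float(n1 + n2 - 2), "p": 1.0, "auc1": a1, "auc2": a2}
    D = (a1 - a2) / denom
    num = (v1 + v2) ** 2
    den = (v1**2) / (n1 - 1) + (v2**2) / (n2 - 1)
    df = float(num / den) if den > 0 else float(n1 + n2 - 2)
    p = float(2.0 * sps.t.sf(abs(D), df))
    return {"D": float(D), "df": df, "p": p, "auc1": a1, "auc2": a2}


def compare_epochs(
    features: FeatureMatrix,
    seed: int = 0,
    train_frac: float = 0.7,
    n_trees: int = 800,
    n_neighbors: int = 15,
) -> tuple[ClassificationReport, ClassificationReport, dict[str, float]]:
    """Embed, classify and DeLong-compare the start and end epochs."""
    reports = []
    for ep in ("start", "end"):
        sub = features.subset(ep)
        coords = embed(sub.X, seed=seed, n_neighbors=n_neighbors)
        reports.append(
            rf_train_test(
                coords, sub.labels, train_frac=train_frac, n_trees=n_trees, seed=seed, epoch=ep
            )
        )
    start, end = reports
    dl = delong_test(start.test_scores, start.test_labels, end.test_scores, end.test_labels)
    return start, end, dl
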