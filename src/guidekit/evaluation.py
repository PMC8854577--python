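"""Model evaluation: correlations, ROC/AUROC, cross-validation, and the
training-size and context-length sweeps used to pick the model configuration.

Observed cutting scores are binarized into active/inactive at a CS threshold
(1.67 for Cas12a, 4.91 for Cas9 by default — the mean CS of the validated
high-activity clusters); AUROC then measures how well predictions rank active
guides above inactive ones.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve, auc
from sklearn.model_selection import KFold

from .model import ACTIVE_CS_THRESHOLDS
from .genome import context_window, one_hot_batch

CAS12A_ACTIVE_CS = ACTIVE_CS_THRESHOLDS["cas12a"]
CAS9_ACTIVE_CS = ACTIVE_CS_THRESHOLDS["cas9"]


@dataclass
class EvaluationReport:
    n: int
    pearson: float = np.nan
    spearman: float = np.nan
    auroc: float = np.nan
    fpr: np.ndarray | None = None
    tpr: np.ndarray | None = None
    thresholds: np.ndarray | None = None
    cs_threshold: float | None = None
    per_fold: list = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {"n": self.n, "pearson": self.pearson, "spearman": self.spearman,
             "auroc": self.auroc, "cs_threshold": self.cs_threshold,
             "per_fold": self.per_fold}
        if self.fpr is not None:
            d["roc"] = [{"fpr": float(f), "tpr": float(t)}
                        for f, t in zip(self.fpr, self.tpr)]
        return d

    def write_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    def write_roc_tsv(self, path) -> None:
        pd.DataFrame({"fpr": self.fpr, "tpr": self.tpr}).to_csv(
            path, sep="\t", index=False)


def correlations(pred, obs) -> tuple[float, float]:
    """Pearson and Spearman correlation between predictions and observations.

    Returns (nan, nan) with a warning when either vector has zero variance.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if len(pred) != len(obs):
        raise ValueError("length mismatch")
    if len(pred) < 3:
        raise ValueError("need at least 3 points")
    if pred.std() == 0 or obs.std() == 0:
        warnings.warn("zero variance: correlation undefined, returning NaN")
        return float("nan"), float("nan")
    r_p = stats.pearsonr(pred, obs).statistic
    r_s = stats.spearmanr(pred, obs).statistic
    return float(r_p), float(r_s)


def binarize_and_roc(pred, obs, cs_threshold: float) -> EvaluationReport:
    """Threshold observed CS into active (> threshold) / inactive, then ROC
    over prediction cutoffs; AUROC by trapezoidal integration."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    labels = (obs > cs_threshold).astype(int)
    if labels.min() == labels.max():
        raise ValueError(f"only one class after thresholding at {cs_threshold} "
                         f"({labels.sum()} of {len(labels)} active)")
    fpr, tpr, thr = roc_curve(labels, pred)
    rep = EvaluationReport(n=len(pred), auroc=float(auc(fpr, tpr)),
                           fpr=fpr, tpr=tpr, thresholds=thr,
                           cs_threshold=cs_threshold)
    rep.pearson, rep.spearman = correlations(pred, obs)
    return rep


def crossvalidate(X, y, model_factory, folds: int = 5, seed: int = 0) -> dict:
    """K-fold cross-validation; each example is tested exactly once.

    ``model_factory()`` must return a fresh unfitted estimator.  Reports
    per-fold Pearson/Spearman plus their mean and sd (the error bars of a
    cross-validated comparison).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if folds > len(y):
        raise ValueError(f"folds={folds} exceeds dataset size {len(y)}")
    kf = KFold(n_splits=folds, shuffle=True, random_state=seed)
    per_fold = []
    for tr, te in kf.split(X):
        est = model_factory()
        est.fit(X[tr], y[tr])
        r_p, r_s = correlations(est.predict(X[te]), y[te])
        per_fold.append({"n_test": len(te), "pearson": r_p, "spearman": r_s})
    pearsons = np.array([f["pearson"] for f in per_fold])
    spearmans = np.array([f["spearman"] for f in per_fold])
    return {"folds": folds, "per_fold": per_fold,
            "pearson_mean": float(pearsons.mean()),
            "pearson_sd": float(pearsons.std(ddof=1)),
            "spearman_mean": float(spearmans.mean()),
            "spearman_sd": float(spearmans.std(ddof=1))}


def downsample_curve(X, y, sizes, model_factory, seed: int = 0,
                     test_fraction: float = 0.2, min_size: int = 50) -> dict:
    """Performance as a function of training-set size.

    For each size: seeded subsample, train/test split, fit, correlate.
    Sizes below ``min_size`` are skipped with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    rng = np.random.default_rng(seed)
    curve = {}
    for size in sizes:
        if size < min_size:
            warnings.warn(f"size {size} below minimum trainable ({min_size}); skipped")
            continue
        if size > len(y):
            raise ValueError(f"size {size} exceeds dataset size {len(y)}")
        sub = rng.choice(len(y), size=size, replace=False)
        n_te = max(1, int(round(test_fraction * size)))
        te, tr = sub[:n_te], sub[n_te:]
        est = model_factory()
        est.fit(X[tr], y[tr])
        r_p, r_s = correlations(est.predict(X[te]), y[te])
        curve[int(size)] = {"pearson": r_p, "spearman": r_s}
    return curve


def context_sweep(genome, guides, cs, lengths, model_factory,
                  nuclease: str = "cas12a", folds: int = 5,
                  seed: int = 0) -> dict:
    """Cross-validated performance per context-window length.

    ``model_factory(length)`` returns a fresh estimator for that input
    length.  Lengths shorter than spacer+PAM raise (no truncation into the
    protospacer).
    """
    cs = np.asarray(cs, dtype=float).ravel()
    out = {}
    for length in lengths:
        windows = [context_window(genome, g, nuclease, length) for g in guides]
        X = one_hot_batch(windows).reshape(len(windows), -1)
        out[int(length)] = crossvalidate(
            X, cs, lambda: model_factory(length), folds=folds, seed=seed)
    return out
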