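"""Level-0 random forests, stacked logistic assembling, metrics and CV.

Three level-0 predictors emit interaction probabilities from different views
of a candidate pair:

* ``SA-RF`` — random forest on the deepest hidden activations of the
  pretrained stacked auto-encoder;
* ``SA-FT-RF`` — random forest on the activations of the supervised
  fine-tuned stack;
* ``RPISeq-RF`` — random forest on the raw composition features (RNA 4-mer
  plus protein conjoint-triad frequencies).

A level-1 logistic regression is then fit on the level-0 probability vector
p, scoring a pair as ``P(+1 | p) = 1 / (1 + exp(-w . p))``.  With equal
weights this degenerates to averaging the level-0 outputs; with a single
non-zero weight it approaches voting with one dominant voter.  To keep the
stacking honest, the level-1 model is always trained on out-of-fold level-0
probabilities obtained by an inner cross-validation of the forests within
the training data.

Evaluation uses stratified 5-fold cross-validation with accuracy,
sensitivity, specificity, precision, the Matthews correlation coefficient
and ROC/AUC, reported per fold and as mean +/- SD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence

import numpy as np
from scipy.special import expit
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold, cross_val_predict

from . import sae as sae_mod
from .sae import StackedAutoEncoder, TrainConfig

LEVEL0_NAMES = ("SA-RF", "SA-FT-RF", "RPISeq-RF")
STRATEGIES = ("stacked", "average", "majority")


@dataclass
class Level0Predictor:
    """A named, fitted random forest emitting class-1 probabilities."""

    name: str
    forest: RandomForestClassifier

    def predict_proba1(self, X: np.ndarray) -> np.ndarray:
        return self.forest.predict_proba(X)[:, 1]


@dataclass
class EnsembleModel:
    """Level-0 predictors plus the level-1 combination rule."""

    level0: list[Level0Predictor] = field(default_factory=list)
    w: Optional[np.ndarray] = None  # len(level0) weights + intercept
    strategy: str = "stacked"

    def __post_init__(self) -> None:
        if self.strategy not in STRATEGIES:
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "stacked" and self.w is not None and self.level0:
            if len(self.w) != len(self.level0) + 1:
                raise ValueError(
                    "w must hold one weight per level-0 predictor plus an "
                    "intercept"
                )


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricsReport:
    """Per-fold metrics with mean and SD summaries."""

    folds: list[dict] = field(default_factory=list)  # per-fold metric dicts

    def _values(self, key: str) -> np.ndarray:
        return np.array([f[key] for f in self.folds], dtype=float)

    def mean(self, key: str) -> float:
        return float(np.nanmean(self._values(key)))

    def sd(self, key: str) -> float:
        return float(np.nanstd(self._values(key), ddof=1))

    def summary(self) -> dict:
        keys = ("acc", "sen", "spec", "prec", "mcc", "auc")
        return {k: (self.mean(k), self.sd(k)) for k in keys}


# --- confusion-table metrics ------------------------------------------------


def confusion(
    scores: np.ndarray, y: Sequence[int], threshold: float = 0.5
) -> ConfusionCounts:
    """Threshold scores at ``threshold`` (>= is positive) and count outcomes."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    y = np.asarray(y, dtype=int)
    pred = scores >= threshold
    pos = y == 1
    return ConfusionCounts(
        TP=int(np.sum(pred & pos)),
        TN=int(np.sum(~pred & ~pos)),
        FP=int(np.sum(pred & ~pos)),
        FN=int(np.sum(~pred & pos)),
    )


def metrics(c: ConfusionCounts) -> dict:
    """Accuracy, sensitivity, specificity, precision and MCC from counts.

    Rates with a zero denominator are reported as NaN with a warning; an MCC
    with a zero denominator is defined as 0.
    """
    if c.total == 0:
        raise ValueError("empty confusion table")
    TP, TN, FP, FN = c.TP, c.TN, c.FP, c.FN

    def _rate(num: int, den: int, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)", stacklevel=3)
            return float("nan")
        return num / den

    acc = (TP + TN) / c.total
    sen = _rate(TP, TP + FN, "sensitivity")
    spec = _rate(TN, TN + FP, "specificity")
    prec = _rate(TP, TP + FP, "precision")
    denom = (TP + FP) * (TP + FN) * (TN + FP) * (TN + FN)
    mcc = 0.0 if denom == 0 else (TP * TN - FP * FN) / np.sqrt(denom)
    return {"acc": acc, "sen": sen, "spec": spec, "prec": prec, "mcc": float(mcc)}


def roc_auc(scores: np.ndarray, y: Sequence[int]) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC plus ROC points (fpr, tpr) by trapezoidal integration.

    Equals the Mann-Whitney probability that a random positive outscores a
    random negative, with ties counting one half.
    """
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("roc_auc requires both classes present")
    fpr, tpr, _ = roc_curve(y, np.asarray(scores, dtype=float))
    auc = float(np.trapezoid(tpr, fpr))
    return auc, fpr, tpr


# --- level-0 / level-1 training --------------------------------------------


def _make_forest(n_trees: int, seed: int) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=n_trees, random_state=seed, n_jobs=1
    )


def train_level0(
    features: Dict[str, np.ndarray],
    y: Sequence[int],
    n_trees: int = 500,
    seed: int = 0,
) -> list[Level0Predictor]:
    """Fit one random forest per feature source (keys of ``features``)."""
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("training labels must contain both classes")
    predictors = []
    for i, (name, X) in enumerate(features.items()):
        X = np.asarray(X, dtype=float)
        if X.shape[0] != len(y):
            raise ValueError(
                f"feature source {name!r} has {X.shape[0]} rows for "
                f"{len(y)} labels"
            )
        forest = _make_forest(n_trees, seed + i)
        forest.fit(X, y)
        predictors.append(Level0Predictor(name=name, forest=forest))
    return predictors


def stack(level0_probs: np.ndarray, y: Sequence[int], seed: int = 0) -> EnsembleModel:
    """Fit the level-1 logistic regression on level-0 probability outputs."""
    P = np.asarray(level0_probs, dtype=float)
    if np.any(P < 0.0) or np.any(P > 1.0):
        raise ValueError("level-0 probabilities must lie in [0, 1]")
    y = np.asarray(y, dtype=int)
    if len(set(y.tolist())) < 2:
        raise ValueError("stacking requires both classes present")
    lr = LogisticRegression(random_state=seed)
    lr.fit(P, y)
    w = np.concatenate([lr.coef_.ravel(), lr.intercept_])
    return EnsembleModel(level0=[], w=w, strategy="stacked")


def assemble_predict(model: EnsembleModel, level0_probs: np.ndarray) -> np.ndarray:
    """Combine level-0 probabilities into final scores per the strategy."""
    P = np.asarray(level0_probs, dtype=float)
    if np.any(P < 0.0) or np.any(P > 1.0):
        raise ValueError("level-0 probabilities must lie in [0, 1]")
    if model.strategy == "stacked":
        if model.w is None:
            raise ValueError("stacked model has no fitted weights")
        w, b = model.w[:-1], model.w[-1]
        return expit(P @ w + b)
    if model.strategy == "average":
        return P.mean(axis=1)
    # majority: fraction of predictors voting positive
    return (P >= 0.5).mean(axis=1)


# --- cross-validation -------------------------------------------------------


@dataclass
class EnsembleConfig:
    """Configuration of the full two-level pipeline."""

    sae: TrainConfig = field(default_factory=TrainConfig)
    n_trees: int = 500
    inner_folds: int = 3


def _minmax_fit(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    lo = X.min(axis=0)
    span = X.max(axis=0) - lo
    span[span == 0.0] = 1.0
    return lo, span


def _minmax_apply(X, lo, span):
    return (X - lo) / span


def fold_assignments(
    y: np.ndarray, n_folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified, seeded fold split as (train_idx, test_idx) pairs."""
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    return [(tr, te) for tr, te in skf.split(np.zeros(len(y)), y)]


def _level0_probs(
    predictors: Sequence[Level0Predictor], views: Dict[str, np.ndarray]
) -> np.ndarray:
    return np.column_stack([p.predict_proba1(views[p.name]) for p in predictors])


@dataclass
class FittedPipeline:
    """Everything needed to score new pairs: scaler, SAEs, forests, stacker."""

    scaler: tuple[np.ndarray, np.ndarray]
    sae_pre: StackedAutoEncoder
    sae_ft: StackedAutoEncoder
    level0: list[Level0Predictor]
    stacker: EnsembleModel

    def views(self, X_pair: np.ndarray, X_raw: np.ndarray) -> Dict[str, np.ndarray]:
        Xs = _minmax_apply(X_pair, *self.scaler)
        return {
            "SA-RF": sae_mod.transform(self.sae_pre, Xs),
            "SA-FT-RF": sae_mod.transform(self.sae_ft, Xs),
            "RPISeq-RF": X_raw,
        }

    def predict(self, X_pair: np.ndarray, X_raw: np.ndarray) -> np.ndarray:
        probs = _level0_probs(self.level0, self.views(X_pair, X_raw))
        return assemble_predict(self.stacker, probs)


def fit_pipeline(
    X_pair: np.ndarray,
    X_raw: np.ndarray,
    y: np.ndarray,
    cfg: EnsembleConfig,
    seed: int = 0,
) -> FittedPipeline:
    """Train the full two-level model on one training set.

    The auto-encoders and forests see only the given data; the level-1
    logistic regression is fit on inner out-of-fold level-0 probabilities so
    its weights are not estimated from resubstitution scores.
    """
    y = np.asarray(y, dtype=int)
    scaler = _minmax_fit(X_pair)
    Xs = _minmax_apply(X_pair, *scaler)
    sae_cfg = TrainConfig(**{**vars(cfg.sae), "seed": seed})
    pre = sae_mod.pretrain(Xs, sae_cfg)
    ft = sae_mod.fine_tune(pre, Xs, y, sae_cfg)
    views = {
        "SA-RF": sae_mod.transform(pre, Xs),
        "SA-FT-RF": sae_mod.transform(ft, Xs),
        "RPISeq-RF": X_raw,
    }
    level0 = train_level0(views, y, n_trees=cfg.n_trees, seed=seed)
    # inner out-of-fold probabilities for honest level-1 training
    inner = StratifiedKFold(
        n_splits=cfg.inner_folds, shuffle=True, random_state=seed + 7
    )
    oof = np.column_stack(
        [
            cross_val_predict(
                clone(p.forest), views[p.name], y, cv=inner,
                method="predict_proba", n_jobs=1,
            )[:, 1]
            for p in level0
        ]
    )
    stacker = stack(oof, y, seed=seed)
    return FittedPipeline(
        scaler=scaler, sae_pre=pre, sae_ft=ft, level0=level0, stacker=stacker
    )


def cross_validate(
    X_pair: np.ndarray,
    X_raw: np.ndarray,
    y: Sequence[int],
    cfg: Optional[EnsembleConfig] = None,
    n_folds: int = 5,
    seed: int = 0,
) -> Dict[str, MetricsReport]:
    """Stratified k-fold evaluation of every predictor and assembling strategy.

    Returns one :class:`MetricsReport` per level-0 predictor and per
    assembling strategy ("stacked", "average", "majority").  All feature
    learning and classifier fitting happens inside each fold's training
    split; test folds are disjoint and cover the data exactly once.
    """
    cfg = cfg or EnsembleConfig()
    y = np.asarray(y, dtype=int)
    n_pos, n_neg = int(np.sum(y == 1)), int(np.sum(y == 0))
    if min(n_pos, n_neg) < n_folds:
        raise ValueError(
            f"need at least {n_folds} samples of each class, have "
            f"{n_pos} positives / {n_neg} negatives"
        )
    X_pair = np.asarray(X_pair, dtype=float)
    X_raw = np.asarray(X_raw, dtype=float)
    reports: Dict[str, MetricsReport] = {
        name: MetricsReport() for name in (*LEVEL0_NAMES, *STRATEGIES)
    }
    for fold_i, (tr, te) in enumerate(fold_assignments(y, n_folds, seed)):
        pipe = fit_pipeline(
            X_pair[tr], X_raw[tr], y[tr], cfg, seed=seed + 101 * fold_i
        )
        test_views = pipe.views(X_pair[te], X_raw[te])
        probs = _level0_probs(pipe.level0, test_views)
        scored = {p.name: probs[:, i] for i, p in enumerate(pipe.level0)}
        scored["stacked"] = assemble_predict(pipe.stacker, probs)
        scored["average"] = assemble_predict(
            EnsembleModel(level0=pipe.level0, strategy="average"), probs
        )
        scored["majority"] = assemble_predict(
            EnsembleModel(level0=pipe.level0, strategy="majority"), probs
        )
        for name, s in scored.items():
            m = metrics(confusion(s, y[te]))
            m["auc"], _, _ = roc_auc(s, y[te])
            m["fold"] = fold_i
            reports[name].folds.append(m)
    return reports
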