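"""Simplified subtype prediction: a categorical naive Bayes classifier.

The integrative subtyping needs every genomic layer; for new cohorts a
five-feature surrogate suffices: the signature cluster, the CNV
cluster, FAT4 mutation status, LRP1B mutation status, and the CCNE1
copy-number state (del/neutral/amp).  A categorical naive Bayes model
with Laplace smoothing is fit on the discovery cohort's subtype labels
and applied to new samples; internal validity is measured by
stratified 10-fold cross-validation.

Feature selection offers two modes: ``fixed`` returns the published
five-feature panel; ``greedy`` runs a transparent forward wrapper
maximizing mean CV accuracy (stopping when the improvement drops below
0.5%), since the original dimensionality-reduction procedure is not
specified.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

log = logging.getLogger(__name__)

FIXED_FEATURES = ["sig_cluster", "cnv_cluster", "FAT4_mut", "LRP1B_mut", "CCNE1_cnv"]

#: reserved vocabulary slot for categories unseen at fit time
UNSEEN = "__unseen__"


def ccne1_cnv_feature(discrete_matrix: pd.DataFrame) -> pd.Series:
    """Encode CCNE1 discrete states as a 3-level {del, neutral, amp} feature."""
    states = discrete_matrix["CCNE1"]
    return pd.Series(
        np.where(states >= 1, "amp", np.where(states <= -1, "del", "neutral")),
        index=discrete_matrix.index, name="CCNE1_cnv",
    )


@dataclass
class NaiveBayesModel:
    classes: list[int]
    priors: np.ndarray                       # len C, sums to 1
    features: list[str]
    vocabularies: dict[str, list[str]]       # observed categories per feature
    conditionals: dict[str, np.ndarray]      # feature -> C x (V+1), rows sum to 1
    alpha: float = 1.0

    def __post_init__(self) -> None:
        assert abs(self.priors.sum() - 1) < 1e-9
        for name, table in self.conditionals.items():
            assert np.allclose(table.sum(axis=1), 1.0), name
            assert (table > 0).all(), f"zero probability in {name}"

    def to_json(self) -> str:
        return json.dumps({
            "classes": self.classes,
            "priors": self.priors.tolist(),
            "features": self.features,
            "vocabularies": self.vocabularies,
            "conditionals": {k: v.tolist() for k, v in self.conditionals.items()},
            "alpha": self.alpha,
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "NaiveBayesModel":
        raw = json.loads(text)
        return cls(
            classes=raw["classes"], priors=np.array(raw["priors"]),
            features=raw["features"], vocabularies=raw["vocabularies"],
            conditionals={k: np.array(v) for k, v in raw["conditionals"].items()},
            alpha=raw["alpha"],
        )


def fit_nb(features: pd.DataFrame, labels: pd.Series, alpha: float = 1.0) -> NaiveBayesModel:
    """Fit a categorical naive Bayes model.

    Priors are maximum likelihood; each feature's per-class conditional
    distribution is Laplace-smoothed with ``alpha`` over its observed
    vocabulary plus one reserved slot for unseen categories, so every
    probability is strictly positive and prediction never fails on a
    new category.
    """
    labels = labels.reindex(features.index)
    if labels.isna().any():
        raise ValueError("labels missing for some samples")
    classes = sorted(labels.unique())
    if any((labels == c).sum() == 0 for c in classes):
        raise ValueError("every class needs at least one sample")
    priors = np.array([(labels == c).mean() for c in classes])
    vocabularies: dict[str, list[str]] = {}
    conditionals: dict[str, np.ndarray] = {}
    for col in features.columns:
        values = features[col].astype(str)
        vocab = sorted(values.unique())
        table = np.zeros((len(classes), len(vocab) + 1))
        for i, c in enumerate(classes):
            sub = values[labels == c]
            for j, v in enumerate(vocab):
                table[i, j] = (sub == v).sum() + alpha
            table[i, -1] = alpha  # unseen slot
        conditionals[col] = table / table.sum(axis=1, keepdims=True)
        vocabularies[col] = vocab
    return NaiveBayesModel(classes=[int(c) for c in classes], priors=priors,
                           features=list(features.columns),
                           vocabularies=vocabularies, conditionals=conditionals,
                           alpha=alpha)


def predict(model: NaiveBayesModel, features: pd.DataFrame) -> pd.DataFrame:
    """Posterior per class and the argmax subtype for each sample.

    Ties break toward the lower subtype index (logged).  Returns a frame
    with one ``p_<class>`` column per class plus ``subtype``; posterior
    rows sum to one.
    """
    missing = [f for f in model.features if f not in features.columns]
    if missing:
        raise ValueError(f"missing feature column(s) {missing}")
    if features[model.features].isna().any().any():
        raise ValueError("missing feature values")
    n = len(features)
    log_post = np.tile(np.log(model.priors), (n, 1))
    for col in model.features:
        vocab = {v: j for j, v in enumerate(model.vocabularies[col])}
        table = np.log(model.conditionals[col])
        idx = features[col].astype(str).map(lambda v: vocab.get(v, len(vocab))).to_numpy()
        log_post += table[:, idx].T
    log_post -= log_post.max(axis=1, keepdims=True)
    post = np.exp(log_post)
    post /= post.sum(axis=1, keepdims=True)
    best = np.argmax(post, axis=1)  # argmax takes the first (lowest) index on ties
    ties = (post == post[np.arange(n), best][:, None]).sum(axis=1) > 1
    if ties.any():
        log.info("%d prediction(s) had tied posteriors; lower subtype index kept",
                 int(ties.sum()))
    out = pd.DataFrame(post, index=features.index,
                       columns=[f"p_{c}" for c in model.classes])
    out["subtype"] = [model.classes[b] for b in best]
    return out


def cross_validate(features: pd.DataFrame, labels: pd.Series, n_folds: int = 10,
                   seed: int = 0, alpha: float = 1.0, stratified: bool = True) -> dict:
    """Stratified k-fold cross-validation accuracy.

    Every sample is tested exactly once; fold assignment is
    deterministic given ``seed``.  Returns overall accuracy plus
    per-fold detail.
    """
    labels = labels.reindex(features.index)
    if n_folds > len(features):
        raise ValueError(f"n_folds={n_folds} > n={len(features)}")
    if stratified and n_folds > labels.value_counts().min():
        raise ValueError("n_folds exceeds the smallest class size")
    splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    y = labels.to_numpy()
    folds = []
    correct = 0
    for fold_id, (train, test) in enumerate(splitter.split(features, y), start=1):
        model = fit_nb(features.iloc[train], labels.iloc[train], alpha=alpha)
        pred = predict(model, features.iloc[test])["subtype"].to_numpy()
        n_ok = int((pred == y[test]).sum())
        correct += n_ok
        folds.append({"fold": fold_id, "n_test": len(test), "n_correct": n_ok,
                      "accuracy": n_ok / len(test)})
    return {"accuracy": correct / len(features), "n_folds": n_folds, "folds": folds}


def select_features(features: pd.DataFrame, labels: pd.Series, method: str = "fixed",
                    seed: int = 0, n_folds: int = 10, alpha: float = 1.0,
                    min_improvement: float = 0.005) -> tuple[list[str], pd.DataFrame]:
    """Select predictor features.

    ``fixed`` returns the five-feature panel (erroring if any is
    absent); ``greedy`` is forward wrapper selection maximizing CV
    accuracy, stopping when the gain is below ``min_improvement``.
    Returns the selection and a trace table.
    """
    if method == "fixed":
        missing = [f for f in FIXED_FEATURES if f not in features.columns]
        if missing:
            raise ValueError(f"fixed feature(s) absent from table: {missing}")
        trace = pd.DataFrame({"step": range(1, 6), "feature": FIXED_FEATURES})
        return list(FIXED_FEATURES), trace
    if method != "greedy":
        raise ValueError(f"unknown selection method {method!r}")
    selected: list[str] = []
    best_acc = 0.0
    rows = []
    remaining = list(features.columns)
    while remaining:
        scored = []
        for cand in remaining:
            acc = cross_validate(features[selected + [cand]], labels,
                                 n_folds=n_folds, seed=seed, alpha=alpha)["accuracy"]
            scored.append((acc, cand))
        acc, cand = max(scored)
        if acc - best_acc < min_improvement and selected:
            break
        selected.append(cand)
        remaining.remove(cand)
        rows.append({"step": len(selected), "feature": cand, "cv_accuracy": acc})
        best_acc = acc
    return selected, pd.DataFrame(rows)
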