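"""Ensemble of L2-regularized logistic models over embedded connectivity.

Ten logistic regressions with ridge (L2) penalty strengths 1..10 are fit on
identical training data; a subject's score is the member average of
``2 * p_hat - 1``, a signed number in [-1, 1].  Scores above the 0 cutoff are
labelled positive (dopaminergic deficit predicted), at or below 0 negative.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

LAMBDAS = tuple(range(1, 11))
POSITIVE, NEGATIVE = "positive", "negative"


@dataclass
class PredictionScore:
    score: float
    label: str

    def __post_init__(self) -> None:
        if not -1.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [-1, 1]")


@dataclass
class EnsembleModel:
    """10 logistic members; member i has L2 strength lambda = i + 1."""

    coefs: np.ndarray           # (10, p)
    intercepts: np.ndarray      # (10,)
    lambdas: tuple = LAMBDAS
    pca_ref: str = ""

    def __post_init__(self) -> None:
        if len(self.lambdas) != 10 or tuple(self.lambdas) != LAMBDAS:
            raise ValueError("ensemble must have 10 members with lambda 1..10")

    def member_probabilities(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        if x.shape[1] != self.coefs.shape[1]:
            raise ValueError(
                f"input dimension {x.shape[1]} does not match model "
                f"({self.coefs.shape[1]})")
        logits = x @ self.coefs.T + self.intercepts
        return 1.0 / (1.0 + np.exp(-logits))       # (n, 10)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({"coefs": self.coefs.tolist(),
                           "intercepts": self.intercepts.tolist(),
                           "lambdas": list(self.lambdas),
                           "pca_ref": self.pca_ref}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EnsembleModel":
        text = Path(str(source)).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        return cls(coefs=np.array(d["coefs"]),
                   intercepts=np.array(d["intercepts"]),
                   lambdas=tuple(d["lambdas"]), pca_ref=d.get("pca_ref", ""))


def train_ensemble(X: np.ndarray, y: np.ndarray,
                   pca_ref: str = "") -> EnsembleModel:
    """Fit the 10-member ridge-logistic ensemble on identical data.

    ``y`` is binary with 1 = positive (dopaminergic deficit).  Member i uses
    penalty strength lambda = i (scikit-learn's C = 1/lambda); the lbfgs
    optimizer with a tight tolerance keeps fits deterministic and
    row-order-invariant.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.unique(y).size != 2:
        raise ValueError("training labels must contain both classes")
    if len(y) < 4:
        raise ValueError("need at least 4 training subjects")
    coefs, intercepts = [], []
    for lam in LAMBDAS:
        clf = LogisticRegression(C=1.0 / lam, solver="lbfgs",
                                 max_iter=5000, tol=1e-10)
        clf.fit(X, y)
        coefs.append(clf.coef_[0])
        intercepts.append(clf.intercept_[0])
    return EnsembleModel(coefs=np.array(coefs),
                         intercepts=np.array(intercepts), pca_ref=pca_ref)


def predict_score(model: EnsembleModel, x: np.ndarray) -> PredictionScore:
    """Signed ensemble score for one subject: mean over members of 2p - 1.

    A score of exactly 0 is labelled negative (only scores strictly above
    the cutoff are positive).
    """
    p = model.member_probabilities(x)
    if p.shape[0] != 1:
        raise ValueError("predict_score expects a single subject")
    score = float((2.0 * p - 1.0).mean())
    return PredictionScore(score=score,
                           label=POSITIVE if score > 0 else NEGATIVE)


def evaluate_cohort(model: EnsembleModel, X: np.ndarray, y_true: np.ndarray,
                    subject_ids: list[str] | None = None) -> dict:
    """Score every subject and tabulate confusion counts.

    Returns a dict with the per-subject table, confusion counts, sensitivity
    (recall on true positives) and specificity (recall on true negatives).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y_true = np.asarray(y_true).astype(int)
    if X.shape[0] == 0:
        raise ValueError("cohort is empty")
    if subject_ids is None:
        subject_ids = [f"s{i:03d}" for i in range(X.shape[0])]
    p = model.member_probabilities(X)
    scores = (2.0 * p - 1.0).mean(axis=1)
    pred = (scores > 0).astype(int)
    table = pd.DataFrame({
        "subject_id": subject_ids, "score": scores,
        "label": np.where(pred == 1, POSITIVE, NEGATIVE),
        "true_label": np.where(y_true == 1, POSITIVE, NEGATIVE)})
    tp = int(np.sum((pred == 1) & (y_true == 1)))
    tn = int(np.sum((pred == 0) & (y_true == 0)))
    fp = int(np.sum((pred == 1) & (y_true == 0)))
    fn = int(np.sum((pred == 0) & (y_true == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    return {"table": table, "tp": tp, "tn": tn, "fp": fp, "fn": fn,
            "sensitivity": sens, "specificity": spec,
            "balanced_accuracy": (sens + spec) / 2.0}
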