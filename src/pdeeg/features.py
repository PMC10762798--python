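"""LDA-derived scalar EEG features on BAF vectors, normalized to 0-100.

Two scalar features are built as analogues of the proprietary cognitive
biomarkers used with this recording system:

* an "A0-analogue", trained to separate any-cognitive-load windows from rest
  windows (pooled loads vs rest), tracking overall task engagement;
* an "L1-analogue", trained on the task-level contrast (high-load vs rest),
  tracking graded cognitive load.

Both are Fisher linear discriminants on per-second BAF vectors with
Ledoit-Wolf shrinkage of the pooled covariance (the atom count can exceed
the per-class window count), affinely normalized so that the 1st/99th
percentiles of the training projections map to 0 and 100, then clipped.
Training always uses a held-out calibration cohort, never the evaluation
subjects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.covariance import ledoit_wolf

from .decomposition import BAFMatrix
from .protocol import load_level


@dataclass
class LDAFeatureModel:
    """A linear discriminant feature with 0-100 normalization anchors."""

    weights: np.ndarray
    bias: float
    norm_lo: float
    norm_hi: float
    atom_ids: list[str]
    label_semantics: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if not self.norm_lo < self.norm_hi:
            raise ValueError("norm_lo must be < norm_hi")
        if len(self.weights) != len(self.atom_ids):
            raise ValueError("weights length must equal atom count")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "weights": self.weights.tolist(), "bias": self.bias,
            "norm_lo": self.norm_lo, "norm_hi": self.norm_hi,
            "atom_ids": self.atom_ids,
            "label_semantics": self.label_semantics}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "LDAFeatureModel":
        text = Path(str(source)).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        return cls(weights=np.array(d["weights"]), bias=d["bias"],
                   norm_lo=d["norm_lo"], norm_hi=d["norm_hi"],
                   atom_ids=d["atom_ids"],
                   label_semantics=d.get("label_semantics", ""))


def train_lda_feature(X: np.ndarray, y: np.ndarray,
                      atom_ids: list[str] | None = None,
                      label_semantics: str = "",
                      shrinkage: str = "ledoit-wolf",
                      anchor_X: np.ndarray | None = None) -> LDAFeatureModel:
    """Fit a two-class Fisher discriminant: w ~ (S_pooled + shrink)^-1 (m1 - m0).

    The projection direction is the classical LDA direction with the pooled
    within-class covariance regularized by Ledoit-Wolf shrinkage, which keeps
    the estimate well-conditioned when atoms outnumber windows.  Norm anchors
    are the 1st and 99th percentiles of the projections of ``anchor_X``
    (default: the training rows); passing a broader reference set keeps the
    0-100 scale from clipping populations the contrast was not trained on.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("exactly two classes required in y")
    X0, X1 = X[y == classes[0]], X[y == classes[1]]
    centered = np.vstack([X0 - X0.mean(axis=0), X1 - X1.mean(axis=0)])
    if shrinkage == "ledoit-wolf":
        cov, _ = ledoit_wolf(centered, assume_centered=True)
    else:
        cov = centered.T @ centered / len(centered)
        cov += 1e-6 * np.trace(cov) / cov.shape[0] * np.eye(cov.shape[0])
    w = np.linalg.solve(cov, X1.mean(axis=0) - X0.mean(axis=0))
    proj = (X if anchor_X is None else np.asarray(anchor_X, dtype=float)) @ w
    lo, hi = np.percentile(proj, [1.0, 99.0])
    if not lo < hi:
        raise ValueError("degenerate training projections (constant)")
    if atom_ids is None:
        atom_ids = [f"atom{i}" for i in range(X.shape[1])]
    return LDAFeatureModel(weights=w, bias=0.0, norm_lo=float(lo),
                           norm_hi=float(hi), atom_ids=list(atom_ids),
                           label_semantics=label_semantics)


@dataclass
class FeatureSeries:
    """A per-second scalar feature in [0, 100]."""

    values: np.ndarray
    feature_name: str

    def to_frame(self, labels: list[str] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({"time_s": np.arange(len(self.values), dtype=float),
                           "value": self.values})
        if labels is not None:
            df["condition"] = list(labels)[:len(df)]
        return df


def project_feature(model: LDAFeatureModel, baf: BAFMatrix,
                    feature_name: str = "feature") -> FeatureSeries:
    """Project BAF rows onto the discriminant and map anchors to [0, 100]."""
    missing = [a for a in model.atom_ids if a not in baf.atom_ids]
    if missing:
        raise ValueError(f"BAF matrix is missing model atoms: {missing}")
    order = [baf.atom_ids.index(a) for a in model.atom_ids]
    proj = baf.values[:, order] @ model.weights + model.bias
    scaled = (proj - model.norm_lo) / (model.norm_hi - model.norm_lo) * 100.0
    return FeatureSeries(values=np.clip(scaled, 0.0, 100.0),
                         feature_name=feature_name)


def condition_means(series: FeatureSeries, labels: list[str]) -> pd.DataFrame:
    """Mean feature value per condition and per ordinal load level.

    The per-second series and the label timeline may differ by up to the
    analysis-window overhang (the final windows have no label of their own);
    longer mismatches are rejected.
    """
    n_s, n_l = len(series.values), len(labels)
    if abs(n_s - n_l) > 4:  # window length minus hop, in seconds
        raise ValueError(
            f"series length {n_s} and label length {n_l} differ by more than "
            "the window-trim tolerance")
    n = min(n_s, n_l)
    df = pd.DataFrame({"value": series.values[:n], "condition": labels[:n]})
    df["load"] = df["condition"].map(load_level)
    out = (df.groupby("condition", sort=True)["value"]
             .agg(["mean", "count"]).reset_index())
    out["load"] = out["condition"].map(load_level)
    return out


def load_means(series: FeatureSeries, labels: list[str]) -> pd.DataFrame:
    """Mean feature value per ordinal load level (0, 1, 2)."""
    cm = condition_means(series, labels)
    cm["wsum"] = cm["mean"] * cm["count"]
    g = cm.groupby("load")[["wsum", "count"]].sum()
    g["mean"] = g["wsum"] / g["count"]
    return g[["mean", "count"]].reset_index()
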