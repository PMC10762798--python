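"""Functional connectivity among BAF time courses, vectorized and PCA-embedded.

The predictor's raw representation for one subject is the Pearson correlation
matrix between all pairs of BAF time courses over the recording — the
single-channel analogue of region-by-region fMRI functional connectivity —
Fisher z-transformed and flattened to its upper triangle.  A PCA fitted on
the training subjects' vectors embeds each subject into a low-dimensional
coordinate space for the classifier.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .decomposition import BAFMatrix

MIN_ROWS = 8
_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    values: np.ndarray          # (K, K) correlations
    atom_ids: list[str]
    zero_variance_atoms: list[str]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.atom_ids,
                            columns=self.atom_ids)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)


def connectivity(baf: BAFMatrix) -> ConnectivityMatrix:
    """Pearson correlation across time between every pair of atoms.

    Zero-variance atom columns (e.g. an always-silent band) cannot carry a
    correlation; they are flagged and given 0 off-diagonal entries.
    """
    V = np.asarray(baf.values, dtype=float)
    if V.shape[0] < MIN_ROWS:
        raise ValueError(
            f"need at least {MIN_ROWS} time points for a stable correlation "
            f"estimate, got {V.shape[0]}")
    sd = V.std(axis=0)
    # constant columns up to floating error count as zero-variance
    flat = sd <= 1e-12 * np.maximum(1.0, np.abs(V).max(axis=0))
    C = np.eye(V.shape[1])
    ok = ~flat
    if ok.sum() >= 2:
        sub = np.corrcoef(V[:, ok], rowvar=False)
        C[np.ix_(ok, ok)] = sub
    np.fill_diagonal(C, 1.0)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    return ConnectivityMatrix(
        values=C, atom_ids=list(baf.atom_ids),
        zero_variance_atoms=[a for a, f in zip(baf.atom_ids, flat) if f])


def connectivity_vector(conn: ConnectivityMatrix) -> np.ndarray:
    """Fisher-z upper triangle of the correlation matrix, length K(K-1)/2."""
    K = conn.values.shape[0]
    iu = np.triu_indices(K, k=1)
    r = np.clip(conn.values[iu], -_CLIP, _CLIP)
    return np.arctanh(r)


@dataclass
class PCAModel:
    """Centered SVD embedding with a deterministic sign convention."""

    mean_vector: np.ndarray
    component_loadings: np.ndarray      # (k, p), orthonormal rows
    explained_variance_ratios: np.ndarray
    k: int

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "mean": self.mean_vector.tolist(),
            "loadings": self.component_loadings.tolist(),
            "ratios": self.explained_variance_ratios.tolist(),
            "k": self.k}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PCAModel":
        text = Path(str(source)).read_text() if Path(str(source)).exists() \
            else str(source)
        d = json.loads(text)
        return cls(mean_vector=np.array(d["mean"]),
                   component_loadings=np.array(d["loadings"]),
                   explained_variance_ratios=np.array(d["ratios"]), k=d["k"])


def fit_pca(train_vectors: np.ndarray | list[np.ndarray], k: int) -> PCAModel:
    """Centered SVD; rows of ``train_vectors`` are subjects.

    The sign of each loading is fixed so its largest-magnitude entry is
    positive, making the embedding deterministic across runs and platforms.
    """
    X = np.asarray(train_vectors, dtype=float)
    n, p = X.shape
    if not 1 <= k <= min(n, p):
        raise ValueError(f"k={k} out of range for {n} vectors of length {p}")
    mean = X.mean(axis=0)
    Xc = X - mean
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    load = Vt[:k]
    for i in range(k):
        j = int(np.argmax(np.abs(load[i])))
        if load[i, j] < 0:
            load[i] = -load[i]
    var = S ** 2
    ratios = (var / var.sum())[:k] if var.sum() > 0 else np.zeros(k)
    return PCAModel(mean_vector=mean, component_loadings=load,
                    explained_variance_ratios=ratios, k=k)


def embed(model: PCAModel, v: np.ndarray) -> np.ndarray:
    """Project one connectivity vector (or a stack) into PCA coordinates."""
    v = np.asarray(v, dtype=float)
    if v.shape[-1] != model.mean_vector.shape[0]:
        raise ValueError(
            f"vector length {v.shape[-1]} does not match model "
            f"({model.mean_vector.shape[0]})")
    return (v - model.mean_vector) @ model.component_loadings.T
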