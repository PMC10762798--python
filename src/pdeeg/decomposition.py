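"""Wavelet-packet best-basis decomposition and windowed FFT band powers.

A recording is analysed in 2,048-sample windows (500 Hz, ~4 s) advanced by
1 s.  Each window is expanded into a full wavelet-packet tree (orthogonal
filters, periodized boundary handling, so energy is conserved exactly at
every level).  A best basis — the disjoint node cover of the tree minimizing
an additive Shannon-entropy cost over a training corpus of windows — defines
the set of atoms; the per-window log energy of each atom forms one "brain
activity feature" (BAF) time course at a 1 s step.  Windowed periodograms of
the same windows give conventional band powers in dB(uV^2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import pywt

from .synth import BANDS

WINDOW_SAMPLES = 2048
HOP_SAMPLES = 500
DEFAULT_WAVELET = "db4"
DEFAULT_DEPTH = 7
LOG_EPS = 1e-12
_MODE = "periodization"  # orthogonal => exact Parseval at every level


def sliding_windows(samples: np.ndarray, window: int = WINDOW_SAMPLES,
                    hop: int = HOP_SAMPLES) -> np.ndarray:
    """(n_windows, window) view of ``samples`` advanced by ``hop``."""
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 1:
        raise ValueError("expected a 1-D sample array")
    if samples.size < window:
        raise ValueError(
            f"recording has {samples.size} samples; need at least {window}")
    n = (samples.size - window) // hop + 1
    view = np.lib.stride_tricks.sliding_window_view(samples, window)[::hop]
    return view[:n]


def wpt_coefficients(window: np.ndarray, wavelet: str = DEFAULT_WAVELET,
                     depth: int = DEFAULT_DEPTH) -> list[np.ndarray]:
    """Full wavelet-packet coefficient tree of one 2,048-sample window.

    Returns a list indexed by level; level ``l`` is an array of shape
    ``(2**l, 2048 / 2**l)`` whose rows are the node coefficient vectors in
    natural (Paley) order.  Level 0 is the window itself.
    """
    window = np.asarray(window, dtype=float)
    if window.ndim == 1:
        window = window[None, :]
        squeeze = True
    else:
        squeeze = False
    if window.shape[-1] != WINDOW_SAMPLES:
        raise ValueError(
            f"analysis windows must have exactly {WINDOW_SAMPLES} samples, "
            f"got {window.shape[-1]}")
    if depth > 11:
        raise ValueError("depth must be <= 11 for 2,048-sample windows")
    tree = _full_tree(window, wavelet, depth)
    if squeeze:
        tree = [lvl[:, 0, :] for lvl in tree]
    return tree


def _full_tree(windows: np.ndarray, wavelet: str, depth: int) -> list[np.ndarray]:
    """Batched full WPT: level l -> array (2**l, n_windows, len/2**l)."""
    levels = [np.ascontiguousarray(windows)[None, :, :]]
    for _ in range(depth):
        a, d = pywt.dwt(levels[-1], wavelet, mode=_MODE, axis=-1)
        # interleave (approx, detail) per parent -> natural (Paley) order
        levels.append(np.stack([a, d], axis=1)
                      .reshape(-1, a.shape[-2], a.shape[-1]))
    return levels


@dataclass
class BestBasis:
    """An orthogonal wavelet-packet basis: a disjoint exact cover of the tree."""

    atoms: list[tuple[int, int]]        # (depth, node_index), natural order
    wavelet_name: str
    max_depth: int
    cost_name: str = "shannon"

    @property
    def atom_ids(self) -> list[str]:
        return [f"L{d}N{i}" for d, i in self.atoms]

    def validate_cover(self) -> None:
        """Check the atoms tile the full-depth leaves exactly once."""
        covered = np.zeros(2 ** self.max_depth, dtype=int)
        for d, i in self.atoms:
            span = 2 ** (self.max_depth - d)
            covered[i * span:(i + 1) * span] += 1
        if not np.all(covered == 1):
            raise ValueError("atoms do not form a disjoint exact cover")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps({
            "wavelet": self.wavelet_name, "max_depth": self.max_depth,
            "cost": self.cost_name, "atoms": self.atoms}, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BestBasis":
        text = Path(source).read_text() if Path(str(source)).exists() else str(source)
        d = json.loads(text)
        return cls(atoms=[tuple(a) for a in d["atoms"]],
                   wavelet_name=d["wavelet"], max_depth=d["max_depth"],
                   cost_name=d["cost"])


def _shannon_cost(coeffs: np.ndarray, window_energy: np.ndarray) -> float:
    """Additive Shannon entropy cost of one node, summed over the corpus.

    p_i = c_i^2 / E_window; cost = sum_windows sum_i -p_i log p_i restricted
    to this node's coefficients.  Additivity over a disjoint cover holds
    because the normalizer is the whole-window energy.
    """
    p = coeffs ** 2 / window_energy[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(p > 0, -p * np.log(p), 0.0)
    return float(terms.sum())


def node_costs(windows: np.ndarray, wavelet: str = DEFAULT_WAVELET,
               depth: int = DEFAULT_DEPTH) -> list[np.ndarray]:
    """Per-node corpus cost table: level l -> array of 2**l costs."""
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    tree = _full_tree(windows, wavelet, depth)
    energy = (windows ** 2).sum(axis=1)
    energy = np.where(energy > 0, energy, 1.0)
    costs = []
    for lvl in tree:
        costs.append(np.array([_shannon_cost(node, energy) for node in lvl]))
    return costs


def select_best_basis(windows: np.ndarray, wavelet: str = DEFAULT_WAVELET,
                      depth: int = DEFAULT_DEPTH,
                      cost: str = "shannon") -> BestBasis:
    """Bottom-up dynamic-programming best-basis selection.

    For every tree node, keep the node itself if its cost is at most the sum
    of its children's best costs, else keep the children's best covers.  The
    result is the disjoint cover of the full tree minimizing the summed
    additive cost over the corpus.
    """
    windows = np.atleast_2d(np.asarray(windows, dtype=float))
    if windows.size == 0:
        raise ValueError("corpus of windows is empty")
    if cost != "shannon":
        raise ValueError(f"unknown cost {cost!r}")
    table = node_costs(windows, wavelet, depth)

    best_cost = [lvl.copy() for lvl in table]
    keep_node = [np.ones_like(lvl, dtype=bool) for lvl in table]
    for level in range(depth - 1, -1, -1):
        child_sum = best_cost[level + 1][0::2] + best_cost[level + 1][1::2]
        keep = table[level] <= child_sum
        keep_node[level] = keep
        best_cost[level] = np.where(keep, table[level], child_sum)

    atoms: list[tuple[int, int]] = []

    def collect(level: int, index: int) -> None:
        if level == depth or keep_node[level][index]:
            atoms.append((level, index))
        else:
            collect(level + 1, 2 * index)
            collect(level + 1, 2 * index + 1)

    collect(0, 0)
    basis = BestBasis(atoms=atoms, wavelet_name=wavelet, max_depth=depth,
                      cost_name=cost)
    basis.validate_cover()
    return basis


def basis_cost(windows: np.ndarray, basis: BestBasis,
               wavelet: str | None = None) -> float:
    """Summed corpus cost of an arbitrary basis (for optimality checks)."""
    table = node_costs(windows, wavelet or basis.wavelet_name, basis.max_depth)
    return float(sum(table[d][i] for d, i in basis.atoms))


def uniform_basis(depth: int, level: int,
                  wavelet: str = DEFAULT_WAVELET) -> BestBasis:
    """The uniform cover at a single level (all 2**level nodes)."""
    return BestBasis(atoms=[(level, i) for i in range(2 ** level)],
                     wavelet_name=wavelet, max_depth=depth)


@dataclass
class BAFMatrix:
    """Per-second x per-atom log-energy time courses."""

    values: np.ndarray           # (n_windows, n_atoms), log10 energies
    atom_ids: list[str]
    window_hop_s: float = 1.0

    @property
    def n_windows(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.atom_ids)
        df.insert(0, "time_s", np.arange(self.n_windows) * self.window_hop_s)
        return df

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BAFMatrix":
        df = pd.read_csv(path)
        atoms = [c for c in df.columns if c != "time_s"]
        return cls(values=df[atoms].to_numpy(), atom_ids=atoms)


def baf_timecourses(samples: np.ndarray, basis: BestBasis,
                    eps: float = LOG_EPS) -> BAFMatrix:
    """Log10 atom energies for every 2,048-sample window advanced by 1 s."""
    windows = sliding_windows(samples)
    tree = _full_tree(windows, basis.wavelet_name, basis.max_depth)
    cols = []
    for d, i in basis.atoms:
        node = tree[d][i]                    # (n_windows, len)
        cols.append(np.log10(eps + (node ** 2).sum(axis=1)))
    values = np.column_stack(cols)
    return BAFMatrix(values=values, atom_ids=[f"L{d}N{i}" for d, i in basis.atoms])


def band_powers(samples: np.ndarray, fs: int = 500,
                bands: dict[str, tuple[float, float]] = BANDS) -> pd.DataFrame:
    """Windowed periodogram band powers in dB(uV^2), one row per second.

    Band power is the mean periodogram power over the band's frequency bins
    (rectangular window, matching the raw FFT description of the pipeline),
    reported as 10*log10.
    """
    windows = sliding_windows(samples)
    freqs = np.fft.rfftfreq(WINDOW_SAMPLES, 1.0 / fs)
    spec = np.fft.rfft(windows, axis=1)
    # one-sided periodogram, uV^2 per bin
    power = (np.abs(spec) ** 2) / WINDOW_SAMPLES ** 2
    power[:, 1:-1] *= 2.0
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (freqs >= lo) & (freqs <= hi)
        out[name] = 10.0 * np.log10(LOG_EPS + power[:, sel].mean(axis=1))
    df = pd.DataFrame(out)
    df.insert(0, "time_s", np.arange(len(df), dtype=float))
    return df
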