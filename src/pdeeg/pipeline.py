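"""End-to-end orchestration: simulate, decompose, embed, predict, test.

``reproduce`` runs the whole analysis in memory and returns the stage
outputs; ``run_reproduction`` additionally writes every table to disk and
returns a manifest with content hashes, so a run is reproducible from its
config alone.  The numbered driver scripts under ``analysis/`` are thin
wrappers over the functions here.
"""

from __future__ import annotations

import hashlib
import json
import time
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import decomposition as dec
from .connectivity import PCAModel, connectivity, connectivity_vector, embed, fit_pca
from .features import LDAFeatureModel, project_feature, train_lda_feature
from .io_edf import read_edf, read_labels, read_recording_csv
from .predictor import evaluate_cohort, train_ensemble
from .protocol import (ProtocolSchedule, build_compact_protocol,
                       build_default_protocol, load_level)
from .stats import bayes_mannwhitney, fit_lmm, posthoc_pairwise, welch_t
from .synth import GeneratorConfig, generate_cohort

EEG_VARIABLES = ("delta", "theta", "A0", "L1")


@dataclass
class RunConfig:
    """All knobs of one reproduction run; JSON round-trips losslessly."""

    seed: int = 0
    n_per_group: int = 26
    n_calibration_per_group: int = 10
    protocol: str = "default"          # "default" | "compact"
    wavelet: str = dec.DEFAULT_WAVELET
    depth: int = dec.DEFAULT_DEPTH
    basis_window_subsample: int = 10   # every k-th window feeds basis selection
    pca_k: int = 10
    prior_scale: float = float(1.0 / np.sqrt(2.0))
    chains: int = 5
    iterations: int = 1000
    generator: dict = field(default_factory=dict)  # GeneratorConfig overrides

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(asdict(self), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "RunConfig":
        text = Path(str(source)).read_text() if Path(str(source)).exists() \
            else str(source)
        return cls(**json.loads(text))

    def schedule(self) -> ProtocolSchedule:
        builder = {"default": build_default_protocol,
                   "compact": build_compact_protocol}.get(self.protocol)
        if builder is None:
            raise ValueError(f"unknown protocol {self.protocol!r}")
        return builder(self.seed)

    def generator_config(self, seed_offset: int = 0) -> GeneratorConfig:
        return GeneratorConfig(seed=(self.seed + seed_offset) & 0x7FFFFFFF,
                               **self.generator)


def decompose_subject(recording, basis) -> tuple[dec.BAFMatrix, pd.DataFrame]:
    """BAF time courses and band powers for one recording."""
    baf = dec.baf_timecourses(recording.samples, basis)
    bands = dec.band_powers(recording.samples, fs=recording.fs)
    return baf, bands


def train_feature_models(bafs, labels_list,
                         anchor_bafs=None) -> dict[str, LDAFeatureModel]:
    """Fit the two scalar feature analogues on pooled calibration windows.

    A0-analogue: any cognitive load (levels 1 and 2) vs rest.
    L1-analogue: high load (level 2) vs rest.

    Callers pass windows from healthy calibration subjects only, mirroring
    the provenance of the original features (trained on prior task corpora
    of unimpaired participants); training on a mixed cohort would let
    group-specific resting differences leak into the load contrast.  The
    0-100 anchors may instead come from the whole calibration cohort
    (``anchor_bafs``) so projections of other populations are not clipped.
    """
    rows, loads = [], []
    for baf, labels in zip(bafs, labels_list):
        n = min(baf.n_windows, len(labels))
        rows.append(baf.values[:n])
        loads.append(np.array([load_level(c) for c in labels[:n]]))
    X = np.vstack(rows)
    load = np.concatenate(loads)
    atom_ids = bafs[0].atom_ids
    anchor_X = None
    if anchor_bafs is not None:
        anchor_X = np.vstack([b.values for b in anchor_bafs])

    models = {}
    sel = load != 1
    models["A0"] = train_lda_feature(X, (load > 0).astype(int), atom_ids,
                                     label_semantics="cognitive load vs rest",
                                     anchor_X=anchor_X)
    models["L1"] = train_lda_feature(X[sel], (load[sel] == 2).astype(int),
                                     atom_ids,
                                     label_semantics="high load vs rest",
                                     anchor_X=anchor_X)
    return models


def subject_variables(baf, bands, models) -> pd.DataFrame:
    """Per-second table of the four EEG variables for one subject."""
    n = min(baf.n_windows, len(bands))
    out = pd.DataFrame({
        "time_s": np.arange(n, dtype=float),
        "delta": bands["delta"].to_numpy()[:n],
        "theta": bands["theta"].to_numpy()[:n],
    })
    for name in ("A0", "L1"):
        series = project_feature(models[name], baf, feature_name=name)
        out[name] = series.values[:n]
    return out


def long_table(recordings, bafs, bands_list, models) -> pd.DataFrame:
    """Stacked per-second observations: subject, group, condition, load, vars."""
    frames = []
    for rec, baf, bands in zip(recordings, bafs, bands_list):
        sv = subject_variables(baf, bands, models)
        n = min(len(sv), len(rec.labels))
        sv = sv.iloc[:n].copy()
        sv["condition"] = rec.labels[:n]
        sv["load"] = sv["condition"].map(load_level).astype(float)
        sv["subject"] = rec.subject_id
        sv["group"] = 1.0 if rec.group == "healthy" else 0.0
        frames.append(sv)
    return pd.concat(frames, ignore_index=True)


def subject_load_means(long: pd.DataFrame, var: str) -> pd.DataFrame:
    """One row per subject per load level: the post-hoc input."""
    g = (long.groupby(["subject", "group", "load"])[var]
         .mean().reset_index().rename(columns={var: "value"}))
    return g


def embed_cohort(bafs, pca: PCAModel | None = None, k: int = 10
                 ) -> tuple[np.ndarray, PCAModel]:
    """Connectivity vectors -> (optionally fit) PCA -> embedded coordinates."""
    vectors = np.array([connectivity_vector(connectivity(b)) for b in bafs])
    if pca is None:
        k_eff = min(k, len(vectors) - 1, vectors.shape[1])
        pca = fit_pca(vectors, k_eff)
    return embed(pca, vectors), pca


def reproduce(config: RunConfig) -> dict:
    """Run the full analysis in memory; returns a dict of stage outputs.

    A failure in any stage is re-raised as a RuntimeError naming the stage
    and the config hash, so aborted runs are attributable.
    """
    t0 = time.time()
    config_hash = hashlib.sha256(config.to_json().encode()).hexdigest()[:12]

    @contextmanager
    def stage(name):
        try:
            yield
        except Exception as exc:
            raise RuntimeError(
                f"stage {name!r} failed for config {config_hash}: {exc}"
            ) from exc

    with stage("protocol"):
        schedule = config.schedule()

    with stage("simulate"):
        calib_recs, calib_meta = generate_cohort(
            config.n_calibration_per_group, schedule,
            config.generator_config(seed_offset=1_000_003))
        eval_recs, eval_meta = generate_cohort(
            config.n_per_group, schedule, config.generator_config())

    with stage("decompose"):
        # basis from calibration windows only
        calib_windows = np.vstack([
            dec.sliding_windows(r.samples)[::config.basis_window_subsample]
            for r in calib_recs])
        basis = dec.select_best_basis(calib_windows, wavelet=config.wavelet,
                                      depth=config.depth)
        calib_pairs = [decompose_subject(r, basis) for r in calib_recs]
        eval_pairs = [decompose_subject(r, basis) for r in eval_recs]
        calib_bafs = [p[0] for p in calib_pairs]
        eval_bafs = [p[0] for p in eval_pairs]

    with stage("features"):
        healthy_idx = [i for i, r in enumerate(calib_recs)
                       if r.group == "healthy"]
        models = train_feature_models(
            [calib_bafs[i] for i in healthy_idx],
            [calib_recs[i].labels for i in healthy_idx],
            anchor_bafs=calib_bafs)

    with stage("predict"):
        # train on calibration, score evaluation subjects
        calib_X, pca = embed_cohort(calib_bafs, k=config.pca_k)
        calib_y = np.array([1 if r.group == "PD" else 0 for r in calib_recs])
        ensemble = train_ensemble(calib_X, calib_y, pca_ref="calibration-pca")
        eval_X, _ = embed_cohort(eval_bafs, pca=pca)
        eval_y = np.array([1 if r.group == "PD" else 0 for r in eval_recs])
        evaluation = evaluate_cohort(ensemble, eval_X, eval_y,
                                     [r.subject_id for r in eval_recs])

    with stage("stats"):
        long = long_table(eval_recs, eval_bafs, [p[1] for p in eval_pairs],
                          models)
        healthy_ids = sorted(long.loc[long.group == 1.0, "subject"].unique())
        half = len(healthy_ids) // 2
        sub_a, sub_b = healthy_ids[:half], healthy_ids[half:]

        welch_validation, lmm_tables, posthoc_tables = {}, {}, {}
        subj_means = long.groupby(["subject", "group"])[
            list(EEG_VARIABLES)].mean().reset_index()
        for var in EEG_VARIABLES:
            if half >= 2:  # half-split validation needs >= 2 subjects a side
                a = subj_means.loc[subj_means.subject.isin(sub_a), var]
                b = subj_means.loc[subj_means.subject.isin(sub_b), var]
                welch_validation[var] = welch_t(a, b)
            lmm_tables[var] = fit_lmm(long, value_col=var)
        posthoc_tables["L1"] = posthoc_pairwise(
            subject_load_means(long, "L1"))

        scores = evaluation["table"]
        bayes = bayes_mannwhitney(
            scores.loc[scores.true_label == "negative", "score"],
            scores.loc[scores.true_label == "positive", "score"],
            chains=config.chains, iters=config.iterations,
            prior_scale=config.prior_scale, seed=config.seed)

    return {
        "schedule": schedule, "basis": basis, "feature_models": models,
        "pca": pca, "ensemble": ensemble, "evaluation": evaluation,
        "welch_validation": welch_validation, "lmm_tables": lmm_tables,
        "posthoc_tables": posthoc_tables, "bayes_scores": bayes,
        "long_table": long, "calib_meta": calib_meta, "eval_meta": eval_meta,
        "wall_clock_s": time.time() - t0,
    }


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_reproduction(config: RunConfig, out_dir: str | Path) -> dict:
    """Run :func:`reproduce` and write every output table with a manifest.

    Returns the in-memory results dict augmented with ``manifest``: a mapping
    file name -> sha256 of content.  Identical configs produce identical
    manifests (wall clock excluded).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res = reproduce(config)

    config.to_json(out / "config.json")
    res["schedule"].to_csv(out / "schedule.csv")
    res["basis"].to_json(out / "basis.json")
    for name, model in res["feature_models"].items():
        model.to_json(out / f"feature_{name}.json")
    res["pca"].to_json(out / "pca.json")
    res["ensemble"].to_json(out / "ensemble.json")
    res["evaluation"]["table"].to_csv(out / "predictions.csv", index=False)

    lmm_rows = []
    for var, lmm in res["lmm_tables"].items():
        t = lmm.fixed_effects.reset_index(names="fixed_effect")
        t.insert(0, "variable", var)
        lmm_rows.append(t)
    pd.concat(lmm_rows, ignore_index=True).to_csv(
        out / "lmm_fixed_effects.csv", index=False)
    res["posthoc_tables"]["L1"].to_csv(out / "posthoc_L1.csv", index=False)

    welch_df = pd.DataFrame(
        [(v, r.t, r.df, r.p) for v, r in res["welch_validation"].items()],
        columns=["variable", "t", "df", "p"])
    welch_df.to_csv(out / "welch_validation.csv", index=False)

    b = res["bayes_scores"]
    (out / "bayes_scores.json").write_text(json.dumps({
        "BF10": b.BF10, "BF01": b.BF01, "W": b.W,
        "rank_biserial": b.rank_biserial, "rhat": b.rhat,
        "chains": b.chains, "iterations_per_chain": b.iterations_per_chain,
        "prior_scale": b.prior_scale}, indent=1))

    manifest = {p.name: _sha256(p) for p in sorted(out.iterdir())
                if p.is_file()}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    res["manifest"] = manifest
    return res


def read_recording(path: str | Path, fmt: str = "EDF",
                   labels_path: str | Path | None = None
                   ) -> tuple[np.ndarray, int, list[str] | None]:
    """Read a recording (EDF or CSV) plus its optional labels sidecar."""
    fmt = fmt.upper()
    if fmt == "EDF":
        samples, fs = read_edf(path)
    elif fmt == "CSV":
        samples, fs = read_recording_csv(path)
    else:
        raise ValueError(f"unknown format {fmt!r}; expected EDF or CSV")
    labels = read_labels(labels_path) if labels_path is not None else None
    return samples, fs, labels


def balanced_accuracy_sweep(n_cohorts: int = 20, n_per_group: int = 26,
                            seed: int = 0, depth: int = 6,
                            protocol: str = "compact",
                            pca_k: int = 10) -> list[float]:
    """Held-out balanced accuracy of the ensemble over repeated cohorts.

    Each cohort is split 50/50 per group into train and test halves; the
    basis, PCA and ensemble are fit on the train half only.
    """
    cfg0 = RunConfig(seed=seed, protocol=protocol, depth=depth, pca_k=pca_k)
    schedule = cfg0.schedule()
    accs = []
    for c in range(n_cohorts):
        gen = GeneratorConfig(seed=(seed + 7919 * (c + 1)) & 0x7FFFFFFF)
        recs, _ = generate_cohort(n_per_group, schedule, gen)
        by_group = {"PD": [r for r in recs if r.group == "PD"],
                    "healthy": [r for r in recs if r.group == "healthy"]}
        half = n_per_group // 2
        train = by_group["PD"][:half] + by_group["healthy"][:half]
        test = by_group["PD"][half:] + by_group["healthy"][half:]

        train_windows = np.vstack([dec.sliding_windows(r.samples)[::10]
                                   for r in train])
        basis = dec.select_best_basis(train_windows, depth=depth)
        train_bafs = [dec.baf_timecourses(r.samples, basis) for r in train]
        test_bafs = [dec.baf_timecourses(r.samples, basis) for r in test]

        Xtr, pca = embed_cohort(train_bafs, k=pca_k)
        ytr = np.array([1 if r.group == "PD" else 0 for r in train])
        model = train_ensemble(Xtr, ytr)
        Xte, _ = embed_cohort(test_bafs, pca=pca)
        yte = np.array([1 if r.group == "PD" else 0 for r in test])
        accs.append(evaluate_cohort(model, Xte, yte)["balanced_accuracy"])
    return accs
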