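"""Simulation studies validating the statistical stage and the full pipeline.

These are the package's own calibration experiments: type-I error and CI
coverage of the mixed model, null and separation behaviour of the Bayesian
rank test, held-out classification accuracy over repeated cohorts, and the
qualitative group/load pattern of a full analysis run.  They are used both
by the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pipeline import RunConfig, balanced_accuracy_sweep, reproduce
from .stats import bayes_mannwhitney, fit_lmm

Z_CRIT = 1.96


def simulate_lmm_table(seed: int, beta_group: float = 0.0, n_subj: int = 30,
                       n_obs: int = 34, re_sd: tuple = (1.0, 0.3),
                       noise: float = 2.0) -> pd.DataFrame:
    """Long table from the mixed model's own generative process."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subj):
        group = float(s < n_subj // 2)
        u = rng.normal(0.0, re_sd[0])
        v = rng.normal(0.0, re_sd[1])
        load = rng.integers(0, 3, size=n_obs).astype(float)
        y = (1.0 + beta_group * group + 0.5 * load + u + v * load
             + rng.normal(0.0, noise, size=n_obs))
        rows.extend((f"s{s}", group, li, yi) for li, yi in zip(load, y))
    return pd.DataFrame(rows, columns=["subject", "group", "load", "value"])


def lmm_calibration(n_sims: int = 50, seed: int = 0,
                    beta: float = 1.0) -> dict:
    """Type-I rate (null group effect) and 95% CI coverage (known effect).

    Each replicate is a 30-subject, ~1,000-observation dataset drawn from
    the model's own process (random intercept + load slope per subject);
    30 clusters keep the Wald z approximation for the between-subject group
    effect close to its nominal size.
    """
    rejections = 0
    covered = 0
    for i in range(n_sims):
        null = fit_lmm(simulate_lmm_table(seed * 100_003 + i, beta_group=0.0))
        rejections += abs(null.effect("group").z) >= Z_CRIT
        eff = fit_lmm(simulate_lmm_table(seed * 100_003 + 50_000 + i,
                                         beta_group=beta))
        g = eff.effect("group")
        covered += g.ci_low <= beta <= g.ci_high
    return {"type1_rate": rejections / n_sims,
            "coverage": covered / n_sims, "n_sims": n_sims}


def bayes_null_calibration(n_runs: int = 20, n: int = 25,
                           seed: int = 0) -> dict:
    """Fraction of same-distribution draws favouring the null (BF01 > 1)."""
    rng = np.random.default_rng(seed)
    favour_null = 0
    for i in range(n_runs):
        x = rng.normal(0.0, 1.0, n)
        y = rng.normal(0.0, 1.0, n)
        res = bayes_mannwhitney(x, y, seed=seed * 7 + i)
        favour_null += res.BF01 > 1.0
    return {"null_bf01_gt1_fraction": favour_null / n_runs, "n_runs": n_runs}


def bayes_separation(n: int = 25, seed: int = 0, shift: float = 2.0) -> dict:
    """BF10 for two groups separated by ``shift`` pooled SDs."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, 1.0, n)
    y = rng.normal(shift, 1.0, n)
    res = bayes_mannwhitney(x, y, seed=seed + 1)
    return {"bf10": res.BF10, "W": res.W, "rhat": res.rhat, "n": n}


def pattern_run(seed: int = 11, n_per_group: int = 26,
                n_calibration_per_group: int = 10, depth: int = 6,
                protocol: str = "compact") -> dict:
    """One full analysis on a default synthetic cohort; key pattern numbers.

    Returns the group-effect p-values for Delta and the A0-analogue, the
    load-effect p-value for the L1-analogue, the BH-adjusted high-vs-rest
    post-hoc p per group, and the evaluation-cohort classification metrics.
    """
    cfg = RunConfig(seed=seed, n_per_group=n_per_group,
                    n_calibration_per_group=n_calibration_per_group,
                    depth=depth, protocol=protocol)
    res = reproduce(cfg)
    lmm = res["lmm_tables"]
    ph = res["posthoc_tables"]["L1"]

    def adj(group, comparison):
        row = ph[(ph.group == group) & (ph.comparison == comparison)]
        return float(row["p adj BH"].iloc[0])

    ev = res["evaluation"]
    return {
        "delta_group_p": float(lmm["delta"].effect("group").p),
        "delta_group_coef": float(lmm["delta"].effect("group").coef),
        "a0_group_p": float(lmm["A0"].effect("group").p),
        "a0_group_coef": float(lmm["A0"].effect("group").coef),
        "theta_group_p": float(lmm["theta"].effect("group").p),
        "l1_load_p": float(lmm["L1"].effect("load").p),
        "healthy_high_vs_rest_adj_p": adj(1.0, "(high, low)"),
        "pd_high_vs_rest_adj_p": adj(0.0, "(high, low)"),
        "balanced_accuracy": float(ev["balanced_accuracy"]),
        "sensitivity": float(ev["sensitivity"]),
        "specificity": float(ev["specificity"]),
        "score_bf10": float(res["bayes_scores"].BF10),
        "n_per_group": n_per_group,
    }


def ensemble_accuracy_study(n_cohorts: int = 20, seed: int = 0,
                            n_per_group: int = 26) -> dict:
    """Held-out balanced accuracy over repeated 50/50-split cohorts."""
    accs = balanced_accuracy_sweep(n_cohorts=n_cohorts,
                                   n_per_group=n_per_group, seed=seed)
    return {"mean_balanced_accuracy": float(np.mean(accs)),
            "min_balanced_accuracy": float(np.min(accs)),
            "accuracies": [float(a) for a in accs],
            "n_cohorts": n_cohorts}
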