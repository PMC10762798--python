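"""Published demographic tables of the study cohort, as input data.

The study's demographic tables report subgroup sizes, means and SDs; the
whole-group values they print alongside are weighted poolings of those
subgroups.  This module stores the printed subgroup statistics and provides
the pooling arithmetic, so the whole-group numbers can be recomputed and
checked rather than copied.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# Second-analysis groups, by gender (n, mean age, mean MMSE).
GROUP_DEMOGRAPHICS = pd.DataFrame(
    [
        ("PD", "male", 15, 63.46, 29.66),
        ("PD", "female", 11, 65.09, 29.54),
        ("healthy", "male", 15, 67.13, 29.06),
        ("healthy", "female", 11, 64.90, 29.09),
    ],
    columns=["group", "gender", "n", "age_mean", "mmse_mean"],
)

# First-analysis clinical table (n and mean years between the F-DOPA test
# and the auditory assessment, per F-DOPA result and gender).
FDOPA_CLINICAL = pd.DataFrame(
    [
        ("negative", "female", 4, 0.49),
        ("negative", "male", 2, 0.50),
        ("positive", "female", 11, 1.91),
        ("positive", "male", 15, 1.14),
    ],
    columns=["fdopa", "gender", "n", "fdopa_auditory_gap_years"],
)

# First-analysis group sizes: positive, negative, unknown, healthy controls.
FIRST_ANALYSIS_N = {"positive": 14, "negative": 6, "unknown": 12,
                    "controls": 20}


def pooled_mean(ns, means) -> float:
    """Sample-size-weighted pooled mean."""
    ns = np.asarray(ns, dtype=float)
    means = np.asarray(means, dtype=float)
    if ns.sum() <= 0:
        raise ValueError("total n must be positive")
    return float((ns * means).sum() / ns.sum())


def pooled_group_stat(group: str, col: str) -> float:
    """Pool a per-gender statistic over one study group."""
    sub = GROUP_DEMOGRAPHICS[GROUP_DEMOGRAPHICS.group == group]
    return pooled_mean(sub["n"], sub[col])


def demographic_checks() -> dict[str, float]:
    """Recompute the whole-group demographic quantities from the subgroups."""
    g = GROUP_DEMOGRAPHICS
    out = {
        "pd_n": int(g.loc[g.group == "PD", "n"].sum()),
        "healthy_n": int(g.loc[g.group == "healthy", "n"].sum()),
        "pd_mean_age": pooled_group_stat("PD", "age_mean"),
        "healthy_mean_age": pooled_group_stat("healthy", "age_mean"),
        "pd_mean_mmse": pooled_group_stat("PD", "mmse_mean"),
        "healthy_mean_mmse": pooled_group_stat("healthy", "mmse_mean"),
        "overall_mean_age": pooled_mean(g["n"], g["age_mean"]),
        "percent_female": 100.0 * g.loc[g.gender == "female", "n"].sum()
        / g["n"].sum(),
        "fdopa_positive_n": int(
            FDOPA_CLINICAL.loc[FDOPA_CLINICAL.fdopa == "positive", "n"].sum()),
        "mean_fdopa_auditory_gap_years": pooled_mean(
            FDOPA_CLINICAL["n"], FDOPA_CLINICAL["fdopa_auditory_gap_years"]),
        "healthy_group_composition_n": FIRST_ANALYSIS_N["controls"]
        + FIRST_ANALYSIS_N["negative"],
        "total_participants": int(sum(FIRST_ANALYSIS_N.values())),
    }
    return out
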