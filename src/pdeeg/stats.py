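"""Group-level statistics: Welch t, Gaussian LMM with random load slopes,
Benjamini-Hochberg post-hocs, and a Bayesian Mann-Whitney U test.

The Bayesian rank test follows the latent-normal data-augmentation approach:
each observation is assigned a latent normal score constrained to respect the
observed pooled ranking; group means are separated by a standardized effect
``delta`` with a Cauchy prior.  A Gibbs sampler (default 5 chains of 1,000
iterations) alternates between truncated-normal updates of the latent scores
and a Metropolis-within-Gibbs update of ``delta``; the Bayes factor BF10 is
computed by the Savage-Dickey density ratio at ``delta = 0`` with a
Rao-Blackwellized posterior-density estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import ndtr, ndtri

DEFAULT_PRIOR_SCALE = 1.0 / np.sqrt(2.0)


def round3(x: float) -> float:
    """Table rounding: 3 decimal places, round-half-even."""
    return float(np.round(x, 3))


# --------------------------------------------------------------------- Welch
@dataclass
class WelchResult:
    t: float
    df: float
    p: float


def welch_t(a, b) -> WelchResult:
    """Two-sided Welch unequal-variance t-test with Satterthwaite df."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both samples are degenerate (zero variance)")
    res = sps.ttest_ind(a, b, equal_var=False)
    return WelchResult(t=float(res.statistic), df=float(res.df),
                       p=float(res.pvalue))


# ----------------------------------------------------------------------- LMM
@dataclass
class LMMResult:
    """Fixed-effect table plus variance components and a convergence flag."""

    fixed_effects: pd.DataFrame   # index: effect; coef, se, z, p, ci_low, ci_high
    variance_components: dict
    converged: bool
    n_obs: int
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        return self.fixed_effects.loc[name]


def fit_lmm(long_table: pd.DataFrame, value_col: str = "value") -> LMMResult:
    """Gaussian linear mixed model: value ~ group + load, random intercept
    and random load slope per subject, fit by maximum likelihood.

    ``long_table`` needs columns subject, group (0/1 numeric, 1 = healthy),
    load (0/1/2 numeric) and the outcome column.  Wald z statistics and
    normal-approximation 95% CIs are reported per fixed effect.
    Non-convergence is flagged, never raised.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = long_table.copy()
    for col in ("subject", "group", "load", value_col):
        if col not in df.columns:
            raise ValueError(f"long table is missing column {col!r}")
    if df.groupby("group")["subject"].nunique().min() < 2:
        raise ValueError("need at least 2 subjects per group")
    df = df.rename(columns={value_col: "_y"})
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fit = smf.mixedlm("_y ~ group + load", df, groups=df["subject"],
                          re_formula="~load").fit(reml=False)
    # singular random-effects covariance (e.g. a near-zero slope variance)
    # leaves the fixed effects usable but is flagged as non-convergence
    flagged = any(issubclass(w.category, (ConvergenceWarning, UserWarning))
                  for w in caught)
    converged = bool(fit.converged) and not flagged
    if np.any(~np.isfinite(fit.bse[:3])):
        # degenerate random-slope fit: fall back to random intercepts only,
        # flagged, rather than reporting unusable standard errors
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = smf.mixedlm("_y ~ group + load", df,
                              groups=df["subject"]).fit(reml=False)
        converged = False

    rows = {}
    ci = fit.conf_int()
    for name in ("Intercept", "group", "load"):
        rows[name] = dict(coef=fit.params[name], se=fit.bse[name],
                          z=fit.tvalues[name], p=fit.pvalues[name],
                          ci_low=ci.loc[name, 0], ci_high=ci.loc[name, 1])
    fe = pd.DataFrame(rows).T[["coef", "se", "z", "p", "ci_low", "ci_high"]]
    vc = {"subject_intercept_var": float(fit.cov_re.iloc[0, 0]),
          "load_slope_var": (float(fit.cov_re.iloc[1, 1])
                             if fit.cov_re.shape[0] > 1 else 0.0),
          "residual_var": float(fit.scale)}
    return LMMResult(fixed_effects=fe, variance_components=vc,
                     converged=converged, n_obs=len(df),
                     n_subjects=df["subject"].nunique())


# ------------------------------------------------------------------ post-hoc
def bh_adjust(pvals, cap: bool = True) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    Sorted ascending, p_(i) * m / i, made monotone non-decreasing from the
    largest rank down, capped at 1 (``cap=False`` skips both the monotone
    enforcement's cap and the final cap — a compatibility mode matching
    software that reports raw p*m/rank).
    """
    p = np.asarray(pvals, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    if cap:
        adj = np.minimum.accumulate(ranked[::-1])[::-1]
        adj = np.minimum(adj, 1.0)
    else:
        adj = ranked
    out = np.empty(m)
    out[order] = adj
    return out


#: (name, (first load level, second load level)) — low = rest (0),
#: mid = low-load tasks (1), high = high-load tasks (2).
PAIRWISE_COMPARISONS = (("(high, low)", (2, 0)),
                        ("(mid, low)", (1, 0)),
                        ("(mid, high)", (1, 2)))


def posthoc_pairwise(cond_means: pd.DataFrame, value_col: str = "value",
                     cap: bool = True) -> pd.DataFrame:
    """Paired t-tests between load levels within each group, BH-adjusted.

    ``cond_means`` holds one row per subject per load level with columns
    subject, group, load, and the value column.  Within each group the three
    pairwise comparisons form one BH family.
    """
    df = cond_means
    for col in ("subject", "group", "load", value_col):
        if col not in df.columns:
            raise ValueError(f"cond_means is missing column {col!r}")
    levels = set(df["load"].unique())
    for lvl in (0, 1, 2):
        if lvl not in levels:
            raise ValueError(f"missing load level {lvl}")
    rows = []
    for group, gdf in df.groupby("group", sort=True):
        wide = gdf.pivot_table(index="subject", columns="load",
                               values=value_col)
        raw = []
        for name, (l1, l2) in PAIRWISE_COMPARISONS:
            pair = wide[[l1, l2]].dropna()
            t, p = sps.ttest_rel(pair[l1], pair[l2])
            raw.append((name, float(t), float(p)))
        adj = bh_adjust([p for _, _, p in raw], cap=cap)
        for (name, t, p), pa in zip(raw, adj):
            rows.append((group, name, t, p, float(pa)))
    return pd.DataFrame(rows, columns=["group", "comparison", "t value",
                                       "p value", "p adj BH"])


# ------------------------------------------------------- rank-based Bayesian
def mann_whitney_W(x, y) -> tuple[float, float]:
    """Mann-Whitney W (favorable x-over-y pairs, ties half) and rank-biserial.

    rank-biserial = 2W / (n1*n2) - 1, in [-1, 1].
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("samples must be non-empty")
    W = float(sps.mannwhitneyu(x, y, alternative="two-sided").statistic)
    rb = 2.0 * W / (x.size * y.size) - 1.0
    return W, rb


@dataclass
class BayesUResult:
    BF10: float
    BF01: float
    W: float
    rank_biserial: float
    rhat: float
    chains: int
    iterations_per_chain: int
    prior_scale: float
    delta_samples: np.ndarray = field(repr=False)
    converged: bool = True

    def __post_init__(self) -> None:
        if abs(self.BF10 * self.BF01 - 1.0) > 1e-9:
            raise ValueError("BF10 * BF01 must equal 1")


def _split_rhat(chains: np.ndarray) -> float:
    """Gelman-Rubin split-R-hat over (n_chains, n_iter) draws."""
    n_chains, n_iter = chains.shape
    half = n_iter // 2
    split = chains[:, :2 * half].reshape(2 * n_chains, half)
    means = split.mean(axis=1)
    vars_ = split.var(axis=1, ddof=1)
    W = vars_.mean()
    B = half * means.var(ddof=1)
    if W <= 0:
        return 1.0
    var_hat = (half - 1) / half * W + B / half
    return float(np.sqrt(var_hat / W))


def _rank_groups(values: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Sorted order plus tie groups (indices into the pooled array)."""
    order = np.argsort(values, kind="stable")
    sorted_vals = values[order]
    groups, start = [], 0
    for i in range(1, len(order) + 1):
        if i == len(order) or sorted_vals[i] != sorted_vals[start]:
            groups.append(order[start:i])
            start = i
    return order, groups


def _trunc_norm(rng, mean, lo, hi):
    """Inverse-CDF truncated-normal draws, vectorized."""
    a = ndtr(lo - mean)
    b = ndtr(hi - mean)
    u = rng.uniform(a, np.maximum(b, a + 1e-300))
    return mean + ndtri(np.clip(u, 1e-15, 1 - 1e-15))


def bayes_mannwhitney(x, y, chains: int = 5, iters: int = 1000,
                      prior_scale: float = DEFAULT_PRIOR_SCALE,
                      seed: int = 0, burn_in: int = 100) -> BayesUResult:
    """Bayesian Mann-Whitney U test via latent-normal data augmentation.

    Latents ``z`` carry the observed pooled ranking; group-x latents are
    N(-delta/2, 1), group-y latents N(+delta/2, 1), and ``delta`` has a
    Cauchy(0, ``prior_scale``) prior.  Tie groups are mutually unconstrained.
    BF10 is the Savage-Dickey ratio prior(0)/posterior(0) with the posterior
    density at 0 Rao-Blackwellized over the conditional
    N(delta_hat, 4/(n1+n2)) x Cauchy posterior slices.  ``rhat`` above 1.1
    clears the ``converged`` flag (warning, not an error).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 values")
    if np.any(~np.isfinite(x)) or np.any(~np.isfinite(y)):
        raise ValueError("samples must be finite")
    burn_in = min(burn_in, iters // 2)

    n1, n2 = x.size, y.size
    n = n1 + n2
    pooled = np.concatenate([x, y])
    is_y = np.concatenate([np.zeros(n1, bool), np.ones(n2, bool)])
    order, tie_groups = _rank_groups(pooled)
    G = len(tie_groups)
    singletons = all(len(g) == 1 for g in tie_groups)

    rng = np.random.default_rng(seed)
    cond_var = 4.0 / n
    cond_sd = np.sqrt(cond_var)

    def cauchy_pdf(v):
        return 1.0 / (np.pi * prior_scale * (1.0 + (v / prior_scale) ** 2))

    # Gauss-Hermite grid for the per-slice normalizer of N x Cauchy
    gh_x, gh_w = np.polynomial.hermite_e.hermegauss(63)

    sign = np.where(is_y, 0.5, -0.5)
    all_delta = np.empty((chains, iters))
    all_hat = np.empty((chains, iters))
    for c in range(chains):
        # initialize latents at normal scores of the ranks
        z = ndtri((sps.rankdata(pooled) - 0.375) / (n + 0.25))
        delta = 0.0
        if singletons:
            # z kept in sorted order; neighbours are the rank constraints
            zs = z[order]
            mu_sign = sign[order]
            even = np.arange(0, n, 2)
            odd = np.arange(1, n, 2)
            inf = np.inf
            for t in range(iters):
                mus = mu_sign * delta
                for idx in (even, odd):
                    lo = np.where(idx > 0, zs[np.maximum(idx - 1, 0)], -inf)
                    hi = np.where(idx < n - 1,
                                  zs[np.minimum(idx + 1, n - 1)], inf)
                    zs[idx] = _trunc_norm(rng, mus[idx], lo, hi)
                delta_hat = 2.0 * (zs * mu_sign).sum() * 2.0 / n
                prop = rng.normal(delta_hat, cond_sd)
                if rng.uniform() < cauchy_pdf(prop) / cauchy_pdf(delta):
                    delta = prop
                all_delta[c, t] = delta
                all_hat[c, t] = delta_hat
        else:
            even_g = list(range(0, G, 2))
            odd_g = list(range(1, G, 2))
            for t in range(iters):
                mu = sign * delta
                for parity in (even_g, odd_g):
                    for gi in parity:
                        idx = tie_groups[gi]
                        lo = np.max(z[tie_groups[gi - 1]]) if gi > 0 else -np.inf
                        hi = np.min(z[tie_groups[gi + 1]]) if gi < G - 1 \
                            else np.inf
                        z[idx] = _trunc_norm(rng, mu[idx], lo, hi)
                delta_hat = 2.0 * (z * sign).sum() * 2.0 / n
                prop = rng.normal(delta_hat, cond_sd)
                if rng.uniform() < cauchy_pdf(prop) / cauchy_pdf(delta):
                    delta = prop
                all_delta[c, t] = delta
                all_hat[c, t] = delta_hat

    keep = slice(burn_in, None)
    delta_samples = all_delta[:, keep]
    hats = all_hat[:, keep].ravel()

    # Rao-Blackwellized posterior density at delta = 0
    nodes = hats[:, None] + cond_sd * gh_x[None, :]
    cauchy_vals = sps.cauchy.pdf(nodes, scale=prior_scale)
    Z = (cauchy_vals * gh_w[None, :]).sum(axis=1) / np.sqrt(2 * np.pi)
    norm_at_0 = sps.norm.pdf(0.0, loc=hats, scale=cond_sd)
    post_at_0 = float(np.mean(norm_at_0 * sps.cauchy.pdf(0.0, scale=prior_scale)
                              / np.maximum(Z, 1e-300)))
    prior_at_0 = float(sps.cauchy.pdf(0.0, scale=prior_scale))
    BF01 = max(post_at_0 / prior_at_0, 1e-12)
    BF10 = 1.0 / BF01

    rhat = _split_rhat(delta_samples)
    W, rb = mann_whitney_W(x, y)
    return BayesUResult(BF10=BF10, BF01=BF01, W=W, rank_biserial=rb,
                        rhat=rhat, chains=chains, iterations_per_chain=iters,
                        prior_scale=prior_scale, delta_samples=delta_samples,
                        converged=bool(rhat <= 1.1))
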