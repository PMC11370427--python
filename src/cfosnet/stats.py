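"""Time-course statistics for whole-brain activity densities.

The experimental design euthanises groups of fish at a series of delays after
the novel tank test (plus home-tank and housing-rack controls) and asks when
whole-brain cfos density peaks. The analysis is a sex × time fixed-effects
ANOVA with classical effect sizes (η² = SS_effect / SS_total), Dunnett
many-to-one comparisons of every group against the home-tank control, Cohen's
d for the flagged contrasts, and Benjamini–Hochberg FDR-corrected paired
t-tests for nuclear versus cytoplasmic staining at each time point.

Dunnett adjustment is computed by seeded Monte-Carlo integration of the
equicorrelated multivariate-t reference distribution of max_j |T_j|; accuracy
is controlled by the number of draws and the Monte-Carlo standard error is
reported alongside each adjusted p-value.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multitest import multipletests


class DesignError(ValueError):
    """The factorial design is degenerate (empty level or cell)."""


def anova_two_way(
    data: pd.DataFrame,
    dv: str = "density",
    factors: tuple[str, str] = ("sex", "group"),
    ss_type: int = 2,
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction and classical η².

    Returns one row per effect (both main effects, the interaction and the
    residual) with sum of squares, df, F, p and η² = SS_effect / SS_total.
    ``ss_type`` selects the sums-of-squares decomposition (Type II default,
    appropriate for mildly unbalanced cell counts; Type I and III available).
    """
    fa, fb = factors
    n_levels = {}
    for f in factors:
        levels = data[f].dropna().unique()
        if len(levels) < 1:
            raise DesignError(f"factor {f!r} has no nonempty level")
        n_levels[f] = len(levels)
    if data[dv].isna().any():
        raise DesignError("response contains missing values")
    if ss_type not in (1, 2, 3):
        raise ValueError(f"ss_type must be 1, 2 or 3, got {ss_type}")
    if n_levels[fa] == 1 or n_levels[fb] == 1:
        # constant factor: the design collapses to a one-way ANOVA
        keep = fb if n_levels[fa] == 1 else fa
        model = smf.ols(f"Q('{dv}') ~ C(Q('{keep}'))", data=data).fit()
    else:
        model = smf.ols(f"Q('{dv}') ~ C(Q('{fa}')) * C(Q('{fb}'))", data=data).fit()
    table = sm.stats.anova_lm(model, typ=ss_type)
    table = table.rename(
        index={
            f"C(Q('{fa}'))": fa,
            f"C(Q('{fb}'))": fb,
            f"C(Q('{fa}')):C(Q('{fb}'))": f"{fa}:{fb}",
            "Residual": "residual",
        }
    )
    ss_total = float(((data[dv] - data[dv].mean()) ** 2).sum())
    out = pd.DataFrame(
        {
            "sum_sq": table["sum_sq"],
            "df": table["df"],
            "F": table.get("F"),
            "p": table.get("PR(>F)"),
        }
    )
    out["eta_sq"] = out["sum_sq"] / ss_total
    out.attrs["ss_type"] = ss_type
    return out


def dunnett(
    groups: Mapping[str, Sequence[float]],
    control: str,
    n_mc: int = 20000,
    seed: int = 0,
) -> pd.DataFrame:
    """Dunnett many-to-one comparisons against a control group.

    Classical Dunnett: a pooled variance across all groups, t statistics for
    every group-vs-control mean difference, and a familywise adjustment that
    refers each |t| to the distribution of max_j |T_j| under the global null,
    where (T_1..T_k) follow the equicorrelated multivariate t implied by the
    shared control. That reference distribution is evaluated by Monte-Carlo
    (``n_mc`` seeded draws); the standard error of each adjusted p is
    reported in the ``p_adj_se`` column.
    """
    if control not in groups:
        raise ValueError(f"control group {control!r} not among groups")
    if len(groups) < 2:
        raise ValueError("need at least one comparison group beside the control")
    arrs = {g: np.asarray(v, dtype=float) for g, v in groups.items()}
    if len(arrs[control]) < 2:
        raise ValueError("control group must have >= 2 observations")
    others = [g for g in arrs if g != control]

    n = {g: len(a) for g, a in arrs.items()}
    n_total = sum(n.values())
    k = len(others)
    df_resid = n_total - len(arrs)
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom for the pooled variance")
    pooled_ss = sum(((a - a.mean()) ** 2).sum() for a in arrs.values())
    s2 = pooled_ss / df_resid
    if s2 == 0:
        raise ValueError("pooled variance is zero; t statistics undefined")

    m0 = arrs[control].mean()
    t_obs = np.array(
        [
            (arrs[g].mean() - m0) / np.sqrt(s2 * (1 / n[g] + 1 / n[control]))
            for g in others
        ]
    )
    lam = np.array([np.sqrt(n[g] / (n[g] + n[control])) for g in others])

    # max_j |T_j| under the global null: T_j = (λ_j Z0 + sqrt(1-λ_j²) Z_j) / sqrt(W/ν)
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(n_mc)
    zj = rng.standard_normal((n_mc, k))
    w = rng.chisquare(df_resid, size=n_mc) / df_resid
    t_null = (z0[:, None] * lam + zj * np.sqrt(1 - lam**2)) / np.sqrt(w)[:, None]
    max_abs = np.abs(t_null).max(axis=1)

    p_adj = np.array([np.mean(max_abs >= abs(t)) for t in t_obs])
    p_adj_se = np.sqrt(p_adj * (1 - p_adj) / n_mc)
    p_raw = 2 * scipy.stats.t.sf(np.abs(t_obs), df_resid)
    return pd.DataFrame(
        {
            "comparison": [f"{g} - {control}" for g in others],
            "group": others,
            "mean_diff": [arrs[g].mean() - m0 for g in others],
            "t": t_obs,
            "df": df_resid,
            "p_raw": p_raw,
            "p_adj": p_adj,
            "p_adj_se": p_adj_se,
        }
    ).set_index("group")


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d: (mean(a) − mean(b)) / pooled SD with n₁+n₂−2 in the pool.

    Sign convention: positive when ``a`` has the larger mean.
    """
    x, y = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("both samples need >= 2 observations")
    pooled = np.sqrt(
        (((x - x.mean()) ** 2).sum() + ((y - y.mean()) ** 2).sum())
        / (len(x) + len(y) - 2)
    )
    if pooled == 0:
        raise ValueError("pooled SD is zero; effect size undefined")
    return float((x.mean() - y.mean()) / pooled)


def fdr_bh(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_t(series_a: Sequence[float], series_b: Sequence[float]) -> tuple[float, float]:
    """Two-sided paired t-test; errors on zero-variance differences."""
    a, b = np.asarray(series_a, dtype=float), np.asarray(series_b, dtype=float)
    if len(a) != len(b):
        raise ValueError("paired samples must have equal length")
    if len(a) < 2:
        raise ValueError("need >= 2 pairs")
    diff = a - b
    if np.all(diff == diff[0]) and diff[0] != 0:
        raise ValueError("all differences identical and nonzero; test degenerate")
    if np.all(diff == 0):
        return 0.0, 1.0
    res = scipy.stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue)


def timecourse_report(
    data: pd.DataFrame,
    control: str = "HT",
    dv: str = "density",
    n_mc: int = 20000,
    seed: int = 0,
    ss_type: int = 2,
) -> dict:
    """Full time-course analysis: ANOVA + Dunnett vs control + Cohen's d."""
    anova = anova_two_way(data, dv=dv, factors=("sex", "group"), ss_type=ss_type)
    groups = {g: sub[dv].to_numpy() for g, sub in data.groupby("group", observed=True)}
    dun = dunnett(groups, control=control, n_mc=n_mc, seed=seed)
    dun["cohens_d"] = [
        cohens_d(groups[g], groups[control]) for g in dun.index
    ]
    return {"anova": anova, "dunnett": dun}
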