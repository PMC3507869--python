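"""Sib-line trait statistics: variance components, contrasts, correlations.

Works on long-format trait tables with columns
(line_id, generation, treatment, sample_id, trait, value, units).

The between/within-line decomposition is the one-way random-effects
method-of-moments estimator: within = pooled within-line mean square;
between = (MS_between - MS_within) / n_tilde, where n_tilde is the
average-group-size coefficient (N - sum n_i^2 / N) / (k - 1).  Treatment
contrasts are differences of group means computed on line means (lines are
the independent replication unit), with a Wald statistic (est/se)^2.
Composition correlations are Pearson correlations of line means with
Fisher-z confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "VarianceDecomposition",
    "GroupContrast",
    "CorrelationResult",
    "variance_components",
    "group_contrast",
    "trait_correlations",
    "variance_equality_test",
    "boxplot_summary",
]

TRAIT_COLUMNS = ("line_id", "sample_id", "trait", "value")


def _trait_values(table: pd.DataFrame, trait: str) -> pd.DataFrame:
    missing = [c for c in TRAIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"trait {trait!r} not present in table")
    return sub


@dataclass
class VarianceDecomposition:
    """One-way random-effects components for one trait."""

    trait: str
    between_line: float
    within_line: float
    ss_between: float
    ss_within: float
    ss_total: float
    df_between: int
    df_within: int
    n_tilde: float
    grand_mean: float
    line_means: pd.Series
    clamped: bool  # True when the between moment estimate was negative


def variance_components(table: pd.DataFrame, trait: str,
                        grouping: str = "line_id") -> VarianceDecomposition:
    """Between/within-line variance components by the moment estimator.

    Requires >= 2 lines and at least one line with >= 2 samples.  A negative
    between-line moment estimate is clamped at zero and flagged.
    """
    sub = _trait_values(table, trait)
    values = sub["value"].to_numpy(dtype=float)
    labels = sub[grouping].to_numpy()
    lines, inverse = np.unique(labels, return_inverse=True)
    k = lines.size
    if k < 2:
        raise ValueError("variance decomposition needs >= 2 lines")
    sizes = np.bincount(inverse).astype(float)
    if not np.any(sizes >= 2):
        raise ValueError("at least one line needs >= 2 samples")
    N = values.size
    grand = values.mean()
    line_means = np.array([values[inverse == i].mean() for i in range(k)])
    ss_between = float((sizes * (line_means - grand) ** 2).sum())
    ss_within = float(sum(
        ((values[inverse == i] - line_means[i]) ** 2).sum() for i in range(k)
    ))
    df_between = k - 1
    df_within = N - k
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within if df_within > 0 else 0.0
    n_tilde = (N - (sizes**2).sum() / N) / df_between
    between = (ms_between - ms_within) / n_tilde
    clamped = between < 0
    return VarianceDecomposition(
        trait=trait,
        between_line=max(between, 0.0),
        within_line=ms_within,
        ss_between=ss_between,
        ss_within=ss_within,
        ss_total=ss_between + ss_within,
        df_between=df_between,
        df_within=df_within,
        n_tilde=n_tilde,
        grand_mean=float(grand),
        line_means=pd.Series(line_means, index=lines),
        clamped=bool(clamped),
    )


@dataclass
class GroupContrast:
    """Treated-minus-control contrast with line-clustered standard error."""

    trait: str
    estimate: float
    se: float
    wald: float
    p_value: float
    group_means: dict
    n_lines: dict
    degenerate: bool = False  # zero between-line variability (se = 0)


def group_contrast(table: pd.DataFrame, trait: str,
                   factor: str = "treatment") -> GroupContrast:
    """Difference of group means with line-level clustering-robust SE.

    Line means are the replication unit: the estimate is the difference of
    the two groups' average line means, its standard error
    sqrt(s1^2/k1 + s2^2/k2) from the line-mean dispersions, and the Wald
    statistic (estimate/se)^2 is referred to chi-square on 1 df.
    """
    sub = _trait_values(table, trait)
    if factor not in sub.columns:
        raise ValueError(f"factor column {factor!r} not present")
    groups = sorted(sub[factor].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    line_means = sub.groupby([factor, "line_id"])["value"].mean()
    means, variances, counts = {}, {}, {}
    for g in groups:
        lm = line_means.loc[g]
        if lm.empty:
            raise ValueError(f"group {g!r} is empty")
        means[g] = float(lm.mean())
        variances[g] = float(lm.var(ddof=1)) if len(lm) > 1 else 0.0
        counts[g] = int(len(lm))
    # Contrast direction: "treated" minus "control" when present, else
    # second-sorted minus first-sorted group.
    if set(groups) == {"control", "treated"}:
        hi, lo = "treated", "control"
    else:
        lo, hi = groups
    estimate = means[hi] - means[lo]
    se = float(np.sqrt(variances[hi] / counts[hi] + variances[lo] / counts[lo]))
    if se == 0.0:
        wald = np.inf if estimate != 0 else 0.0
        p = 0.0 if estimate != 0 else 1.0
        return GroupContrast(trait, estimate, se, wald, p, means, counts,
                             degenerate=True)
    wald = (estimate / se) ** 2
    p = float(stats.chi2.sf(wald, df=1))
    return GroupContrast(trait, float(estimate), se, float(wald), p,
                         means, counts)


@dataclass
class CorrelationResult:
    """Pearson correlations of line means with Fisher-z 95% intervals."""

    r: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    n_lines: int
    undefined_pairs: list


def fisher_z_interval(r: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Fisher-z confidence interval for a Pearson correlation."""
    if n < 4 or abs(r) >= 1.0:
        return (np.nan, np.nan)
    z = np.arctanh(r)
    half = stats.norm.ppf(0.5 + conf / 2.0) / np.sqrt(n - 3)
    return (float(np.tanh(z - half)), float(np.tanh(z + half)))


def trait_correlations(table: pd.DataFrame,
                       traits: list[str] | None = None) -> CorrelationResult:
    """Pairwise Pearson correlations between line means of traits.

    Line means (not individual samples) are the unit of correlation.  Pairs
    with fewer than 3 complete line means, or zero variance in either trait,
    are reported as NaN and listed in ``undefined_pairs``.
    """
    missing = [c for c in TRAIT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"trait table missing columns: {missing}")
    if traits is None:
        traits = sorted(table["trait"].unique())
    wide = (
        table[table["trait"].isin(traits)]
        .groupby(["line_id", "trait"])["value"].mean()
        .unstack("trait")
        .reindex(columns=traits)
    )
    k = len(traits)
    r = np.full((k, k), np.nan)
    lo = np.full((k, k), np.nan)
    hi = np.full((k, k), np.nan)
    undefined = []
    for i in range(k):
        r[i, i] = 1.0
        for j in range(i + 1, k):
            pair = wide[[traits[i], traits[j]]].dropna()
            n = len(pair)
            x, y = pair.iloc[:, 0].to_numpy(), pair.iloc[:, 1].to_numpy()
            if n < 3 or np.std(x) == 0 or np.std(y) == 0:
                undefined.append((traits[i], traits[j]))
                continue
            rij = float(stats.pearsonr(x, y).statistic)
            r[i, j] = r[j, i] = rij
            lo[i, j], hi[i, j] = fisher_z_interval(rij, n)
            lo[j, i], hi[j, i] = lo[i, j], hi[i, j]
    idx = pd.Index(traits)
    return CorrelationResult(
        r=pd.DataFrame(r, index=idx, columns=idx),
        ci_low=pd.DataFrame(lo, index=idx, columns=idx),
        ci_high=pd.DataFrame(hi, index=idx, columns=idx),
        n_lines=int(wide.dropna().shape[0]),
        undefined_pairs=undefined,
    )


def variance_equality_test(
    table: pd.DataFrame,
    trait: str,
    factor: str = "treatment",
    component: str = "between",
    n_bootstrap: int = 999,
    rng_seed: int = 0,
) -> dict:
    """Seeded parametric bootstrap test of equal variance components.

    Under the null, both groups share the pooled between- and within-line
    components; the test statistic is the absolute log-ratio of the two
    groups' estimated components (between or within).  Normal data are
    resampled under the null with each group's own design (line count and
    per-line sample sizes) and the add-one bootstrap p-value returned.
    """
    sub = _trait_values(table, trait)
    groups = sorted(sub[factor].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, found {groups}")
    if component not in ("between", "within"):
        raise ValueError("component must be 'between' or 'within'")

    def comp_of(t: pd.DataFrame) -> float:
        d = variance_components(t, trait)
        return d.between_line if component == "between" else d.within_line

    eps = 1e-12

    def statistic(t: pd.DataFrame) -> float:
        vals = [comp_of(t[t[factor] == g]) for g in groups]
        return abs(np.log((vals[0] + eps) / (vals[1] + eps)))

    observed = statistic(sub)
    pooled = variance_components(sub, trait)
    sd_b = np.sqrt(pooled.between_line)
    sd_w = np.sqrt(pooled.within_line)
    designs = {
        g: sub[sub[factor] == g].groupby("line_id").size().to_numpy()
        for g in groups
    }
    rng = np.random.default_rng(rng_seed)
    exceed = 0
    for _ in range(n_bootstrap):
        rows = []
        for g in groups:
            for li, n_i in enumerate(designs[g]):
                mean_i = sd_b * rng.standard_normal()
                vals = mean_i + sd_w * rng.standard_normal(n_i)
                for si, v in enumerate(vals):
                    rows.append((f"{g}_L{li}", g, f"{g}_L{li}_s{si}", trait, v))
        boot = pd.DataFrame(
            rows, columns=["line_id", factor, "sample_id", "trait", "value"]
        )
        if statistic(boot) >= observed - 1e-12:
            exceed += 1
    return {
        "statistic": observed,
        "p_value": (exceed + 1) / (n_bootstrap + 1),
        "component": component,
        "n_bootstrap": n_bootstrap,
    }


def boxplot_summary(table: pd.DataFrame, trait: str,
                    factor: str = "treatment") -> pd.DataFrame:
    """Quartile/whisker summary of line means per group (Fig-6-style)."""
    sub = _trait_values(table, trait)
    line_means = sub.groupby([factor, "line_id"])["value"].mean()
    rows = []
    for g, lm in line_means.groupby(level=0):
        v = lm.to_numpy()
        q1, med, q3 = np.percentile(v, [25, 50, 75])
        iqr = q3 - q1
        lo_w = v[v >= q1 - 1.5 * iqr].min()
        hi_w = v[v <= q3 + 1.5 * iqr].max()
        rows.append((g, len(v), lo_w, q1, med, q3, hi_w, v.mean()))
    return pd.DataFrame(
        rows,
        columns=[factor, "n_lines", "whisker_low", "q1", "median", "q3",
                 "whisker_high", "mean"],
    )
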