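"""Cohort-level statistics over processed subjects.

Paired pre/post comparisons (paired t, Cohen's d with three variants,
fold and percent change), one-way repeated-measures ANOVA with
Bonferroni-adjusted pairwise post-hoc tests, and a summary-table
builder (mean ± SD per variable and timepoint with paired p and d).

Effect sizes use the pooled-SD Cohen's d by default, with the
small-sample (Hedges) correction J = 1 - 3/(4*df - 1) at df = n - 1
for paired designs; a Glass delta (post SD denominator) is also
available.  Sphericity corrections are not applied and that is noted
in the ANOVA metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats

__all__ = [
    "ComparisonResult",
    "RMAnovaResult",
    "paired_t",
    "cohen_d",
    "fold_change",
    "pct_change",
    "rm_anova_bonferroni",
    "summarize_cohort",
]

D_VARIANTS = ("pooled", "pooled_hedges", "glass")
#: interpretation bands for |d| (nonstandard but conventional here)
D_BANDS = ((0.2, "trivial"), (0.5, "medium"), (float("inf"), "large"))


def interpret_d(d: float) -> str:
    for cut, label in D_BANDS:
        if abs(d) < cut:
            return label
    return "large"


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    p_value: float
    effect_size: float
    variant_tag: str
    n: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p_value must lie in [0, 1]")
        if self.n < 2:
            raise ValueError("n must be >= 2")


def paired_t(pre, post, d_variant: str = "pooled_hedges") -> ComparisonResult:
    """Two-sided paired-sample t-test with a Cohen's d effect size.

    Raises on degenerate input (zero variance of the differences),
    which includes identical pre/post vectors and constant shifts.
    """
    pre = np.asarray(pre, float)
    post = np.asarray(post, float)
    if pre.shape != post.shape or pre.ndim != 1 or len(pre) < 2:
        raise ValueError("pre and post must be equal-length 1-d arrays, n >= 2")
    diffs = post - pre
    if np.std(diffs, ddof=1) == 0:
        raise ValueError("paired differences have zero variance; the paired "
                         "t statistic is undefined for degenerate data")
    t, p = stats.ttest_rel(post, pre)
    d = cohen_d(pre.mean(), pre.std(ddof=1), post.mean(), post.std(ddof=1),
                len(pre), variant=d_variant)
    return ComparisonResult(float(t), float(p), d, d_variant, len(pre))


def cohen_d(pre_mean: float, pre_sd: float, post_mean: float, post_sd: float,
            n: int, variant: str = "pooled_hedges") -> float:
    """Cohen's d from summary statistics.

    pooled:        |post - pre| / sqrt((sd_pre^2 + sd_post^2) / 2)
    pooled_hedges: pooled * (1 - 3/(4*(n-1) - 1))   (paired-design df)
    glass:         |post - pre| / sd_post
    """
    if pre_sd < 0 or post_sd < 0 or (pre_sd == 0 and post_sd == 0):
        raise ValueError("SDs must be >= 0 and not both 0")
    delta = abs(post_mean - pre_mean)
    if variant in ("pooled", "pooled_hedges"):
        sp = np.sqrt((pre_sd ** 2 + post_sd ** 2) / 2.0)
        d = delta / sp
        if variant == "pooled_hedges":
            df = n - 1
            d *= 1.0 - 3.0 / (4.0 * df - 1.0)
        return float(d)
    if variant == "glass":
        if post_sd == 0:
            raise ValueError("glass variant undefined for zero post SD")
        return float(delta / post_sd)
    raise ValueError(f"unknown variant {variant!r}; expected one of {D_VARIANTS}")


def fold_change(pre_mean: float, post_mean: float) -> float:
    """post/pre ratio; requires pre > 0."""
    if pre_mean <= 0:
        raise ValueError("fold change requires pre_mean > 0")
    return post_mean / pre_mean


def pct_change(pre_mean: float, post_mean: float) -> float:
    """Percent change 100*(post - pre)/pre; requires pre > 0."""
    if pre_mean <= 0:
        raise ValueError("percent change requires pre_mean > 0")
    return 100.0 * (post_mean - pre_mean) / pre_mean


@dataclass
class RMAnovaResult:
    f: float
    p_value: float
    df_effect: float
    df_error: float
    pairwise: pd.DataFrame  # columns: a, b, t, p_raw, p_bonferroni
    n_subjects: int
    metadata: dict = field(default_factory=dict)


def rm_anova_bonferroni(values) -> RMAnovaResult:
    """One-way repeated-measures ANOVA with Bonferroni post-hoc tests.

    ``values`` is a complete subjects x timepoints matrix (DataFrame
    with timepoint columns, or 2-d array).  Missing cells raise (no
    imputation).  Pairwise paired t-tests have their p-values
    multiplied by the number of comparisons and capped at 1; a
    degenerate pair (zero-variance differences) reports t=0, p=1.
    """
    if isinstance(values, pd.DataFrame):
        wide = values.copy()
    else:
        arr = np.asarray(values, float)
        if arr.ndim != 2:
            raise ValueError("values must be a 2-d subjects x timepoints matrix")
        wide = pd.DataFrame(arr, columns=[f"t{i}" for i in range(arr.shape[1])])
    if wide.isna().any().any():
        raise ValueError("missing cells are not allowed (no imputation)")
    n_sub, n_tp = wide.shape
    if n_tp < 2 or n_sub < 3:
        raise ValueError("need >= 2 timepoints and >= 3 subjects")

    long = wide.reset_index(names="subject").melt(
        id_vars="subject", var_name="timepoint", value_name="value")
    arr = wide.to_numpy(float)
    grand = arr.mean()
    ss_effect = n_sub * ((arr.mean(axis=0) - grand) ** 2).sum()
    ss_error = ((arr - arr.mean(axis=0, keepdims=True)
                 - arr.mean(axis=1, keepdims=True) + grand) ** 2).sum()
    if np.isclose(ss_effect, 0.0) and np.isclose(ss_error, 0.0):
        f, p = 0.0, 1.0
        df1, df2 = float(n_tp - 1), float((n_tp - 1) * (n_sub - 1))
    else:
        aov = pg.rm_anova(data=long, dv="value", within="timepoint",
                          subject="subject", detailed=False)
        f = float(aov.loc[0, "F"])
        p = float(aov.loc[0, "p_unc"])
        df1 = float(aov.loc[0, "ddof1"])
        df2 = float(aov.loc[0, "ddof2"])

    cols = list(wide.columns)
    m = n_tp * (n_tp - 1) // 2
    rows = []
    for i in range(n_tp):
        for j in range(i + 1, n_tp):
            a, b = wide[cols[i]].to_numpy(), wide[cols[j]].to_numpy()
            if np.std(b - a, ddof=1) == 0:
                t_ij, p_ij = 0.0, 1.0
            else:
                t_ij, p_ij = stats.ttest_rel(b, a)
            rows.append({"a": cols[i], "b": cols[j], "t": float(t_ij),
                         "p_raw": float(p_ij),
                         "p_bonferroni": min(float(p_ij) * m, 1.0)})
    pairwise = pd.DataFrame(rows)
    return RMAnovaResult(f=f, p_value=p, df_effect=df1, df_error=df2,
                         pairwise=pairwise, n_subjects=n_sub,
                         metadata={"sphericity_correction": "none",
                                   "n_comparisons": m})


def summarize_cohort(table: pd.DataFrame, pre: str = "baseline",
                     post: str = "post", variables=None,
                     d_variant: str = "pooled_hedges") -> pd.DataFrame:
    """Summary-table report: mean ± SD per variable and timepoint,
    with paired p and Cohen's d for the pre/post contrast.

    ``table`` holds one row per subject x timepoint: columns
    ``subject_id``, ``timepoint`` and one column per variable.
    Returns one row per variable; serializable to CSV/JSON as-is.
    """
    for col in ("subject_id", "timepoint"):
        if col not in table.columns:
            raise ValueError(f"table must have a {col!r} column")
    if table.duplicated(["subject_id", "timepoint"]).any():
        raise ValueError("duplicate subject x timepoint keys")
    if table["subject_id"].nunique() < 2:
        raise ValueError("need >= 2 subjects")
    if variables is None:
        variables = [c for c in table.columns
                     if c not in ("subject_id", "timepoint")]

    rows = []
    for var in variables:
        wide = table.pivot(index="subject_id", columns="timepoint",
                           values=var)
        if pre not in wide.columns or post not in wide.columns:
            continue
        paired = wide[[pre, post]].dropna()
        a, b = paired[pre].to_numpy(float), paired[post].to_numpy(float)
        row = {
            "variable": var,
            "pre_mean": a.mean(), "pre_sd": a.std(ddof=1),
            "post_mean": b.mean(), "post_sd": b.std(ddof=1),
            "n": len(paired),
        }
        try:
            cmp = paired_t(a, b, d_variant=d_variant)
            row.update(t=cmp.statistic, p=cmp.p_value, d=cmp.effect_size,
                       d_variant=cmp.variant_tag,
                       d_label=interpret_d(cmp.effect_size))
        except ValueError:
            row.update(t=np.nan, p=np.nan, d=np.nan, d_variant=d_variant,
                       d_label="degenerate")
        rows.append(row)
    return pd.DataFrame(rows)
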