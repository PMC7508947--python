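"""Group-level statistics shared by the EEG and histology arms.

Implements the study-level statistical layer: control-normalized relative
concentrations, pooled-variance two-sample t-tests, one-way and two-way
ANOVA with Tukey HSD post-hoc comparisons, and post-hoc power of the
two-sample t at an observed effect size (noncentral-t formulation).

Two-way ANOVA uses Type II sums of squares, which reduce to the textbook
Type I decomposition on balanced designs.  Tukey HSD with unequal group
sizes uses the Tukey-Kramer statistic.  Per-section observations nested in
animals are treated as independent observations by default (matching the
upstream protocol's degrees of freedom); an animal-mean aggregation helper
is provided for the conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .exceptions import AnalysisError, ParameterError


@dataclass
class StatReport:
    """Outcome of one test: headline statistic, dfs, p, optional post-hoc table."""

    test: str
    statistic: float
    df: tuple[float, ...]
    p_value: float
    alpha: float = 0.05
    posthoc: pd.DataFrame | None = None
    table: pd.DataFrame | None = None  # full ANOVA table where applicable

    def __str__(self) -> str:  # human-readable one-liner + post-hoc table
        dfs = ",".join(f"{d:g}" for d in self.df)
        head = f"{self.test}: stat({dfs}) = {self.statistic:.4g}, p = {self.p_value:.4g}"
        if self.posthoc is not None:
            head += "\n" + self.posthoc.to_string(index=False)
        return head


def relative_concentration(
    values: np.ndarray, groups: np.ndarray, control_label: str
) -> np.ndarray:
    """Divide per-animal values by the control-group mean.

    The normalized control mean is exactly 1; the operation is idempotent.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    ctrl = values[groups == control_label]
    if len(ctrl) == 0:
        raise AnalysisError(f"no observations with control label {control_label!r}")
    mean = ctrl.mean()
    if mean <= 0:
        raise AnalysisError(f"control mean must be positive, got {mean}")
    return values / mean


def two_sample_t(
    group_a: np.ndarray,
    group_b: np.ndarray,
    equal_var: bool = True,
    alpha: float = 0.05,
) -> StatReport:
    """Two-sided two-sample t-test, pooled variance by default (Welch optional)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ParameterError("each group needs at least 2 observations")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    df = (float(res.df),) if hasattr(res, "df") else (len(a) + len(b) - 2.0,)
    return StatReport(
        test="student_t" if equal_var else "welch_t",
        statistic=float(res.statistic),
        df=df,
        p_value=float(res.pvalue),
        alpha=alpha,
    )


def one_way_anova_hsd(
    values: np.ndarray, groups: np.ndarray, alpha: float = 0.05
) -> StatReport:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    Unequal group sizes are allowed (Tukey-Kramer adjustment in the HSD).
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ParameterError("need at least 2 groups")
    samples = [values[groups == g] for g in levels]
    if any(len(s) < 2 for s in samples):
        raise ParameterError("every group needs at least 2 observations")
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    if np.ptp(values) == 0:
        # all observations identical: no between- or within-group variability
        f_stat, p = 0.0, 1.0
        hsd_p = np.ones((k, k))
    else:
        f_stat, p = sps.f_oneway(*samples)
        hsd_p = sps.tukey_hsd(*samples).pvalue
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            rows.append(
                {
                    "group_a": levels[i],
                    "group_b": levels[j],
                    "mean_diff": float(np.mean(samples[i]) - np.mean(samples[j])),
                    "p_adj": float(hsd_p[i, j]),
                    "reject": bool(hsd_p[i, j] < alpha),
                }
            )
    return StatReport(
        test="one_way_anova",
        statistic=float(f_stat),
        df=(float(k - 1), float(n_total - k)),
        p_value=float(p),
        alpha=alpha,
        posthoc=pd.DataFrame(rows),
    )


def animal_means(
    table: pd.DataFrame,
    value_col: str,
    by: tuple[str, ...] = ("animal_id", "genotype", "region"),
) -> pd.DataFrame:
    """Aggregate per-section observations to one mean per animal and cell.

    Conservative alternative to treating sections as observations
    (avoids pseudo-replication at the cost of error df).
    """
    return table.groupby(list(by), as_index=False)[value_col].mean()


def two_way_anova_hsd(
    table: pd.DataFrame,
    value_col: str = "normalized",
    factor_a: str = "genotype",
    factor_b: str = "region",
    alpha: float = 0.05,
) -> StatReport:
    """Two-way ANOVA (Type II SS) with per-``factor_b`` HSD comparisons of ``factor_a``.

    The ANOVA fits ``value ~ A * B``; the headline statistic is the
    interaction F.  Post-hoc: Tukey HSD over the A x B cell means (family =
    all cells), reported for the within-B pairs that differ only in A — e.g.
    ChR2+ vs ChR2- within each brain region.

    Raises on empty cells, listing them.
    """
    for col in (value_col, factor_a, factor_b):
        if col not in table.columns:
            raise ParameterError(f"table lacks required column {col!r}")
    levels_a = pd.unique(table[factor_a])
    levels_b = pd.unique(table[factor_b])
    if len(levels_a) < 2 or len(levels_b) < 2:
        raise ParameterError("each factor needs at least 2 levels")
    counts = table.groupby([factor_a, factor_b]).size()
    empty = [
        (a, b) for a in levels_a for b in levels_b if (a, b) not in counts.index
    ]
    if empty:
        raise AnalysisError(f"empty design cells: {empty}")

    df = table[[value_col, factor_a, factor_b]].rename(
        columns={value_col: "value", factor_a: "A", factor_b: "B"}
    )
    model = smf.ols("value ~ C(A) * C(B)", data=df).fit()
    anova = sm.stats.anova_lm(model, typ=2)
    anova = anova.rename(
        index={
            "C(A)": factor_a,
            "C(B)": factor_b,
            "C(A):C(B)": f"{factor_a}:{factor_b}",
        }
    )
    inter = anova.loc[f"{factor_a}:{factor_b}"]
    resid_df = float(anova.loc["Residual", "df"])

    cells = df["B"].astype(str) + "||" + df["A"].astype(str)
    hsd = pairwise_tukeyhsd(df["value"].to_numpy(), cells.to_numpy(), alpha=alpha)
    hsd_table = pd.DataFrame(
        hsd.summary().data[1:], columns=hsd.summary().data[0]
    )
    rows = []
    for _, r in hsd_table.iterrows():
        b1, a1 = str(r["group1"]).split("||")
        b2, a2 = str(r["group2"]).split("||")
        if b1 == b2 and a1 != a2:
            rows.append(
                {
                    factor_b: b1,
                    "group_a": a1,
                    "group_b": a2,
                    "mean_diff": float(r["meandiff"]),
                    "p_adj": float(r["p-adj"]),
                    "reject": bool(r["reject"]),
                }
            )
    return StatReport(
        test="two_way_anova",
        statistic=float(inter["F"]),
        df=(float(inter["df"]), resid_df),
        p_value=float(inter["PR(>F)"]),
        alpha=alpha,
        posthoc=pd.DataFrame(rows),
        table=anova,
    )


def posthoc_power_t(
    mean_a: float,
    sem_a: float,
    n_a: int,
    mean_b: float,
    sem_b: float,
    n_b: int,
    alpha: float = 0.05,
) -> float:
    """Post-hoc power of the two-sided two-sample t at the observed effect.

    SDs are recovered as SEM * sqrt(n); the pooled SD gives Cohen's d, the
    noncentrality parameter is d * sqrt(n_a n_b / (n_a + n_b)), and power is
    the probability mass of the noncentral t outside the two-sided critical
    values.  At zero effect the value equals alpha.
    """
    if n_a < 2 or n_b < 2:
        raise ParameterError("need n >= 2 per group")
    if sem_a <= 0 or sem_b <= 0:
        raise ParameterError("SEMs must be positive")
    if not 0 < alpha < 1:
        raise ParameterError("alpha must be in (0, 1)")
    sd_a = sem_a * np.sqrt(n_a)
    sd_b = sem_b * np.sqrt(n_b)
    df = n_a + n_b - 2
    sd_pooled = np.sqrt(((n_a - 1) * sd_a**2 + (n_b - 1) * sd_b**2) / df)
    d = abs(mean_a - mean_b) / sd_pooled
    ncp = d * np.sqrt(n_a * n_b / (n_a + n_b))
    t_crit = sps.t.ppf(1 - alpha / 2, df)
    return float(sps.nct.sf(t_crit, df, ncp) + sps.nct.cdf(-t_crit, df, ncp))
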