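"""Group comparison layer: normality gating and the tests used on cohorts.

The reporting style follows common practice for imaging cohorts: a Lilliefors
normality check (plus a variance-ratio homoscedasticity check) gates the
choice between parametric and rank-based tests; rank-based results carry
per-group mean ranks, parametric results carry means +/- SEM.

The Kruskal-Wallis H statistic (midranks, tie-corrected) and the two-sample
Kolmogorov-Smirnov D are computed directly from their definitions; p-values
come from the chi-square and asymptotic Kolmogorov distributions.  The
two-sample t uses the pooled-variance form throughout (df = n1 + n2 - 2),
including a reconstruction from printed summary values (mean, SEM, n) for
checking published statistics without raw data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import kolmogorov
from statsmodels.stats.diagnostic import lilliefors as _sm_lilliefors

__all__ = [
    "GroupSample",
    "TestResult",
    "lilliefors_gate",
    "kruskal_wallis",
    "ks_two_sample",
    "t_from_summary",
    "unpaired_t",
    "compare_cohorts",
]

# Hartley-style maximum variance ratio accepted as homoscedastic.
VARIANCE_RATIO_LIMIT = 4.0


@dataclass
class GroupSample:
    label: str
    values: np.ndarray
    unit: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size < 1:
            raise ValueError(f"group {self.label!r} is empty")
        if not np.all(np.isfinite(self.values)):
            raise ValueError(f"group {self.label!r} contains non-finite values")

    @property
    def n(self) -> int:
        return int(self.values.size)


@dataclass
class TestResult:
    method: str
    statistic: float
    p_value: float
    df: float | None = None
    n_groups: int | None = None
    mean_ranks: dict[str, float] | None = None
    group_summaries: dict[str, tuple[float, float, int]] = field(default_factory=dict)
    groups: tuple[str, ...] = ()

    def p_repr(self) -> str:
        """P-value as printed; underflowed values reported as a bound."""
        if self.p_value == 0.0:
            return "< 1e-300"
        return f"{self.p_value:.4g}"

    def __str__(self) -> str:
        parts = [f"{self.method}: statistic = {self.statistic:.4f}"]
        if self.df is not None:
            parts.append(f"df = {self.df:g}")
        parts.append(f"p = {self.p_repr()}")
        if self.mean_ranks:
            ranks = ", ".join(f"{k} = {v:.2f}" for k, v in self.mean_ranks.items())
            parts.append(f"mean ranks: {ranks}")
        return "; ".join(parts)


def lilliefors_gate(samples: GroupSample | list[GroupSample], alpha: float = 0.05) -> str:
    """Decide 'parametric' vs 'nonparametric' for the supplied sample(s).

    Each group must pass a Lilliefors normality test (KS against the normal
    with estimated mean/variance, small-sample critical values) at ``alpha``;
    with two or more groups the maximum/minimum variance ratio must also stay
    below 4.  Any failure selects the nonparametric branch.
    """
    groups = [samples] if isinstance(samples, GroupSample) else list(samples)
    variances = []
    for g in groups:
        if g.n < 4:
            raise ValueError(f"group {g.label!r} needs n >= 4 for the normality test")
        if np.std(g.values) == 0:
            raise ValueError(f"group {g.label!r} is constant (degenerate)")
        _, p = _sm_lilliefors(g.values, dist="norm", pvalmethod="table")
        if p < alpha:
            return "nonparametric"
        variances.append(np.var(g.values, ddof=1))
    if len(variances) >= 2:
        if max(variances) / min(variances) > VARIANCE_RATIO_LIMIT:
            return "nonparametric"
    return "parametric"


def kruskal_wallis(groups: list[GroupSample]) -> TestResult:
    """Tie-corrected Kruskal-Wallis H with per-group mean ranks.

    H = 12/(N(N+1)) * sum_g R_g^2/n_g - 3(N+1), on midranks, divided by the
    tie-correction factor 1 - sum(t^3 - t)/(N^3 - N); chi-square p-value on
    k - 1 degrees of freedom.  All-identical values give H = 0, p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    pooled = np.concatenate([g.values for g in groups])
    n_total = pooled.size
    if n_total < 3:
        raise ValueError("need total n >= 3")
    ranks = sps.rankdata(pooled)  # midranks
    mean_ranks: dict[str, float] = {}
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + g.n]
        start += g.n
        mean_ranks[g.label] = float(r.mean())
        h += r.sum() ** 2 / g.n
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    tie_corr = 1.0 - float(np.sum(counts**3 - counts)) / (n_total**3 - n_total)
    if tie_corr == 0.0:  # every value identical
        h, p = 0.0, 1.0
    else:
        h = h / tie_corr
        p = float(sps.chi2.sf(h, df=len(groups) - 1))
    return TestResult(
        method="Kruskal-Wallis H",
        statistic=float(h),
        p_value=p,
        df=len(groups) - 1,
        n_groups=len(groups),
        mean_ranks=mean_ranks,
        group_summaries={
            g.label: (float(g.values.mean()), _sem(g.values), g.n) for g in groups
        },
        groups=tuple(g.label for g in groups),
    )


def _sem(x: np.ndarray) -> float:
    return float(np.std(x, ddof=1) / np.sqrt(x.size)) if x.size > 1 else float("nan")


def ks_two_sample(a: GroupSample, b: GroupSample) -> TestResult:
    """Two-sample Kolmogorov-Smirnov: D = sup |ECDF_a - ECDF_b|, asymptotic p."""
    x, y = np.sort(a.values), np.sort(b.values)
    grid = np.concatenate([x, y])
    cdf_a = np.searchsorted(x, grid, side="right") / x.size
    cdf_b = np.searchsorted(y, grid, side="right") / y.size
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = np.sqrt(x.size * y.size / (x.size + y.size))
    p = float(np.clip(kolmogorov((en + 0.12 + 0.11 / en) * d), 0.0, 1.0))
    return TestResult(
        method="two-sample Kolmogorov-Smirnov",
        statistic=d,
        p_value=p,
        n_groups=2,
        group_summaries={
            g.label: (float(g.values.mean()), _sem(g.values), g.n) for g in (a, b)
        },
        groups=(a.label, b.label),
    )


def t_from_summary(
    mean1: float, sem1: float, n1: int, mean2: float, sem2: float, n2: int
) -> TestResult:
    """Pooled-variance two-sample t reconstructed from printed summaries.

    Group variances are recovered as var_i = n_i * sem_i^2; the pooled t has
    df = n1 + n2 - 2 and, for n1 = n2, reduces to
    (mean1 - mean2) / sqrt(sem1^2 + sem2^2).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need n >= 2 per group")
    if sem1 <= 0 or sem2 <= 0:
        raise ValueError("SEMs must be positive")
    var1, var2 = n1 * sem1**2, n2 * sem2**2
    df = n1 + n2 - 2
    pooled = ((n1 - 1) * var1 + (n2 - 1) * var2) / df
    t = (mean1 - mean2) / np.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    p = float(2.0 * sps.t.sf(abs(t), df=df))
    return TestResult(
        method="unpaired t (from summary)",
        statistic=float(t),
        p_value=p,
        df=df,
        n_groups=2,
        group_summaries={
            "group1": (mean1, sem1, n1),
            "group2": (mean2, sem2, n2),
        },
        groups=("group1", "group2"),
    )


def unpaired_t(a: GroupSample, b: GroupSample) -> TestResult:
    """Pooled-variance two-sample t on raw samples (first minus second)."""
    if a.n < 2 or b.n < 2:
        raise ValueError("need n >= 2 per group")
    s1, s2 = _sem(a.values), _sem(b.values)
    if (np.var(a.values, ddof=1) + np.var(b.values, ddof=1)) == 0:
        raise ValueError("zero pooled variance")
    res = t_from_summary(
        float(a.values.mean()), s1, a.n, float(b.values.mean()), s2, b.n
    )
    res.method = "unpaired t"
    res.group_summaries = {
        a.label: (float(a.values.mean()), s1, a.n),
        b.label: (float(b.values.mean()), s2, b.n),
    }
    res.groups = (a.label, b.label)
    return res


def compare_cohorts(
    table: pd.DataFrame,
    value_col: str = "value",
    metric_col: str = "metric",
    group_col: str = "group",
    alpha: float = 0.05,
    correction: str = "none",
) -> pd.DataFrame:
    """Run the gated comparison for every metric of a tidy results table.

    For each metric: the Lilliefors/variance gate selects the branch, then
    three or more groups get Kruskal-Wallis (rank-based, mean ranks
    reported) and two groups get an unpaired t (parametric branch) or KS
    (nonparametric branch).  Returns one row per metric with the statistic,
    p-value, and per-group mean +/- SEM and mean ranks.

    ``correction="holm"`` adds Holm-adjusted p-values across the metrics in
    a ``p_adjusted`` column; no correction is applied by default.
    """
    if correction not in ("none", "holm"):
        raise ValueError("correction must be 'none' or 'holm'")
    rows = []
    for metric, sub in table.groupby(metric_col, sort=False):
        groups = [
            GroupSample(label=str(lbl), values=g[value_col].to_numpy())
            for lbl, g in sub.groupby(group_col, sort=False)
        ]
        groups = [g for g in groups if g.n >= 1]
        if len(groups) < 2:
            continue
        try:
            gate = lilliefors_gate(groups, alpha=alpha)
        except ValueError:
            gate = "nonparametric"
        if len(groups) >= 3:
            res = kruskal_wallis(groups)
        elif gate == "parametric":
            res = unpaired_t(groups[0], groups[1])
        else:
            res = ks_two_sample(groups[0], groups[1])
        row = {
            "metric": metric,
            "method": res.method,
            "gate": gate,
            "statistic": res.statistic,
            "df": res.df,
            "p_value": res.p_value,
            "p_repr": res.p_repr(),
            "groups": ",".join(res.groups),
        }
        for lbl, (m, s, n) in res.group_summaries.items():
            row[f"mean[{lbl}]"] = m
            row[f"sem[{lbl}]"] = s
            row[f"n[{lbl}]"] = n
        if res.mean_ranks:
            for lbl, r in res.mean_ranks.items():
                row[f"mean_rank[{lbl}]"] = r
        rows.append(row)
    table_out = pd.DataFrame(rows)
    if correction == "holm" and len(table_out):
        from statsmodels.stats.multitest import multipletests

        table_out["p_adjusted"] = multipletests(
            table_out["p_value"].to_numpy(), method="holm"
        )[1]
    return table_out
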