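"""Group statistics: t-tests, two-way ANOVA with Bonferroni post-tests,
baseline-normalized time courses and the summary digest.

Conventions follow the source field's reporting style: values are summarised
as mean ± SEM per group with the experimental unit being the soma/unit,
significance is starred at P < 0.05 (*), < 0.01 (**) and < 0.001 (***), the
unpaired t-test defaults to the equal-variance Student form (Welch by flag),
and ANOVA F statistics are reported with their degree-of-freedom pair as
F_{df1, df2}.  Gaussianity is assumed; no normality gate is applied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import DesignError, ParameterError

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def p_to_stars(p: float) -> str:
    """Significance stars: P<0.05 '*', P<0.01 '**', P<0.001 '***', else 'ns'."""
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


@dataclass
class GroupSample:
    """Per-unit metric values of one group × treatment cell."""

    group: str
    values: np.ndarray
    treatment: str = ""
    n_animals: Optional[int] = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.all(np.isfinite(self.values)):
            raise ParameterError(f"group {self.group}: non-finite values")

    @property
    def n_units(self) -> int:
        return int(self.values.size)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sem(self) -> float:
        if self.values.size < 2:
            return float("nan")
        return float(sps.sem(self.values))


@dataclass
class GroupStats:
    label: str
    n: int
    mean: float
    sem: float
    n_animals: Optional[int] = None


@dataclass
class TestResult:
    test_name: str
    statistic: float
    df: float | tuple[float, float]
    p_value: float
    groups: list[GroupStats] = field(default_factory=list)
    stars: str = "ns"

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ParameterError("p-value outside [0, 1]")

    @property
    def df_label(self) -> str:
        if isinstance(self.df, tuple):
            return f"F_{{{self.df[0]:g}, {self.df[1]:g}}}"
        return f"df={self.df:g}"


# ---------------------------------------------------------------------------
# t-tests
# ---------------------------------------------------------------------------

def _as_sample(x, label) -> GroupSample:
    if isinstance(x, GroupSample):
        return x
    return GroupSample(group=label, values=np.asarray(x, dtype=float))


def ttest(a, b, paired: bool = False, equal_var: bool = True,
          labels: tuple[str, str] = ("a", "b")) -> TestResult:
    """Two-sided t-test between two groups of per-unit values.

    Unpaired defaults to the equal-variance Student form; ``equal_var=False``
    gives Welch.  Paired requires equal n in matched order.  Degenerate
    zero-variance identical samples return t = 0, p = 1.
    """
    sa, sb = _as_sample(a, labels[0]), _as_sample(b, labels[1])
    if sa.n_units < 2 or sb.n_units < 2:
        raise ParameterError("need n >= 2 per group")
    if paired:
        if sa.n_units != sb.n_units:
            raise ParameterError("paired test needs equal n")
        res = sps.ttest_rel(sa.values, sb.values)
        df = float(sa.n_units - 1)
        name = "paired t-test"
    else:
        res = sps.ttest_ind(sa.values, sb.values, equal_var=equal_var)
        df = float(res.df)
        name = "unpaired t-test" if equal_var else "Welch t-test"
    t, p = float(res.statistic), float(res.pvalue)
    if np.isnan(t):
        # zero within- (or difference-) variance with equal means
        t, p = 0.0, 1.0
    return TestResult(
        test_name=name, statistic=t, df=df, p_value=p,
        groups=[GroupStats(sa.group, sa.n_units, sa.mean, sa.sem, sa.n_animals),
                GroupStats(sb.group, sb.n_units, sb.mean, sb.sem, sb.n_animals)],
        stars=p_to_stars(p),
    )


# ---------------------------------------------------------------------------
# two-way ANOVA + Bonferroni post-tests
# ---------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Main effects + interaction, and Bonferroni-adjusted pairwise post-tests
    between groups within each treatment level."""

    effects: dict[str, TestResult]
    table: pd.DataFrame
    posthoc: pd.DataFrame


def bonferroni(p_values: Sequence[float], n_comparisons: Optional[int] = None
               ) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, p × m).  Always >= raw p."""
    p = np.asarray(p_values, dtype=float)
    m = int(n_comparisons) if n_comparisons is not None else p.size
    if m < 1:
        raise ParameterError("need at least one comparison")
    return np.minimum(1.0, p * m)


def two_way_anova(
    data: pd.DataFrame,
    value: str = "value",
    group: str = "group",
    treatment: str = "treatment",
) -> AnovaResult:
    """Two-way ANOVA (type II) with Bonferroni post-tests.

    ``data`` is long-format with one row per unit/soma.  Post-tests compare
    group levels pairwise within each treatment level; the Bonferroni factor
    is the total number of such contrasts.  Degenerate all-identical data
    yields F = 0, p = 1 for every effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    for col in (value, group, treatment):
        if col not in data.columns:
            raise DesignError(f"missing column {col!r}")
    g_levels = sorted(data[group].astype(str).unique())
    t_levels = sorted(data[treatment].astype(str).unique())
    if len(g_levels) < 2 or len(t_levels) < 2:
        raise DesignError("need >= 2 levels per factor")
    cells = data.groupby([group, treatment], observed=True)[value].count()
    if len(cells) < len(g_levels) * len(t_levels) or (cells < 1).any():
        raise DesignError("empty factorial cell")

    d = data[[value, group, treatment]].copy()
    d.columns = ["y", "g", "t"]
    d["g"] = d["g"].astype(str)
    d["t"] = d["t"].astype(str)
    model = smf.ols("y ~ C(g) * C(t)", data=d).fit()
    table = sm.stats.anova_lm(model, typ=2)

    name_map = {"C(g)": group, "C(t)": treatment, "C(g):C(t)": "interaction"}
    df_resid = float(table.loc["Residual", "df"])
    # scale below which a sum of squares is numerically zero (identical data)
    ss_floor = 1e-12 * max(1.0, float(np.mean(np.abs(d["y"])) ** 2)) * len(d)
    effects: dict[str, TestResult] = {}
    for src, label in name_map.items():
        ss = float(table.loc[src, "sum_sq"])
        df1 = float(table.loc[src, "df"])
        F = float(table.loc[src, "F"])
        p = float(table.loc[src, "PR(>F)"])
        if ss <= ss_floor:
            # no effect variance at all (e.g. identical values everywhere)
            F, p = 0.0, 1.0
        elif not np.isfinite(F):
            # nonzero effect against exactly zero residual variance
            F, p = float("inf"), 0.0
        effects[label] = TestResult(
            test_name=f"two-way ANOVA: {label}", statistic=F,
            df=(df1, df_resid), p_value=p, stars=p_to_stars(p),
        )

    # Bonferroni pairwise post-tests within treatment levels
    rows = []
    n_pairs = len(g_levels) * (len(g_levels) - 1) // 2
    m = n_pairs * len(t_levels)
    for t_lv in t_levels:
        sub = d[d["t"] == t_lv]
        for i in range(len(g_levels)):
            for j in range(i + 1, len(g_levels)):
                x = sub.loc[sub["g"] == g_levels[i], "y"].to_numpy()
                yv = sub.loc[sub["g"] == g_levels[j], "y"].to_numpy()
                if x.size < 2 or yv.size < 2:
                    continue
                r = ttest(x, yv, labels=(g_levels[i], g_levels[j]))
                rows.append(
                    dict(treatment=t_lv, group_1=g_levels[i], group_2=g_levels[j],
                         n_1=x.size, n_2=yv.size, t=r.statistic, df=r.df,
                         p_raw=r.p_value)
                )
    posthoc = pd.DataFrame(
        rows, columns=["treatment", "group_1", "group_2", "n_1", "n_2",
                       "t", "df", "p_raw"],
    )
    if len(posthoc):
        posthoc["p_bonf"] = bonferroni(posthoc["p_raw"].to_numpy(), m)
        posthoc["stars"] = [p_to_stars(p) for p in posthoc["p_bonf"]]
    else:
        posthoc["p_bonf"] = []
        posthoc["stars"] = []
    return AnovaResult(effects=effects, table=table, posthoc=posthoc)


# ---------------------------------------------------------------------------
# time courses
# ---------------------------------------------------------------------------

def build_timecourse(
    sr: pd.DataFrame,
    group: str = "group",
    time_bin: str = "time_bin",
    value: str = "sr_percent",
    baseline_label: str = "baseline",
    bin_order: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Group mean ± SEM of relative spike rate (%) per time bin.

    The baseline bin is 100% with SEM 0 by construction (each unit normalized
    to itself); it is emitted even when absent from the input.  Missing
    non-baseline bins are reported as absent (NaN mean, n = 0), never imputed.
    Units with undefined SR (NaN) are dropped per bin.
    """
    rows = []
    bins = list(bin_order) if bin_order is not None else sorted(
        sr[time_bin].astype(str).unique()
    )
    if baseline_label not in bins:
        bins = [baseline_label] + bins
    for g, grp in sr.groupby(group, sort=True):
        for b in bins:
            if b == baseline_label:
                n = grp["unit_id"].nunique() if "unit_id" in grp else len(grp)
                rows.append(dict(group=g, time_bin=b, mean_pct=100.0,
                                 sem_pct=0.0, n=int(n), absent=False))
                continue
            vals = grp.loc[grp[time_bin].astype(str) == b, value].dropna()
            if len(vals) == 0:
                rows.append(dict(group=g, time_bin=b, mean_pct=float("nan"),
                                 sem_pct=float("nan"), n=0, absent=True))
            else:
                rows.append(dict(
                    group=g, time_bin=b, mean_pct=float(vals.mean()),
                    sem_pct=float(sps.sem(vals)) if len(vals) > 1 else float("nan"),
                    n=int(len(vals)), absent=False,
                ))
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# report assembly
# ---------------------------------------------------------------------------

def assemble_report(tables: dict[str, pd.DataFrame],
                    n_animals: Optional[dict[str, int]] = None) -> dict:
    """Assemble the stats digest from upstream result tables.

    ``tables`` maps metric names to long-format DataFrames with columns
    ``group`` and ``value`` (optionally ``treatment``).  Emits one digest row
    per pairwise group comparison per metric, annotated with n units/somas
    and, when provided, n animals.  An arm with fewer than 2 observations is
    marked absent rather than tested.
    """
    rows = []
    for metric, df in tables.items():
        if df is None or len(df) == 0:
            rows.append(dict(metric=metric, group_1="", group_2="",
                             test="absent", n_1=0, n_2=0,
                             statistic=float("nan"), df="", p=float("nan"),
                             stars="", note="arm absent"))
            continue
        groups = sorted(df["group"].astype(str).unique())
        if len(groups) == 1:
            x = df["value"].dropna()
            g = GroupSample(group=groups[0], values=x.to_numpy()) \
                if len(x) else None
            rows.append(dict(metric=metric, group_1=groups[0], group_2="",
                             test="descriptive", n_1=len(x), n_2=0,
                             statistic=g.mean if g else float("nan"), df="",
                             p=float("nan"), stars="",
                             note=f"mean±SEM = {g.mean:.4g}±{g.sem:.4g}"
                             if g and len(x) > 1 else "single group"))
            continue
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                x = df.loc[df["group"].astype(str) == groups[i], "value"].dropna()
                y = df.loc[df["group"].astype(str) == groups[j], "value"].dropna()
                if len(x) < 2 or len(y) < 2:
                    rows.append(dict(metric=metric, group_1=groups[i],
                                     group_2=groups[j], test="absent",
                                     n_1=len(x), n_2=len(y),
                                     statistic=float("nan"), df="",
                                     p=float("nan"), stars="",
                                     note="arm absent"))
                    continue
                r = ttest(x.to_numpy(), y.to_numpy(), labels=(groups[i], groups[j]))
                na = (n_animals or {}).get(groups[i])
                nb = (n_animals or {}).get(groups[j])
                note = ""
                if na is not None and nb is not None:
                    note = f"{len(x)} units/{na} mice vs {len(y)} units/{nb} mice"
                rows.append(dict(metric=metric, group_1=groups[i],
                                 group_2=groups[j], test=r.test_name,
                                 n_1=len(x), n_2=len(y), statistic=r.statistic,
                                 df=r.df_label, p=r.p_value, stars=r.stars,
                                 note=note))
    digest = pd.DataFrame(
        rows, columns=["metric", "group_1", "group_2", "test", "n_1", "n_2",
                       "statistic", "df", "p", "stars", "note"],
    )
    return {"digest": digest}


def plot_timecourse(tc: pd.DataFrame, ax=None):
    """Mean ± SEM time course per group with the 100% baseline line."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for g, grp in tc.groupby("group"):
        grp = grp[~grp["absent"]]
        ax.errorbar(range(len(grp)), grp["mean_pct"], yerr=grp["sem_pct"],
                    marker="o", capsize=3, label=str(g))
        ax.set_xticks(range(len(grp)), grp["time_bin"])
    ax.axhline(100.0, linestyle=":", color="grey")
    ax.set_ylabel("relative spike rate (% of baseline)")
    ax.legend()
    return ax


def plot_fractions(fractions: pd.DataFrame, ax=None):
    """Stacked response-class fractions per group."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    piv = fractions.pivot(index="group", columns="response_class",
                          values="fraction")
    piv.plot(kind="bar", stacked=True, ax=ax)
    ax.set_ylabel("fraction of units")
    return ax


__all__ = [
    "GroupSample",
    "GroupStats",
    "TestResult",
    "AnovaResult",
    "p_to_stars",
    "ttest",
    "two_way_anova",
    "bonferroni",
    "build_timecourse",
    "assemble_report",
    "plot_timecourse",
    "plot_fractions",
]
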