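"""Normality-routed group comparisons with matched post hoc procedures.

The routing contract for one-way designs: run a Shapiro-Wilk normality
test on every group at alpha = 0.05; if *all* groups pass, compare with
one-way ANOVA followed by Tukey-Kramer (or Holm-Sidak-adjusted pairwise
t tests when selected); if *any* group fails, fall back to the
Kruskal-Wallis test followed by Dunn's post hoc with Bonferroni
adjustment.  Two-way (condition x day) designs use a two-way ANOVA with
interaction followed by Tukey on the condition-day cells.

Established implementations are called throughout (scipy.stats,
statsmodels); this module contributes the routing, Dunn's rank-based
post hoc (with tie correction), and the reporting contract including
the four-level significance stars (* p<0.05 ... **** p<0.0001).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

from .errors import ValidationError

__all__ = [
    "GroupData",
    "ComparisonResult",
    "significance_stars",
    "route_omnibus",
    "dunn_posthoc",
    "route_and_compare",
    "type_i_error_check",
]


def significance_stars(p: float) -> str:
    """Caption-style stars: * <0.05, ** <0.01, *** <0.001, **** <0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass
class GroupData:
    """Labeled measurement groups for a one-way or two-way design.

    For two-way designs, ``frame`` must hold columns ``value``,
    ``condition`` and ``day``; for one-way designs ``groups`` maps each
    label to its measurement array.
    """

    groups: dict[str, np.ndarray] | None = None
    frame: pd.DataFrame | None = None
    design: str = "one-way"
    alpha: float = 0.05

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError(f"alpha must be in (0,1), got {self.alpha}", field="alpha")
        if self.design not in ("one-way", "two-way"):
            raise ValidationError(f"unknown design {self.design!r}", field="design")
        if self.design == "one-way":
            if not self.groups or len(self.groups) < 2:
                raise ValidationError("need >= 2 groups", field="groups")
            self.groups = {k: np.asarray(v, dtype=float) for k, v in self.groups.items()}
            for label, vals in self.groups.items():
                if vals.size < 3:
                    raise ValidationError(
                        f"group {label!r} has n={vals.size} < 3", field=label)
        else:
            if self.frame is None:
                raise ValidationError("two-way design requires a data frame", field="frame")
            missing = {"value", "condition", "day"} - set(self.frame.columns)
            if missing:
                raise ValidationError(f"missing columns {sorted(missing)}", field="frame")


@dataclass
class ComparisonResult:
    """Outcome of a routed comparison.

    ``posthoc`` has columns: group1, group2, p_adj, stars.
    """

    route: str                      # "parametric" | "nonparametric"
    omnibus_test: str
    omnibus_stat: float
    omnibus_p: float
    posthoc_test: str
    posthoc: pd.DataFrame
    shapiro_p: dict[str, float] = field(default_factory=dict)
    extra: dict = field(default_factory=dict)

    def summary(self) -> str:
        lines = [
            f"route:   {self.route}",
            f"omnibus: {self.omnibus_test}  stat={self.omnibus_stat:.4g}  "
            f"p={self.omnibus_p:.4g} {significance_stars(self.omnibus_p)}",
            f"posthoc: {self.posthoc_test}",
            self.posthoc.to_string(index=False),
        ]
        return "\n".join(lines)


def route_omnibus(groups: dict[str, np.ndarray], alpha: float = 0.05):
    """Normality-routed omnibus test.

    Returns (route, test_name, statistic, p, shapiro_p_by_group).  The
    route is a pure function of the per-group Shapiro-Wilk outcomes at
    ``alpha``.  Degenerate (zero-variance) data yield p = 1 and no
    rejection.
    """
    shapiro_p = {}
    all_normal = True
    for label, vals in groups.items():
        if np.ptp(vals) == 0:
            # constant group: Shapiro-Wilk is undefined; treat as non-normal
            shapiro_p[label] = 0.0
            all_normal = False
            continue
        p = float(stats.shapiro(vals).pvalue)
        shapiro_p[label] = p
        if p < alpha:
            all_normal = False
    samples = list(groups.values())
    if np.ptp(np.concatenate(samples)) == 0:
        # all observations identical across every group: nothing to test
        return ("degenerate", "none", float("nan"), 1.0, shapiro_p)
    if all_normal:
        stat, p = stats.f_oneway(*samples)
        return ("parametric", "one-way ANOVA", float(stat), float(p), shapiro_p)
    try:
        stat, p = stats.kruskal(*samples)
    except ValueError:  # all numbers identical within scipy's check
        return ("degenerate", "none", float("nan"), 1.0, shapiro_p)
    return ("nonparametric", "Kruskal-Wallis", float(stat), float(p), shapiro_p)


def _pairs(labels):
    labels = list(labels)
    return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]


def dunn_posthoc(groups: dict[str, np.ndarray], adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based multiple-comparison test after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)) over tie groups.
    Two-sided normal p-values, Bonferroni-adjusted by default.
    """
    labels = list(groups)
    pooled = np.concatenate([groups[k] for k in labels])
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    mean_rank, sizes = {}, {}
    start = 0
    for k in labels:
        n = groups[k].size
        mean_rank[k] = ranks[start:start + n].mean()
        sizes[k] = n
        start += n
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    raw_p = []
    for a, b in _pairs(labels):
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append({"group1": a, "group2": b, "stat": float(z)})
        raw_p.append(p)
    if adjust == "bonferroni":
        p_adj = np.minimum(np.asarray(raw_p) * len(raw_p), 1.0)
    else:
        p_adj = multipletests(raw_p, method=adjust)[1]
    for row, p in zip(rows, p_adj):
        row["p_adj"] = float(p)
        row["stars"] = significance_stars(float(p))
    return pd.DataFrame(rows)


def _tukey_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    labels = list(groups)
    res = stats.tukey_hsd(*[groups[k] for k in labels])
    rows = []
    for i, a in enumerate(labels):
        for j in range(i + 1, len(labels)):
            p = float(res.pvalue[i, j])
            rows.append({"group1": a, "group2": labels[j],
                         "stat": float(res.statistic[i, j]),
                         "p_adj": p, "stars": significance_stars(p)})
    return pd.DataFrame(rows)


def _holm_sidak_posthoc(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows, raw_p = [], []
    for a, b in _pairs(groups):
        t, p = stats.ttest_ind(groups[a], groups[b])
        rows.append({"group1": a, "group2": b, "stat": float(t)})
        raw_p.append(float(p))
    p_adj = multipletests(raw_p, method="holm-sidak")[1]
    for row, p in zip(rows, p_adj):
        row["p_adj"] = float(p)
        row["stars"] = significance_stars(float(p))
    return pd.DataFrame(rows)


def _two_way(data: GroupData) -> ComparisonResult:
    df = data.frame.copy()
    model = ols("value ~ C(condition) * C(day)", data=df).fit()
    table = anova_lm(model, typ=2)
    cells = {f"{c}|{d}": g["value"].to_numpy()
             for (c, d), g in df.groupby(["condition", "day"])}
    posthoc = _tukey_posthoc(cells)
    p_cond = float(table.loc["C(condition)", "PR(>F)"])
    return ComparisonResult(
        route="parametric",
        omnibus_test="two-way ANOVA",
        omnibus_stat=float(table.loc["C(condition)", "F"]),
        omnibus_p=p_cond,
        posthoc_test="Tukey HSD (condition x day cells)",
        posthoc=posthoc,
        extra={
            "anova_table": table,
            "p_condition": p_cond,
            "p_day": float(table.loc["C(day)", "PR(>F)"]),
            "p_interaction": float(table.loc["C(condition):C(day)", "PR(>F)"]),
        },
    )


def route_and_compare(data: GroupData, posthoc: str = "auto") -> ComparisonResult:
    """Run the study's comparison pipeline on a GroupData.

    One-way: Shapiro-Wilk routing -> ANOVA + Tukey-Kramer (or Holm-Sidak
    pairwise t tests when ``posthoc='holm-sidak'``) if all groups are
    normal, else Kruskal-Wallis + Dunn (Bonferroni).  Two-way: two-way
    ANOVA with interaction + Tukey on cells.  The chosen procedures are
    recorded on the result.
    """
    if posthoc not in ("auto", "tukey", "dunn", "holm-sidak"):
        raise ValidationError(f"unknown posthoc {posthoc!r}", field="posthoc")
    if data.design == "two-way":
        return _two_way(data)
    route, test, stat, p, shapiro_p = route_omnibus(data.groups, data.alpha)
    if route == "degenerate":
        empty = pd.DataFrame(columns=["group1", "group2", "stat", "p_adj", "stars"])
        return ComparisonResult(route=route, omnibus_test=test, omnibus_stat=stat,
                                omnibus_p=p, posthoc_test="none", posthoc=empty,
                                shapiro_p=shapiro_p)
    if route == "parametric":
        if posthoc == "holm-sidak":
            table, name = _holm_sidak_posthoc(data.groups), "Holm-Sidak pairwise t"
        elif posthoc == "dunn":
            table, name = dunn_posthoc(data.groups), "Dunn (Bonferroni)"
        else:
            table, name = _tukey_posthoc(data.groups), "Tukey-Kramer"
    else:
        if posthoc == "tukey":
            table, name = _tukey_posthoc(data.groups), "Tukey-Kramer"
        elif posthoc == "holm-sidak":
            table, name = _holm_sidak_posthoc(data.groups), "Holm-Sidak pairwise t"
        else:
            table, name = dunn_posthoc(data.groups), "Dunn (Bonferroni)"
    return ComparisonResult(route=route, omnibus_test=test, omnibus_stat=stat,
                            omnibus_p=p, posthoc_test=name, posthoc=table,
                            shapiro_p=shapiro_p)


def type_i_error_check(dist: str = "normal", n_groups: int = 3, n: int = 10,
                       reps: int = 500, alpha: float = 0.05,
                       seed: int | None = None) -> float:
    """Empirical type-I error of the routed omnibus under a true null.

    Simulates ``reps`` datasets of ``n_groups`` iid groups drawn from the
    same distribution (``normal``, ``exponential``, ``lognormal`` or
    ``t3`` heavy-tailed), routes each through the normality-based
    omnibus, and returns the fraction rejecting at ``alpha``.
    """
    if reps < 1:
        raise ValidationError("reps must be >= 1", field="reps")
    rng = np.random.default_rng(seed)
    samplers = {
        "normal": lambda size: rng.normal(size=size),
        "exponential": lambda size: rng.exponential(size=size),
        "lognormal": lambda size: rng.lognormal(size=size),
        "t3": lambda size: rng.standard_t(3, size=size),
    }
    if dist not in samplers:
        raise ValidationError(f"unknown distribution {dist!r}", field="dist")
    draw = samplers[dist]
    rejections = 0
    for _ in range(reps):
        groups = {f"g{i}": draw(n) for i in range(n_groups)}
        _, _, _, p, _ = route_omnibus(groups, alpha)
        if p < alpha:
            rejections += 1
    return rejections / reps
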