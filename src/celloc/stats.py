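"""Heteroscedastic group inference on per-cell colocalization values.

The per-cell Pearson r values of each genotype form groups with unequal
variances and sizes, so group comparison uses Welch's one-way ANOVA for the
omnibus test and the Games-Howell procedure (studentized-range reference
distribution with Welch–Satterthwaite degrees of freedom) for pairwise
post-hoc comparisons against the wild-type group.

The module exposes both the individual statistics (:func:`welch_anova`,
:func:`games_howell`) and a statsmodels-style model object,
:class:`WelchOneWay`, whose :meth:`~WelchOneWay.fit` returns a
:class:`WelchOneWayResults` carrying the omnibus result, the post-hoc
table, per-group summaries and a text ``summary()``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "GroupSummary",
    "WelchResult",
    "GHComparison",
    "summarize_groups",
    "welch_anova",
    "games_howell",
    "compare_to_wt",
    "WelchOneWay",
    "WelchOneWayResults",
]

STAR_THRESHOLDS = ((0.001, "***"), (0.01, "**"), (0.05, "*"))


def significance_stars(p: float) -> str:
    for cut, stars in STAR_THRESHOLDS:
        if p < cut:
            return stars
    return "ns"


@dataclass(frozen=True)
class GroupSummary:
    genotype_label: str
    comarker: str
    n: int
    mean: float
    sd: float
    median: float
    q1: float
    q3: float
    min: float
    max: float


@dataclass(frozen=True)
class WelchResult:
    F: float
    df1: int
    df2: float
    p: float
    k: int
    W: float  # sum of weights n_i / s_i^2


@dataclass(frozen=True)
class GHComparison:
    group_i: str
    group_j: str
    mean_diff: float
    se: float
    t: float
    df: float
    q: float
    p_adj: float
    significance_stars: str


def _quartiles(x: np.ndarray) -> tuple[float, float, float]:
    """Median and quartiles by linear interpolation between order statistics."""
    q1, med, q3 = np.percentile(x, [25, 50, 75], method="linear")
    return float(q1), float(med), float(q3)


def summarize_groups(records: pd.DataFrame,
                     value: str = "pearson_r") -> list[GroupSummary]:
    """One summary (n, mean, sd, median, quartiles, range) per
    (genotype, comarker) group — the numbers a box-and-whisker plot shows."""
    out: list[GroupSummary] = []
    if len(records) == 0:
        return out
    for (gen, com), grp in records.groupby(["genotype_label", "comarker"],
                                           sort=True):
        x = grp[value].to_numpy(dtype=float)
        q1, med, q3 = _quartiles(x)
        out.append(GroupSummary(
            genotype_label=str(gen), comarker=str(com), n=len(x),
            mean=float(x.mean()), sd=float(x.std(ddof=1)) if len(x) > 1 else 0.0,
            median=med, q1=q1, q3=q3, min=float(x.min()), max=float(x.max())))
    return out


def welch_anova(groups: Sequence[np.ndarray]) -> WelchResult:
    """Welch's heteroscedastic one-way ANOVA.

    With weights w_i = n_i / s_i^2, W = sum(w_i) and weighted grand mean
    xbar_w, the statistic is

        F = [ sum w_i (xbar_i - xbar_w)^2 / (k-1) ]
            / [ 1 + 2 (k-2) / (k^2 - 1) * Lambda ]

    where Lambda = sum (1 - w_i/W)^2 / (n_i - 1), with df1 = k - 1 and
    df2 = (k^2 - 1) / (3 Lambda).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if k < 2:
        raise ValueError("need at least 2 groups")
    n = np.array([g.size for g in groups], dtype=float)
    if (n < 2).any():
        raise ValueError("every group needs n >= 2")
    m = np.array([g.mean() for g in groups])
    v = np.array([g.var(ddof=1) for g in groups])
    if (v <= 0).any():
        bad = int(np.argmax(v <= 0))
        raise ValueError(f"group {bad} has zero within-group variance")

    w = n / v
    W = w.sum()
    xw = (w * m).sum() / W
    lam = ((1.0 - w / W) ** 2 / (n - 1.0)).sum()
    num = (w * (m - xw) ** 2).sum() / (k - 1)
    den = 1.0 + 2.0 * (k - 2) / (k ** 2 - 1.0) * lam
    F = num / den
    df1 = k - 1
    df2 = (k ** 2 - 1.0) / (3.0 * lam)
    p = float(sps.f.sf(F, df1, df2))
    return WelchResult(F=float(F), df1=df1, df2=float(df2), p=p, k=k, W=float(W))


def _gh_pair(xi: np.ndarray, xj: np.ndarray, k: int) -> tuple[float, ...]:
    ni, nj = xi.size, xj.size
    vi, vj = xi.var(ddof=1), xj.var(ddof=1)
    se = float(np.sqrt(vi / ni + vj / nj))
    diff = float(xi.mean() - xj.mean())
    t = abs(diff) / se
    df = (vi / ni + vj / nj) ** 2 / (
        (vi / ni) ** 2 / (ni - 1) + (vj / nj) ** 2 / (nj - 1))
    q = float(np.sqrt(2.0) * t)
    p_adj = float(sps.studentized_range.sf(q, k, df))
    p_adj = min(1.0, max(0.0, p_adj))
    return diff, se, float(t), float(df), q, p_adj


def games_howell(groups: Sequence[np.ndarray],
                 names: Optional[Sequence[str]] = None,
                 reference: Optional[str] = None) -> list[GHComparison]:
    """Games-Howell pairwise comparisons.

    ``reference=None`` (or "all-pairs") compares every pair; otherwise only
    each group against the reference group.  The studentized-range upper
    tail is always evaluated with the full number of groups k, so the
    correction is familywise over the whole family of group means.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    k = len(groups)
    if names is None:
        names = [str(i) for i in range(k)]
    if len(names) != k:
        raise ValueError("names length must match groups")
    for g in groups:
        if g.size < 2 or g.var(ddof=1) <= 0:
            raise ValueError("every group needs n >= 2 and positive variance")
    if reference not in (None, "all-pairs") and reference not in names:
        raise ValueError(f"reference group {reference!r} absent")

    if reference in (None, "all-pairs"):
        pairs = list(combinations(range(k), 2))
    else:
        ref = list(names).index(reference)
        pairs = [(ref, j) for j in range(k) if j != ref]

    out = []
    for i, j in pairs:
        diff, se, t, df, q, p_adj = _gh_pair(groups[i], groups[j], k)
        out.append(GHComparison(
            group_i=names[i], group_j=names[j], mean_diff=diff, se=se,
            t=t, df=df, q=q, p_adj=p_adj,
            significance_stars=significance_stars(p_adj)))
    return out


def compare_to_wt(records: pd.DataFrame, wt_label: str,
                  min_cells: int = 30, enforce_min_cells: bool = True,
                  value: str = "pearson_r",
                  ) -> dict[str, tuple[WelchResult, list[GHComparison]]]:
    """Omnibus Welch ANOVA + Games-Howell vs wild type, per comarker.

    Every genotype must contribute at least ``min_cells`` observations
    (set ``enforce_min_cells=False`` to override the gate).
    """
    out: dict[str, tuple[WelchResult, list[GHComparison]]] = {}
    for com, sub in records.groupby("comarker", sort=True):
        model = WelchOneWay.from_dataframe(sub, value=value,
                                           group="genotype_label")
        if wt_label not in model.names:
            raise ValueError(f"wild-type label {wt_label!r} absent for {com}")
        if enforce_min_cells:
            low = [n for n, g in zip(model.names, model.groups)
                   if g.size < min_cells]
            if low:
                raise ValueError(
                    f"groups below min_cells={min_cells} for {com}: {low}")
        res = model.fit(reference=wt_label)
        out[str(com)] = (res.anova, res.comparisons)
    return out


# ---------------------------------------------------------------------------
# model / results objects

class WelchOneWay:
    """One-way fixed-effects comparison of group means under heteroscedasticity.

    Parameters
    ----------
    groups : sequence of 1-D arrays
        Observations per group.
    names : sequence of str, optional
        Group labels (defaults to indices).

    Use :meth:`from_dataframe` to build the model from long-format data.
    """

    def __init__(self, groups: Sequence[np.ndarray],
                 names: Optional[Sequence[str]] = None):
        self.groups = [np.asarray(g, dtype=float) for g in groups]
        self.names = list(names) if names is not None else [
            str(i) for i in range(len(self.groups))]
        if len(self.names) != len(self.groups):
            raise ValueError("names length must match groups")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, value: str,
                       group: str) -> "WelchOneWay":
        names, groups = [], []
        for name, sub in data.groupby(group, sort=True):
            names.append(str(name))
            groups.append(sub[value].to_numpy(dtype=float))
        return cls(groups, names)

    def fit(self, reference: Optional[str] = None) -> "WelchOneWayResults":
        anova = welch_anova(self.groups)
        comparisons = games_howell(self.groups, self.names,
                                   reference=reference or "all-pairs")
        return WelchOneWayResults(self, anova, comparisons, reference)


class WelchOneWayResults:
    """Fitted results: omnibus Welch ANOVA plus Games-Howell post-hoc table."""

    def __init__(self, model: WelchOneWay, anova: WelchResult,
                 comparisons: list[GHComparison],
                 reference: Optional[str]):
        self.model = model
        self.anova = anova
        self.comparisons = comparisons
        self.reference = reference

    @property
    def posthoc_frame(self) -> pd.DataFrame:
        return pd.DataFrame([c.__dict__ for c in self.comparisons])

    def group_means(self) -> pd.Series:
        return pd.Series({n: g.mean() for n, g in
                          zip(self.model.names, self.model.groups)})

    def summary(self) -> str:
        a = self.anova
        lines = [
            "Welch one-way ANOVA (heteroscedastic)",
            f"  groups: {a.k}   F({a.df1}, {a.df2:.1f}) = {a.F:.4f}   "
            f"p = {a.p:.3e}",
            "",
            "Games-Howell post-hoc"
            + (f" (vs {self.reference})" if self.reference else ""),
            f"  {'pair':<24}{'diff':>9}{'se':>8}{'t':>8}{'df':>8}"
            f"{'p_adj':>11}  sig",
        ]
        for c in self.comparisons:
            pair = f"{c.group_i} vs {c.group_j}"
            lines.append(
                f"  {pair:<24}{c.mean_diff:>9.4f}{c.se:>8.4f}{c.t:>8.3f}"
                f"{c.df:>8.1f}{c.p_adj:>11.3e}  {c.significance_stars}")
        return "\n".join(lines)
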