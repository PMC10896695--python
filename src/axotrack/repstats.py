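"""Replicate-level statistics with a normality-gated test family.

The pipeline mirrors standard practice in live-imaging studies: per-track
values are first averaged within each biological replicate, all inference
then runs on the replicate means. Each group's means are checked with
Shapiro–Wilk; if every group is consistent with normality the parametric
family is used (Student's t for two groups, one-way ANOVA + Tukey HSD for
more), otherwise the rank-based family (Kruskal–Wallis + Dunn post hoc).
The gate is joint: a single non-normal group switches the whole family.

The Dunn test (pooled mid-ranks, tie correction, two-sided normal p
values, Holm adjustment by default) is implemented here directly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["GroupData", "ComparisonResults", "ReplicateComparison",
           "replicate_means", "omnibus_test", "dunn_posthoc"]

GroupData = dict[str, dict[str, list[float]]]
"""group label -> replicate label -> per-track values."""


def replicate_means(data: GroupData) -> dict[str, list[float]]:
    """Arithmetic mean per biological replicate, per group.

    One value per replicate enters any downstream test, regardless of
    how many tracks the replicate contains.
    """
    out: dict[str, list[float]] = {}
    for group, reps in data.items():
        means = []
        for rep, values in reps.items():
            arr = np.asarray(values, dtype=float)
            if arr.size == 0:
                raise ValueError(f"empty replicate '{rep}' in group '{group}'")
            means.append(float(arr.mean()))
        out[group] = means
    return out


def dunn_posthoc(groups: dict[str, list[float]],
                 adjustment: str = "holm") -> pd.DataFrame:
    """Dunn's z test on pooled ranks for all unordered group pairs.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j))
    with tie correction T = sum(t^3 - t) / (12 (N - 1)). Two-sided
    normal p values; ``adjustment`` in {"none", "holm"}.
    """
    if adjustment not in ("none", "holm"):
        raise ValueError("adjustment must be 'none' or 'holm'")
    labels = list(groups)
    arrs = [np.asarray(groups[g], dtype=float) for g in labels]
    pooled = np.concatenate(arrs)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    mean_ranks, sizes = [], []
    start = 0
    for a in arrs:
        mean_ranks.append(ranks[start:start + a.size].mean())
        sizes.append(a.size)
        start += a.size
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (12.0 * (n_total - 1)) \
        if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se if se > 0 else 0.0
        p = 2.0 * stats.norm.sf(abs(z)) if se > 0 else 1.0
        rows.append({"group_1": labels[i], "group_2": labels[j],
                     "statistic": float(z), "p": float(min(p, 1.0))})
    table = pd.DataFrame(rows)
    if adjustment == "holm" and not table.empty:
        table["p_adjusted"] = multipletests(table["p"].to_numpy(), method="holm")[1]
    else:
        table["p_adjusted"] = table["p"]
    table["adjustment"] = adjustment
    return table


def _tukey_table(labels: list[str], arrs: list[np.ndarray]) -> pd.DataFrame:
    res = stats.tukey_hsd(*arrs)
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        rows.append({"group_1": labels[i], "group_2": labels[j],
                     "statistic": float(res.statistic[i, j]),
                     "p": float(res.pvalue[i, j]),
                     "p_adjusted": float(res.pvalue[i, j]),
                     "adjustment": "tukey-hsd"})
    return pd.DataFrame(rows)


@dataclass
class ComparisonResults:
    """Outcome of the gated omnibus + post-hoc pipeline."""

    test_name: str
    statistic: float
    p_value: float
    pairwise: pd.DataFrame
    normality: dict[str, float]  # group -> Shapiro-Wilk p (NaN if not testable)
    normal_branch: bool
    status: str = "ok"
    group_means: dict[str, float] = field(default_factory=dict)

    def summary(self) -> str:
        lines = [f"Omnibus: {self.test_name}"]
        if self.status != "ok":
            lines.append(f"  status: {self.status}")
        lines.append(f"  statistic = {self.statistic:.4g}, p = {self.p_value:.4g}")
        branch = "parametric (all groups normal)" if self.normal_branch \
            else "rank-based"
        lines.append(f"  branch: {branch}")
        for g, p in self.normality.items():
            lines.append(f"    Shapiro-Wilk {g}: p = {p:.3g}")
        if not self.pairwise.empty:
            lines.append(self.pairwise.to_string(index=False))
        return "\n".join(lines)


class ReplicateComparison:
    """Normality-gated comparison of groups of replicate means.

    Parameters
    ----------
    data : GroupData or dict of group -> list of replicate means
        Nested input is reduced with :func:`replicate_means` first.
    alpha : float
        Level of the Shapiro–Wilk normality gate (default 0.05).
    adjustment : str
        Dunn adjustment, "holm" (default) or "none".
    family : str
        "auto" (default) applies the normality gate; "parametric" or
        "rank" forces the corresponding branch.
    """

    def __init__(self, data, alpha: float = 0.05, adjustment: str = "holm",
                 family: str = "auto"):
        if family not in ("auto", "parametric", "rank"):
            raise ValueError("family must be 'auto', 'parametric' or 'rank'")
        if not data or len(data) < 2:
            raise ValueError("need at least two groups")
        first = next(iter(data.values()))
        if isinstance(first, dict):
            data = replicate_means(data)
        self.groups: dict[str, list[float]] = {
            g: [float(v) for v in vals] for g, vals in data.items()}
        for g, vals in self.groups.items():
            if len(vals) == 0:
                raise ValueError(f"group '{g}' is empty")
        self.alpha = alpha
        self.adjustment = adjustment
        self.family = family

    def _normality(self) -> tuple[dict[str, float], bool]:
        """Shapiro–Wilk per group; groups with < 3 values or zero variance
        cannot be tested and force the rank-based branch."""
        ps: dict[str, float] = {}
        all_normal = True
        for g, vals in self.groups.items():
            arr = np.asarray(vals, dtype=float)
            if arr.size < 3 or np.allclose(arr, arr[0]):
                ps[g] = float("nan")
                all_normal = False
                continue
            p = float(stats.shapiro(arr).pvalue)
            ps[g] = p
            if p <= self.alpha:
                all_normal = False
        return ps, all_normal

    def fit(self) -> ComparisonResults:
        labels = list(self.groups)
        arrs = [np.asarray(self.groups[g], dtype=float) for g in labels]
        means = {g: float(a.mean()) for g, a in zip(labels, arrs)}
        pooled = np.concatenate(arrs)
        if np.allclose(pooled, pooled[0]):
            empty = pd.DataFrame(columns=["group_1", "group_2", "statistic",
                                          "p", "p_adjusted", "adjustment"])
            return ComparisonResults(
                test_name="degenerate", statistic=float("nan"), p_value=1.0,
                pairwise=empty, normality={g: float("nan") for g in labels},
                normal_branch=False, status="degenerate variance",
                group_means=means)
        normality, all_normal = self._normality()
        if self.family == "parametric":
            all_normal = True
        elif self.family == "rank":
            all_normal = False
        if all_normal:
            if len(labels) == 2:
                res = stats.ttest_ind(arrs[0], arrs[1])
                pairwise = pd.DataFrame([{
                    "group_1": labels[0], "group_2": labels[1],
                    "statistic": float(res.statistic), "p": float(res.pvalue),
                    "p_adjusted": float(res.pvalue), "adjustment": "none"}])
                return ComparisonResults("t-test", float(res.statistic),
                                         float(res.pvalue), pairwise, normality,
                                         True, group_means=means)
            stat, p = stats.f_oneway(*arrs)
            return ComparisonResults("one-way ANOVA + Tukey", float(stat),
                                     float(p), _tukey_table(labels, arrs),
                                     normality, True, group_means=means)
        stat, p = stats.kruskal(*arrs)
        pairwise = dunn_posthoc(self.groups, adjustment=self.adjustment)
        return ComparisonResults("Kruskal-Wallis + Dunn", float(stat), float(p),
                                 pairwise, normality, False, group_means=means)


def omnibus_test(groups, alpha: float = 0.05, adjustment: str = "holm",
                 family: str = "auto") -> ComparisonResults:
    """Run the full gated pipeline on groups of replicate means."""
    return ReplicateComparison(groups, alpha=alpha, adjustment=adjustment,
                               family=family).fit()
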