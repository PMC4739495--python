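"""Group comparison and summary reporting for diffusion and intensity data.

Nonparametric comparisons matching the field's conventions: Mann-Whitney U
for two-group intensity data, two-sample Kolmogorov-Smirnov for diffusion
coefficient distributions, Kruskal-Wallis with Dunn's post-hoc test for
multi-group designs.  Summaries report median and quartiles per group.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ComparisonReport", "compare_groups", "dunn_posthoc"]


@dataclass
class ComparisonReport:
    test: str
    statistic: float
    pvalue: float
    summary: pd.DataFrame                 # group, n, median, q25, q75
    pairwise: pd.DataFrame | None = None  # Dunn post-hoc rows

    def to_dict(self) -> dict:
        d = {"test": self.test, "statistic": self.statistic, "pvalue": self.pvalue,
             "groups": self.summary.to_dict(orient="records")}
        if self.pairwise is not None:
            d["pairwise"] = self.pairwise.to_dict(orient="records")
        return d


def _summary(groups: dict[str, np.ndarray]) -> pd.DataFrame:
    rows = []
    for name, v in groups.items():
        v = np.asarray(v, float)
        rows.append({"group": name, "n": len(v),
                     "median": float(np.median(v)),
                     "q25": float(np.percentile(v, 25)),
                     "q75": float(np.percentile(v, 75))})
    return pd.DataFrame(rows)


def dunn_posthoc(groups: dict[str, np.ndarray],
                 adjust: str = "bonferroni") -> pd.DataFrame:
    """Dunn's rank-based pairwise comparisons after Kruskal-Wallis.

    z_ij = (Rbar_i - Rbar_j) / sqrt((N(N+1)/12 - T) (1/n_i + 1/n_j)) with the
    tie correction T = sum(t^3 - t) / (12 (N - 1)); two-sided normal p-values
    with Bonferroni adjustment over the k(k-1)/2 pairs.
    """
    names = list(groups)
    values = np.concatenate([np.asarray(groups[g], float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    n_total = len(values)
    ranks = stats.rankdata(values)
    mean_rank, start = {}, 0
    for g in names:
        mean_rank[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = np.sum(tie_counts ** 3 - tie_counts) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term

    pairs = list(itertools.combinations(names, 2))
    rows = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1.0 / sizes[a] + 1.0 / sizes[b]))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        p_adj = min(p * len(pairs), 1.0) if adjust == "bonferroni" else p
        rows.append({"group_a": a, "group_b": b, "z": float(z),
                     "pvalue": float(p), "pvalue_adj": float(p_adj)})
    return pd.DataFrame(rows)


def compare_groups(groups: dict[str, np.ndarray], test: str = "MW"
                   ) -> ComparisonReport:
    """Compare value distributions between named groups.

    ``test``: "MW" (Mann-Whitney U, 2 groups), "KS" (two-sample
    Kolmogorov-Smirnov, 2 groups) or "KW_dunn" (Kruskal-Wallis followed by
    Dunn's pairwise comparisons).  All tests are two-sided; every group must
    have n >= 3.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    for name, v in groups.items():
        if len(v) < 3:
            raise ValueError(f"group {name!r} has n={len(v)} < 3")
    arrays = [np.asarray(v, float) for v in groups.values()]
    pairwise = None
    if test == "MW":
        if len(groups) != 2:
            raise ValueError("MW compares exactly 2 groups")
        res = stats.mannwhitneyu(*arrays, alternative="two-sided")
    elif test == "KS":
        if len(groups) != 2:
            raise ValueError("KS compares exactly 2 groups")
        res = stats.ks_2samp(*arrays)
    elif test == "KW_dunn":
        res = stats.kruskal(*arrays)
        pairwise = dunn_posthoc(groups)
    else:
        raise ValueError(f"unknown test {test!r}")
    return ComparisonReport(test=test, statistic=float(res.statistic),
                            pvalue=float(res.pvalue), summary=_summary(groups),
                            pairwise=pairwise)
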