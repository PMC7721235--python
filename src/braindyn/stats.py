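"""Group statistics: Welch tests, BH-FDR, Fisher's exact tests, correlations.

Implements the comparison layer used to contrast fitted model parameters,
graph metrics, and cognitive scores across cohorts, with false-discovery-rate
control over region families.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, lgamma

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import (
    AlignmentError,
    DegenerateInputError,
    InsufficientReplicatesError,
    InvalidArgumentError,
)


def welch_t_test(x, y) -> tuple[float, float, float]:
    """Welch's unequal-variance two-sample t test.

    Returns (t, Welch-Satterthwaite df, two-sided p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise InvalidArgumentError("each sample needs >= 2 values")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0 and vy == 0:
        raise DegenerateInputError("both samples have zero variance")
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    t = (x.mean() - y.mean()) / np.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up procedure.

    Returns (adjusted p-values, rejection mask at level ``q``).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    _, adjusted, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return adjusted, adjusted <= q


@dataclass
class CorrelationResult:
    """Pearson correlation with its two-sided p-value."""

    r: float
    p: float
    n: int
    x_name: str = "x"
    y_name: str = "y"
    group: str | None = None


def correlate(x, y, x_name: str = "x", y_name: str = "y",
              group: str | None = None) -> CorrelationResult:
    """Pearson correlation; p from the t transform with n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise AlignmentError("x and y lengths differ")
    if x.size < 3:
        raise InvalidArgumentError("correlation needs n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateInputError("zero variance in a correlate input")
    r, p = sps.pearsonr(x, y)
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size),
                             x_name=x_name, y_name=y_name, group=group)


# ---------------------------------------------------------------------------
# Fisher's exact test

def _log_table_prob(table: np.ndarray) -> float:
    # hypergeometric log-probability of an r x c table with fixed margins
    rs, cs = table.sum(1), table.sum(0)
    ntot = table.sum()
    num = sum(lgamma(v + 1) for v in rs) + sum(lgamma(v + 1) for v in cs)
    den = lgamma(ntot + 1) + sum(lgamma(v + 1) for v in table.ravel())
    return num - den


def _enumerate_2xc(row1_total: int, col_sums: list[int]):
    # all first rows (a_1..a_c) with sum = row1_total and 0 <= a_j <= col_j
    c = len(col_sums)

    def rec(j, remaining, prefix):
        if j == c - 1:
            if 0 <= remaining <= col_sums[j]:
                yield prefix + [remaining]
            return
        for a in range(0, min(col_sums[j], remaining) + 1):
            yield from rec(j + 1, remaining - a, prefix + [a])

    yield from rec(0, row1_total, [])


def fisher_exact(table) -> float:
    """Two-sided Fisher exact p for a 2x2 or 2x3 contingency table.

    2x2 uses the standard hypergeometric summation; 2x3 the Freeman-Halton
    extension by full enumeration of tables with the observed margins.
    """
    t = np.asarray(table, dtype=int)
    if t.ndim != 2 or t.shape[0] != 2 or t.shape[1] not in (2, 3):
        raise InvalidArgumentError("table must be 2x2 or 2x3")
    if np.any(t < 0):
        raise InvalidArgumentError("table counts must be nonnegative")
    if np.any(t.sum(0) == 0) or np.any(t.sum(1) == 0):
        raise InvalidArgumentError("table has a zero margin")
    if t.shape[1] == 2:
        return float(sps.fisher_exact(t, alternative="two-sided")[1])
    obs_logp = _log_table_prob(t)
    col_sums = t.sum(0).tolist()
    r1 = int(t.sum(1)[0])
    p = 0.0
    for first_row in _enumerate_2xc(r1, col_sums):
        cand = np.array([first_row, list(np.array(col_sums) - first_row)])
        lp = _log_table_prob(cand)
        if lp <= obs_logp + 1e-9:
            p += np.exp(lp)
    return float(min(p, 1.0))


# ---------------------------------------------------------------------------
# Regional parameter comparisons

def compare_regional_parameters(results_by_group: dict, which: str = "w",
                                q: float = 0.01) -> pd.DataFrame:
    """Region-wise Welch tests of fitted parameters between cohorts.

    ``results_by_group`` maps a group label to a list of RMFMParameters (the
    selected top-k runs, the unit of replication).  All pairwise group
    contrasts are tested per region; BH-FDR is applied over the full
    regions-by-pairs family.  Returns a tidy frame with means, SDs, t, df,
    raw and adjusted p, and a significance flag at ``q``.
    """
    if which not in ("w", "I"):
        raise InvalidArgumentError("which must be 'w' or 'I'")
    groups = list(results_by_group)
    if len(groups) < 2:
        raise InvalidArgumentError("need >= 2 groups")
    mats = {}
    n_regions = None
    for g, params_list in results_by_group.items():
        if len(params_list) < 2:
            raise InsufficientReplicatesError(
                f"group {g!r} has {len(params_list)} parameter sets; need >= 2")
        arr = np.array([getattr(p, which) for p in params_list])
        if n_regions is None:
            n_regions = arr.shape[1]
        elif arr.shape[1] != n_regions:
            raise AlignmentError("groups have different region counts")
        mats[g] = arr
    rows = []
    for g1, g2 in combinations(groups, 2):
        for region in range(n_regions):
            x, y = mats[g1][:, region], mats[g2][:, region]
            try:
                t, df, p = welch_t_test(x, y)
            except DegenerateInputError:
                t, df, p = 0.0, float(x.size + y.size - 2), 1.0
            rows.append({
                "region": region, "pair": f"{g1}-vs-{g2}", "which": which,
                "mean_1": x.mean(), "sd_1": x.std(ddof=1),
                "mean_2": y.mean(), "sd_2": y.std(ddof=1),
                "t": t, "df": df, "p": p,
            })
    out = pd.DataFrame(rows)
    adjusted, reject = bh_fdr(out["p"].to_numpy(), q)
    out["p_adj"] = adjusted
    out["significant"] = reject
    out["q"] = q
    return out


def omnibus_region_flags(comparison: pd.DataFrame) -> pd.Series:
    """Per-region flag: significant in any pairwise contrast."""
    return comparison.groupby("region")["significant"].any()


def nodal_metric_parameter_association(nodal_metrics, params, which: str = "w",
                                       metric_name: str = "metric",
                                       group: str | None = None) -> CorrelationResult:
    """Across-region correlation between a nodal metric and a parameter vector."""
    vec = np.asarray(getattr(params, which) if hasattr(params, which) else params,
                     dtype=float)
    metric = np.asarray(nodal_metrics, dtype=float)
    if metric.size != vec.size:
        raise AlignmentError("metric and parameter vectors have different lengths")
    return correlate(metric, vec, x_name=metric_name, y_name=which, group=group)


def compare_metric_grids(values_by_group: dict, q: float = 0.05) -> pd.DataFrame:
    """Welch tests of a global graph metric between cohorts per sparsity level.

    ``values_by_group`` maps group -> DataFrame with columns ``sparsity`` and
    ``value`` (one row per subject per level).  BH-FDR is applied across
    levels within each pairwise contrast.
    """
    groups = list(values_by_group)
    rows = []
    for g1, g2 in combinations(groups, 2):
        d1, d2 = values_by_group[g1], values_by_group[g2]
        levels = sorted(set(d1["sparsity"]) & set(d2["sparsity"]))
        pvals = []
        for s in levels:
            x = d1.loc[d1["sparsity"] == s, "value"].to_numpy(float)
            y = d2.loc[d2["sparsity"] == s, "value"].to_numpy(float)
            t, df, p = welch_t_test(x, y)
            pvals.append(p)
            rows.append({"pair": f"{g1}-vs-{g2}", "sparsity": s,
                         "t": t, "df": df, "p": p})
        adj, rej = bh_fdr(np.array(pvals), q)
        for i in range(len(levels)):
            rows[-len(levels) + i]["p_adj"] = adj[i]
            rows[-len(levels) + i]["significant"] = bool(rej[i])
    return pd.DataFrame(rows)
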