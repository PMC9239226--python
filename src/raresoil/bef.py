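"""BEF regressions, diversity-function correlations, the
supporting-phylotype screen and support-breadth comparisons.

A "supporting phylotype" for a function is one whose per-sample relative
abundance is positively Spearman-correlated with that function at raw
P < 0.01 (no multiplicity correction here, by design).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from raresoil.core import CommunityTable, relative_abundance
from raresoil.partition import AbundanceClasses

logger = logging.getLogger(__name__)


@dataclass
class RegressionResult:
    """Simple OLS fit of y on x."""

    slope: float
    standardized_slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def bef_regression(diversity, mf) -> RegressionResult:
    """OLS of multifunctionality on a diversity measure.

    The standardized slope is the slope after z-scoring both variables,
    i.e. the Pearson correlation for a simple regression.
    """
    x = np.asarray(diversity, dtype=float)
    y = np.asarray(mf, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("need equal-length vectors with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if x.std() == 0:
        raise ValueError("zero-variance predictor")
    fit = stats.linregress(x, y)
    std_slope = fit.slope * x.std(ddof=1) / y.std(ddof=1) if y.std() > 0 else 0.0
    return RegressionResult(
        slope=float(fit.slope),
        standardized_slope=float(std_slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue ** 2),
        p_value=float(fit.pvalue),
        n=x.size,
    )


def _spearman_matrix(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-pairwise Spearman rho and two-sided p between matrices.

    Rank-transforms columns (average ranks for ties) then computes Pearson
    correlations; p-values use the t approximation, matching
    :func:`scipy.stats.spearmanr`.  Constant columns yield NaN.
    """
    n = a.shape[0]
    ra = np.apply_along_axis(stats.rankdata, 0, a)
    rb = np.apply_along_axis(stats.rankdata, 0, b)
    ra_c = ra - ra.mean(axis=0)
    rb_c = rb - rb.mean(axis=0)
    sa = np.sqrt((ra_c ** 2).sum(axis=0))
    sb = np.sqrt((rb_c ** 2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ra_c.T @ rb_c) / np.outer(sa, sb)
    rho = np.clip(rho, -1.0, 1.0)
    rho[np.outer(sa == 0, np.ones(sb.size, bool))] = np.nan
    rho[np.outer(np.ones(sa.size, bool), sb == 0)] = np.nan
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isnan(rho)] = np.nan
    p[np.abs(rho) == 1.0] = 0.0
    return rho, p


def diversity_function_correlations(
    diversities: dict[str, np.ndarray], functions: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Spearman rho/p for every (diversity measure, function) pair.

    Returns a long-format frame with a significance mask at ``alpha``;
    undefined (constant-input) pairs are excluded from the mask.
    """
    names = list(diversities)
    a = np.column_stack([np.asarray(diversities[k], float) for k in names])
    b = functions.to_numpy(float)
    if a.shape[0] != b.shape[0]:
        raise ValueError("diversity vectors and function table have mismatched samples")
    rho, p = _spearman_matrix(a, b)
    records = []
    for i, d in enumerate(names):
        for j, f in enumerate(functions.columns):
            records.append(
                {
                    "diversity": d,
                    "function": f,
                    "rho": rho[i, j],
                    "p": p[i, j],
                    "significant": bool(p[i, j] < alpha) if np.isfinite(p[i, j]) else False,
                }
            )
    return pd.DataFrame.from_records(records)


@dataclass
class SupportTable:
    """Phylotype x function support screen results."""

    phylotype_ids: list[str]
    group: list[str]
    label: list[str]
    function_ids: list[str]
    rho: np.ndarray
    p: np.ndarray
    supports: np.ndarray
    n_functions_supported: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(
            self.supports.astype(int), index=self.phylotype_ids, columns=self.function_ids
        )
        df.insert(0, "group", self.group)
        df.insert(1, "label", self.label)
        df["n_functions_supported"] = self.n_functions_supported
        return df


def supporting_phylotypes(
    tables: dict[str, CommunityTable] | CommunityTable,
    classes: dict[str, AbundanceClasses] | AbundanceClasses,
    functions: pd.DataFrame,
    p_cut: float = 0.01,
    prevalence_min: float = 0.10,
) -> SupportTable:
    """Screen phylotypes for significant positive correlation with functions.

    Correlations are Spearman on per-sample relative abundance (within each
    group's table) versus each standardized function.  A phylotype supports
    a function when rho > 0 and p < ``p_cut``.  Phylotypes present in fewer
    than ``prevalence_min`` of samples are excluded up front.
    """
    if isinstance(tables, CommunityTable):
        tables = {tables.group: tables}
        classes = {tables[next(iter(tables))].group: classes}
    fvals = functions.to_numpy(float)
    ids: list[str] = []
    grp: list[str] = []
    lab: list[str] = []
    blocks = []
    for g, table in tables.items():
        if fvals.shape[0] != table.n_samples:
            raise ValueError("community table and function table have mismatched samples")
        cls = classes[g]
        label_of = dict(zip(cls.phylotype_ids, cls.label))
        rel = relative_abundance(table, "per_sample")
        prevalence = (table.counts > 0).mean(axis=0)
        keep = prevalence >= prevalence_min
        if not keep.any():
            continue
        kept_ids = [p for p, k in zip(table.phylotype_ids, keep) if k]
        logger.info(
            "%s: %d/%d phylotypes pass prevalence >= %.0f%%",
            g, len(kept_ids), table.n_phylotypes, 100 * prevalence_min,
        )
        ids += kept_ids
        grp += [g] * len(kept_ids)
        lab += [label_of[p] for p in kept_ids]
        blocks.append(rel[:, keep])
    if not ids:
        raise ValueError("no phylotype passes the prevalence filter")
    abund = np.hstack(blocks)
    rho, p = _spearman_matrix(abund, fvals)
    with np.errstate(invalid="ignore"):
        supports = (rho > 0) & (p < p_cut)
    return SupportTable(
        phylotype_ids=ids,
        group=grp,
        label=lab,
        function_ids=list(functions.columns),
        rho=rho,
        p=p,
        supports=supports,
        n_functions_supported=supports.sum(axis=1),
    )


def support_summary(st: SupportTable) -> dict:
    """Aggregate the support screen.

    Returns per-function rare/abundant supporter shares, per-service-group
    pooled shares (when the caller passes a service map via
    ``per_function['service_group']`` externally this is done there), the
    per-subcommunity fraction of member phylotypes supporting >= 1 function,
    and the regression of per-function supporter proportion on the mean
    number of functions its supporters support.
    """
    if len(st.phylotype_ids) == 0:
        raise ValueError("empty support table")
    labels = np.asarray(st.label)
    n_phy = len(st.phylotype_ids)
    per_function = []
    for j, f in enumerate(st.function_ids):
        supp = st.supports[:, j]
        n_supp = int(supp.sum())
        rec = {
            "function": f,
            "n_supporting": n_supp,
            "proportion_supporting": n_supp / n_phy,
            "empty": n_supp == 0,
        }
        for which in ("rare", "abundant", "intermediate"):
            rec[f"share_{which}"] = (
                float((labels[supp] == which).mean()) if n_supp else 0.0
            )
        rec["mean_breadth_of_supporters"] = (
            float(st.n_functions_supported[supp].mean()) if n_supp else 0.0
        )
        per_function.append(rec)
    per_function = pd.DataFrame(per_function)

    per_subcommunity = {}
    for which in ("rare", "abundant", "intermediate"):
        members = labels == which
        per_subcommunity[which] = {
            "n_members": int(members.sum()),
            "fraction_supporting_any": (
                float((st.n_functions_supported[members] > 0).mean())
                if members.any()
                else 0.0
            ),
        }

    nonempty = per_function[~per_function["empty"]]
    trend = None
    if len(nonempty) >= 3 and nonempty["mean_breadth_of_supporters"].std() > 0:
        trend = bef_regression(
            nonempty["mean_breadth_of_supporters"].to_numpy(),
            nonempty["proportion_supporting"].to_numpy(),
        )
    return {
        "per_function": per_function,
        "per_subcommunity": per_subcommunity,
        "breadth_trend": trend,
    }


def rank_sum_test(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum z-test with tie correction.

    Returns ``(z, p)`` using the normal approximation without continuity
    correction; equivalent to the asymptotic Mann-Whitney U test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    w = ranks[:n1].sum()
    n = n1 + n2
    mu = n1 * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum()) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var == 0:
        return 0.0, 1.0
    z = (w - mu) / np.sqrt(var)
    return float(z), float(2.0 * stats.norm.sf(abs(z)))


def compare_support_breadth(st: SupportTable) -> dict:
    """Wilcoxon rank-sum of supporting-phylotype breadth, abundant vs rare."""
    labels = np.asarray(st.label)
    supp_any = st.n_functions_supported > 0
    abundant = st.n_functions_supported[(labels == "abundant") & supp_any]
    rare = st.n_functions_supported[(labels == "rare") & supp_any]
    if abundant.size == 0 or rare.size == 0:
        raise ValueError("need at least one supporting phylotype in each class")
    z, p = rank_sum_test(abundant, rare)
    return {
        "mean_abundant": float(abundant.mean()),
        "mean_rare": float(rare.mean()),
        "n_abundant": int(abundant.size),
        "n_rare": int(rare.size),
        "z": z,
        "p": p,
    }
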