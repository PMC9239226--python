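"""Null-model community-assembly analysis: the stochasticity ratio (ST).

Observed pairwise similarity is C = 1 - Bray-Curtis; the null expectation E
is the mean similarity over randomized communities that keep every sample's
observed richness, draw phylotype membership proportionally to occurrence
frequency across samples, and fill abundances proportionally to the
regional relative-abundance pool rescaled to the sample's total.

Per pair, when C >= E determinism drives similarity and st = E/C; when
C < E determinism drives dissimilarity and st = (1-E)/(1-C).  Both branches
lie in [0, 1]; the unbounded plain ratio E/C is also reported.  ST is the
mean pairwise st over the sample set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from raresoil.core import CommunityTable, relative_abundance
from raresoil.partition import AbundanceClasses, subset_community


def _as_matrix(table) -> np.ndarray:
    if isinstance(table, CommunityTable):
        return table.counts.astype(float)
    return np.asarray(table, dtype=float)


def bray_curtis_matrix(table) -> np.ndarray:
    """Abundance-weighted Bray-Curtis dissimilarity between all sample pairs.

    BC(i, j) = sum_k |x_ik - x_jk| / sum_k (x_ik + x_jk).
    """
    x = _as_matrix(table)
    if x.shape[0] < 2:
        raise ValueError("need >= 2 samples")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample rows are not allowed")
    return squareform(pdist(x, metric="braycurtis"))


def null_model_randomize(table, n_null: int, seed: int):
    """Yield ``n_null`` randomized community matrices (floats).

    Each null community preserves per-sample richness and total abundance;
    membership is drawn without replacement with probability proportional
    to occurrence frequency (Gumbel top-k weighted sampling); member
    abundances are proportional to the dataset-level pool.
    """
    if n_null < 1:
        raise ValueError("n_null must be >= 1")
    x = _as_matrix(table)
    n, m = x.shape
    rng = np.random.default_rng(seed)
    occ = (x > 0).sum(axis=0).astype(float)
    regional = x.sum(axis=0)
    regional = regional / regional.sum()
    richness = (x > 0).sum(axis=1)
    totals = x.sum(axis=1)
    with np.errstate(divide="ignore"):
        log_occ = np.log(occ)  # -inf excludes never-observed phylotypes
    for _ in range(n_null):
        gumbel = rng.gumbel(size=(n, m))
        keys = log_occ[None, :] + gumbel
        order = np.argsort(-keys, axis=1)
        null = np.zeros((n, m))
        for i in range(n):
            if richness[i] == 0:
                continue
            members = order[i, : richness[i]]
            ab = regional[members]
            s = ab.sum()
            if s == 0:  # all drawn members have zero pool mass; spread evenly
                ab = np.full(members.size, 1.0 / members.size)
            else:
                ab = ab / s
            null[i, members] = ab * totals[i]
        yield null


@dataclass
class StochasticityResult:
    """Observed/expected pairwise similarities and the aggregate ST."""

    sample_ids: list[str]
    observed_similarity: np.ndarray     # condensed C
    expected_similarity: np.ndarray     # condensed E (mean over nulls)
    pairwise_st: np.ndarray             # condensed, two-branch, in [0,1]
    pairwise_ratio: np.ndarray          # plain E/C, unbounded
    st: float
    n_null: int
    seed: int

    def similarity_matrices(self) -> tuple[np.ndarray, np.ndarray]:
        c = squareform(self.observed_similarity)
        e = squareform(self.expected_similarity)
        np.fill_diagonal(c, 1.0)
        np.fill_diagonal(e, 1.0)
        return c, e


def _pairwise_st(c: np.ndarray, e: np.ndarray) -> np.ndarray:
    st = np.empty_like(c)
    hi = c >= e
    with np.errstate(divide="ignore", invalid="ignore"):
        st[hi] = np.where(c[hi] > 0, e[hi] / np.where(c[hi] > 0, c[hi], 1.0), 1.0)
        st[~hi] = (1.0 - e[~hi]) / (1.0 - c[~hi])
    return np.clip(st, 0.0, 1.0)


def stochasticity_ratio(table, n_null: int = 1000, seed: int = 0) -> StochasticityResult:
    """Compute the stochasticity ratio for a sample set."""
    x = _as_matrix(table)
    if x.shape[0] < 3:
        raise ValueError("need >= 3 samples")
    if (x.sum(axis=1) == 0).any():
        raise ValueError("all-zero sample rows are not allowed")
    c = 1.0 - pdist(x, metric="braycurtis")
    e_acc = np.zeros_like(c)
    for null in null_model_randomize(x, n_null, seed):
        e_acc += 1.0 - pdist(null, metric="braycurtis")
    e = e_acc / n_null
    pair_st = _pairwise_st(c, e)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(c > 0, e / np.where(c > 0, c, 1.0), np.inf)
    sample_ids = (
        list(table.sample_ids)
        if isinstance(table, CommunityTable)
        else [f"row{i}" for i in range(x.shape[0])]
    )
    return StochasticityResult(
        sample_ids=sample_ids,
        observed_similarity=c,
        expected_similarity=e,
        pairwise_st=pair_st,
        pairwise_ratio=ratio,
        st=float(pair_st.mean()),
        n_null=n_null,
        seed=seed,
    )


def pool_relative_abundance(
    tables: dict[str, CommunityTable],
    classes: dict[str, AbundanceClasses] | None = None,
    label: str | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Concatenate per-group per-sample relative abundances (optionally for
    one abundance class) into a single samples x phylotypes float matrix."""
    blocks, ids = [], []
    sample_ref = None
    for g, table in tables.items():
        if sample_ref is None:
            sample_ref = table.sample_ids
        elif table.sample_ids != sample_ref:
            raise ValueError("community tables have mismatched samples")
        if classes is not None and label is not None:
            table = subset_community(table, classes[g], label)
        if table.n_phylotypes == 0:
            continue
        keep_rows = table.counts.sum(axis=1) > 0
        rel = np.zeros(table.counts.shape, dtype=float)
        rel[keep_rows] = table.counts[keep_rows] / table.counts[keep_rows].sum(
            axis=1, keepdims=True
        )
        blocks.append(rel)
        ids += list(table.phylotype_ids)
    if not blocks:
        raise ValueError("no phylotypes to pool")
    return np.hstack(blocks), ids


def st_by_category(
    table,
    ordering,
    n_groups: int = 19,
    n_null: int = 1000,
    seed: int = 0,
    degree: int = 2,
) -> dict:
    """ST within equal-size rank bins of an ordering variable, plus trend.

    Samples are ranked by ``ordering`` (stable), split into ``n_groups``
    contiguous bins (remainder samples go to the last bins), ST is computed
    within each bin, and a polynomial of the requested degree is fitted to
    ST versus the bin-mean ordering value.
    """
    from raresoil.windows import polynomial_trend  # local: avoids cycle

    x = _as_matrix(table)
    ordering = np.asarray(ordering, dtype=float)
    n = x.shape[0]
    if ordering.shape != (n,):
        raise ValueError("ordering length mismatch")
    if n_groups < 2:
        raise ValueError("n_groups must be >= 2")
    base, rem = divmod(n, n_groups)
    sizes = [base] * (n_groups - rem) + [base + 1] * rem
    if min(sizes) < 3:
        raise ValueError("bins of size < 3; reduce n_groups")
    order = np.argsort(ordering, kind="stable")
    rows = []
    start = 0
    seeds = np.random.SeedSequence(seed).spawn(n_groups)
    for b, size in enumerate(sizes):
        idx = order[start : start + size]
        start += size
        res = stochasticity_ratio(
            x[idx], n_null=n_null, seed=int(seeds[b].generate_state(1)[0])
        )
        rows.append(
            {
                "bin": b,
                "n": size,
                "ordering_mean": float(ordering[idx].mean()),
                "st": res.st,
            }
        )
    df = pd.DataFrame(rows)
    trend = None
    degenerate = df["ordering_mean"].std() == 0
    if not degenerate:
        trend = polynomial_trend(
            df["ordering_mean"].to_numpy(), df["st"].to_numpy(), degree=degree
        )
    return {"bins": df, "trend": trend, "degenerate_ordering": bool(degenerate)}
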