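"""Richness, min-max standardization and multidiversity.

Richness counts phylotypes with positive counts.  Multidiversity is the
per-sample mean of the four organism groups' standardized richness, with
standardization performed separately within each subcommunity x group
combination.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from raresoil.core import GROUPS, CommunityTable, StandardizedVector


def richness(table: CommunityTable) -> np.ndarray:
    """Number of phylotypes with count > 0, per sample."""
    return (table.counts > 0).sum(axis=1)


def minmax_standardize(x) -> StandardizedVector:
    """STD = (X - X_min) / (X_max - X_min); maps the range onto [0, 1]."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise ValueError("minmax_standardize requires a 1-D vector of length >= 2")
    lo, hi = float(x.min()), float(x.max())
    if hi == lo:
        raise ValueError(
            "cannot min-max standardize a constant vector (X_max == X_min); "
            "the variable carries no between-sample variation"
        )
    return StandardizedVector(raw=x, minimum=lo, maximum=hi, std=(x - lo) / (hi - lo))


def multidiversity(per_group_richness: dict[str, np.ndarray] | list) -> np.ndarray:
    """Mean of the four groups' min-max standardized richness, per sample."""
    if isinstance(per_group_richness, dict):
        vectors = [np.asarray(per_group_richness[g]) for g in sorted(per_group_richness)]
    else:
        vectors = [np.asarray(v) for v in per_group_richness]
    if len(vectors) != 4:
        raise ValueError("multidiversity expects exactly four group richness vectors")
    n = vectors[0].size
    if any(v.shape != (n,) for v in vectors):
        raise ValueError("group richness vectors have mismatched lengths")
    return np.mean([minmax_standardize(v).std for v in vectors], axis=0)


@dataclass
class DiversityTable:
    """Per-sample richness and multidiversity for each subcommunity."""

    sample_ids: list[str]
    richness: pd.DataFrame          # columns: (group, subcommunity)
    standardized: pd.DataFrame      # same layout, min-max standardized
    multidiversity: pd.DataFrame    # columns: subcommunity

    def to_dataframe(self) -> pd.DataFrame:
        rich = self.richness.copy()
        rich.columns = [f"richness_{g}_{s}" for g, s in rich.columns]
        std = self.standardized.copy()
        std.columns = [f"std_{g}_{s}" for g, s in std.columns]
        md = self.multidiversity.copy()
        md.columns = [f"multidiversity_{s}" for s in md.columns]
        return pd.concat([rich, std, md], axis=1)


def diversity_table(
    subcommunities: dict[str, dict[str, CommunityTable]]
) -> DiversityTable:
    """Build the full diversity table.

    ``subcommunities`` maps subcommunity label (e.g. ``rare``, ``abundant``,
    ``whole``) -> group -> community table; all tables must share sample
    order.
    """
    first = next(iter(next(iter(subcommunities.values())).values()))
    sample_ids = list(first.sample_ids)
    rich_cols, std_cols, md_cols = {}, {}, {}
    for sub, tables in subcommunities.items():
        per_group = {}
        for g in GROUPS:
            t = tables[g]
            if t.sample_ids != sample_ids:
                raise ValueError("subcommunity tables have mismatched samples")
            r = richness(t)
            rich_cols[(g, sub)] = r
            per_group[g] = r
            std_cols[(g, sub)] = minmax_standardize(r).std
        md_cols[sub] = np.mean([std_cols[(g, sub)] for g in GROUPS], axis=0)
    return DiversityTable(
        sample_ids=sample_ids,
        richness=pd.DataFrame(rich_cols, index=sample_ids),
        standardized=pd.DataFrame(std_cols, index=sample_ids),
        multidiversity=pd.DataFrame(md_cols, index=sample_ids),
    )
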