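"""Abundant / intermediate / rare classification of phylotypes.

Classification uses dataset-level relative abundance within one organism
group (phylotype total over the group's grand total), computed after
rarefaction.  Thresholds are strict: boundary values are intermediate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from raresoil.core import CommunityTable, relative_abundance

logger = logging.getLogger(__name__)

LABELS = ("abundant", "intermediate", "rare")


@dataclass(frozen=True)
class ThresholdScheme:
    """Abundance-class thresholds (fractions of total sequences)."""

    abundant_min: float = 0.005
    rare_max: float = 0.0005
    name: str = "default"

    def __post_init__(self) -> None:
        if not (0.0 < self.rare_max < self.abundant_min < 1.0):
            raise ValueError(
                "threshold scheme requires 0 < rare_max < abundant_min < 1, "
                f"got rare_max={self.rare_max}, abundant_min={self.abundant_min}"
            )


DEFAULT_SCHEME = ThresholdScheme()


def alternative_schemes() -> list[ThresholdScheme]:
    """The three published threshold schemes, default first."""
    return [
        ThresholdScheme(0.005, 0.0005, "default"),
        ThresholdScheme(0.01, 0.001, "loose"),
        ThresholdScheme(0.001, 0.0001, "strict"),
    ]


@dataclass
class AbundanceClasses:
    """Per-phylotype abundance-class labels under one threshold scheme."""

    phylotype_ids: list[str]
    dataset_relabund: np.ndarray
    label: list[str]
    scheme: ThresholdScheme
    group: str

    def ids_with_label(self, label: str) -> list[str]:
        if label not in LABELS:
            raise ValueError(f"unknown abundance label {label!r}")
        return [p for p, l in zip(self.phylotype_ids, self.label) if l == label]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "phylotype_id": self.phylotype_ids,
                "group": self.group,
                "dataset_relabund": self.dataset_relabund,
                "label": self.label,
                "scheme": self.scheme.name,
            }
        )


def classify_phylotypes(
    table: CommunityTable, scheme: ThresholdScheme = DEFAULT_SCHEME
) -> AbundanceClasses:
    """Label each phylotype abundant (> abundant_min), rare (< rare_max) or
    intermediate (everything else, boundaries included)."""
    rel = relative_abundance(table, level="dataset")
    label = np.where(
        rel > scheme.abundant_min,
        "abundant",
        np.where(rel < scheme.rare_max, "rare", "intermediate"),
    )
    return AbundanceClasses(
        phylotype_ids=list(table.phylotype_ids),
        dataset_relabund=rel,
        label=[str(l) for l in label],
        scheme=scheme,
        group=table.group,
    )


def subset_community(
    table: CommunityTable, classes: AbundanceClasses, label: str
) -> CommunityTable:
    """Columns of ``table`` carrying the requested abundance label."""
    if label not in LABELS:
        raise ValueError(f"unknown abundance label {label!r}")
    if classes.phylotype_ids != table.phylotype_ids:
        raise ValueError("classes were not derived from this table")
    keep = np.array([l == label for l in classes.label])
    if not keep.any():
        logger.warning(
            "no %s phylotypes in %s table under scheme %s",
            label, table.group, classes.scheme.name,
        )
    return CommunityTable(
        sample_ids=list(table.sample_ids),
        phylotype_ids=[p for p, k in zip(table.phylotype_ids, keep) if k],
        counts=table.counts[:, keep].copy(),
        group=table.group,
    )


def write_classification(classes_by_group: dict[str, AbundanceClasses], path) -> None:
    pd.concat([c.to_dataframe() for c in classes_by_group.values()]).to_csv(
        path, sep="\t", index=False
    )
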