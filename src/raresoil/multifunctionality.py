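"""Ecosystem-function standardization and multifunctionality indices.

Three per-sample composites of the 16 standardized functions are computed:
the averaging index (plain row mean), the service-weighted index (mean of
the four within-service means, so each ecosystem service contributes
equally) and the multidimensional index (first principal-coordinate axis of
the Euclidean distance matrix, oriented to correlate positively with the
averaging index).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from raresoil.core import SERVICE_GROUPS, FunctionTable


def standardize_functions(ft: FunctionTable) -> pd.DataFrame:
    """Min-max standardize every function to [0, 1].

    Functions annotated with sign -1 ("less is better") are multiplied by
    -1 before standardization, so high standardized scores always mean a
    better-functioning sample.
    """
    out = {}
    for j, f in enumerate(ft.function_ids):
        x = ft.values[:, j] * ft.sign[f]
        lo, hi = x.min(), x.max()
        if hi == lo:
            raise ValueError(f"function {f!r} is constant; cannot standardize")
        out[f] = (x - lo) / (hi - lo)
    return pd.DataFrame(out, index=ft.sample_ids)


def averaging_index(std: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Arithmetic mean of the standardized functions, per sample."""
    return np.asarray(std, dtype=float).mean(axis=1)


def weighted_index(std: pd.DataFrame, groups: dict[str, str]) -> np.ndarray:
    """Two-stage mean: within each service group, then across the four groups."""
    by_group: dict[str, list[str]] = {}
    for f in std.columns:
        if f not in groups:
            raise ValueError(f"function {f!r} has no service group")
        by_group.setdefault(groups[f], []).append(f)
    present = [g for g in SERVICE_GROUPS if g in by_group]
    missing = [g for g in SERVICE_GROUPS if g not in by_group]
    if missing:
        raise ValueError(f"empty service groups: {', '.join(missing)}")
    group_means = np.column_stack(
        [std[by_group[g]].to_numpy(float).mean(axis=1) for g in present]
    )
    return group_means.mean(axis=1)


def multidimensional_index(
    std: pd.DataFrame | np.ndarray, n_axes: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Classical-scaling (principal coordinate) axis scores.

    Decomposes the doubly-centered squared Euclidean distance matrix of the
    standardized function profiles.  Returns ``(scores, eigenvalues)`` where
    ``scores`` has one column per requested axis; axis 1 is sign-flipped if
    needed so its Pearson correlation with the averaging index is >= 0.
    """
    x = np.asarray(std, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValueError("multidimensional index requires >= 3 samples")
    d = squareform(pdist(x, metric="euclidean"))
    if np.allclose(d, 0.0):
        raise ValueError("all samples have identical function profiles")
    d2 = d ** 2
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ d2 @ j
    eigval, eigvec = np.linalg.eigh(b)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    pos = np.clip(eigval, 0.0, None)
    scores = eigvec[:, :n_axes] * np.sqrt(pos[:n_axes])
    avg = averaging_index(x)
    if np.corrcoef(scores[:, 0], avg)[0, 1] < 0:
        scores[:, 0] = -scores[:, 0]
    return scores, eigval


@dataclass
class MultifunctionalityResult:
    """All three multifunctionality indices for one function table."""

    sample_ids: list[str]
    standardized: pd.DataFrame
    averaging: np.ndarray
    weighted: np.ndarray
    multidimensional: np.ndarray
    eigenvalues: np.ndarray

    def index(self, method: str) -> np.ndarray:
        if method not in ("averaging", "weighted", "multidimensional"):
            raise ValueError(f"unknown multifunctionality method {method!r}")
        return getattr(self, method)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "averaging": self.averaging,
                "weighted": self.weighted,
                "multidimensional": self.multidimensional,
            },
            index=self.sample_ids,
        )


def compute_multifunctionality(ft: FunctionTable) -> MultifunctionalityResult:
    std = standardize_functions(ft)
    scores, eigval = multidimensional_index(std)
    return MultifunctionalityResult(
        sample_ids=list(ft.sample_ids),
        standardized=std,
        averaging=averaging_index(std),
        weighted=weighted_index(std, ft.service_group),
        multidimensional=scores[:, 0],
        eigenvalues=eigval,
    )
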