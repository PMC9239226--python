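"""Moving-window BEF slopes and stochasticity along the latitude gradient.

Samples are sorted ascending by latitude (stable, ties broken by sample
id); windows of a fixed size advance one sample at a time, giving
n - w + 1 windows.  Within each window the standardized OLS slope of
multifunctionality on diversity and the window's stochasticity ratio are
computed; a second-order polynomial relates slope to ST across windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from raresoil.assembly import stochasticity_ratio
from raresoil.bef import bef_regression
from raresoil.core import CommunityTable, SampleMetadata


@dataclass
class WindowSet:
    """Contiguous sample windows along the sorted latitude gradient."""

    window_size: int
    sample_order: list[str]         # latitude-ascending sample ids
    windows: list[range]            # index ranges into sample_order

    @property
    def n_windows(self) -> int:
        return len(self.windows)


def make_windows(metadata: SampleMetadata, window_size: int) -> WindowSet:
    """Latitude-sorted sliding windows advancing by one sample."""
    n = len(metadata.sample_ids)
    if not (3 <= window_size <= n):
        raise ValueError(f"window_size must be in [3, {n}], got {window_size}")
    order = sorted(
        range(n), key=lambda i: (metadata.latitude[i], metadata.sample_ids[i])
    )
    sample_order = [metadata.sample_ids[i] for i in order]
    windows = [range(s, s + window_size) for s in range(n - window_size + 1)]
    return WindowSet(window_size=window_size, sample_order=sample_order, windows=windows)


def polynomial_trend(x, y, degree: int = 2) -> dict:
    """OLS fit of y = b0 + b1 x + ... + b_d x^d with coefficient p-values."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size != y.size or x.size < degree + 2:
        raise ValueError(f"need >= {degree + 2} points for a degree-{degree} fit")
    if x.std() == 0:
        raise ValueError("constant x; polynomial fit undefined")
    design = np.column_stack([x ** k for k in range(degree + 1)])
    fit = sm.OLS(y, design).fit()
    return {
        "coefficients": np.asarray(fit.params),
        "p_values": np.asarray(fit.pvalues),
        "r_squared": float(fit.rsquared),
        "f_pvalue": float(fit.f_pvalue) if np.isfinite(fit.f_pvalue) else float("nan"),
        "degree": degree,
        "n": int(x.size),
    }


def window_bef_st(
    ws: WindowSet,
    diversity,
    mf,
    table,
    n_null: int = 1000,
    seed: int = 0,
    trend_degree: int = 2,
) -> dict:
    """Per-window standardized BEF slope and ST, plus their polynomial trend.

    ``diversity``, ``mf`` and ``table`` rows must follow ``ws.sample_order``.
    Windows with zero diversity variance are flagged and excluded from the
    trend; the trend needs >= 10 valid windows.
    """
    diversity = np.asarray(diversity, float)
    mf = np.asarray(mf, float)
    x = table.counts.astype(float) if isinstance(table, CommunityTable) else np.asarray(table, float)
    n = len(ws.sample_order)
    if diversity.shape != (n,) or mf.shape != (n,) or x.shape[0] != n:
        raise ValueError("inputs not aligned with the window set")
    seeds = np.random.SeedSequence(seed).spawn(ws.n_windows)
    rows = []
    for k, win in enumerate(ws.windows):
        idx = np.asarray(win)
        d, m = diversity[idx], mf[idx]
        valid = d.std() > 0 and m.std() > 0
        if valid:
            fit = bef_regression(d, m)
            slope, std_slope, pval = fit.slope, fit.standardized_slope, fit.p_value
        else:
            slope = std_slope = pval = float("nan")
        st = stochasticity_ratio(
            x[idx], n_null=n_null, seed=int(seeds[k].generate_state(1)[0])
        ).st
        rows.append(
            {
                "window": k,
                "start": int(idx[0]),
                "stop": int(idx[-1]) + 1,
                "slope": slope,
                "standardized_slope": std_slope,
                "slope_p": pval,
                "st": st,
                "valid": bool(valid),
            }
        )
    df = pd.DataFrame(rows)
    ok = df[df["valid"]]
    trend = None
    if len(ok) >= 10 and ok["st"].std() > 0 and ok["standardized_slope"].std() > 0:
        trend = polynomial_trend(
            ok["st"].to_numpy(), ok["standardized_slope"].to_numpy(), degree=trend_degree
        )
    return {"windows": df, "trend": trend, "window_size": ws.window_size}
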