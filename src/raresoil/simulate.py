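"""Synthetic dataset generator emulating the study design.

Generates four rarefied community tables (lognormal regional abundance
pools, latitude-dependent environmental filtering, multinomial sampling at
fixed depth), a 16-function table responding linearly to the realized
rare/abundant multidiversity, and a sample metadata table along a latitude
gradient.  The generating parameters and realized latent drivers are
recorded so downstream parameter recovery can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from raresoil.core import (
    DEFAULT_DEPTHS,
    DEFAULT_FUNCTION_SCHEMA,
    GROUPS,
    CommunityTable,
    FunctionTable,
    SampleMetadata,
    write_community_table,
    write_function_table,
    write_metadata,
)
from raresoil.diversity import richness
from raresoil.partition import DEFAULT_SCHEME, classify_phylotypes, subset_community

LAT_RANGE = (18.30, 48.35)

DEFAULT_N_OTUS = {"archaea": 1500, "bacteria": 3000, "fungi": 2000, "protist": 1500}

#: (mean, sd) of per-OTU log regional abundance; heavy right skew so most
#: OTUs sit below the rare threshold and only a handful above the abundant
#: threshold.
DEFAULT_LOGNORMAL = {
    "archaea": (0.0, 5.0),
    "bacteria": (0.0, 5.0),
    "fungi": (0.0, 5.0),
    "protist": (0.0, 5.0),
}


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study-design emulator.

    ``beta_rare`` / ``beta_abundant`` couple the realized rare/abundant
    multidiversity to the function means; ``beta_env`` scales the sharpness
    of latitude-based environmental filtering of community composition
    (0 = neutral / stochastic assembly); ``beta_env_function`` adds a direct
    latitude effect on the functions (0 by default, keeping the null regime
    clean).
    """

    n_samples: int = 228
    group_depths: dict = field(default_factory=lambda: dict(DEFAULT_DEPTHS))
    n_otus: dict = field(default_factory=lambda: dict(DEFAULT_N_OTUS))
    lognormal_shape: dict = field(default_factory=lambda: dict(DEFAULT_LOGNORMAL))
    niche_width: float = 3.0
    compositional_noise_sd: float = 1.0
    dropout: float = 0.10
    generalist_min: float = 0.005
    beta_rare: float = 0.8
    beta_abundant: float = 0.0
    beta_env: float = 1.0
    beta_env_function: float = 0.0
    noise_sd: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 4:
            raise ValueError("n_samples must be >= 4")
        for g in GROUPS:
            for d, what in (
                (self.group_depths, "group_depths"),
                (self.n_otus, "n_otus"),
                (self.lognormal_shape, "lognormal_shape"),
            ):
                if g not in d:
                    raise ValueError(f"{what} missing group {g!r}")
            if self.group_depths[g] <= 0 or self.n_otus[g] <= 0:
                raise ValueError(f"depth and OTU count must be positive for {g!r}")
        for name in ("beta_rare", "beta_abundant", "beta_env", "beta_env_function"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")
        if self.noise_sd < 0 or self.niche_width <= 0:
            raise ValueError("noise_sd must be >= 0 and niche_width > 0")
        if self.compositional_noise_sd < 0:
            raise ValueError("compositional_noise_sd must be >= 0")
        if not (0 <= self.dropout < 1):
            raise ValueError("dropout must be in [0, 1)")
        if not (0 < self.generalist_min < 1):
            raise ValueError("generalist_min must be a fraction in (0, 1)")


@dataclass
class SyntheticDataset:
    """One realized dataset plus the ground truth that generated it."""

    tables: dict[str, CommunityTable]
    functions: FunctionTable
    metadata: SampleMetadata
    truth: dict


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        return np.zeros_like(x, dtype=float)
    return (x - x.mean()) / sd


def _safe_minmax(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        return np.zeros_like(x, dtype=float)
    return (x - lo) / (hi - lo)


def _simulate_group(
    rng: np.random.Generator,
    group: str,
    lat: np.ndarray,
    config: SimulationConfig,
) -> CommunityTable:
    n, m = config.n_samples, config.n_otus[group]
    mu, sd = config.lognormal_shape[group]
    regional = np.exp(rng.normal(mu, sd, size=m))
    regional /= regional.sum()
    optima = rng.uniform(*LAT_RANGE, size=m)
    # Regionally dominant OTUs behave as broadly adapted generalists: no
    # latitude filtering and a fixed total community share, so turnover in
    # the generalist block never leaks into the filtered (rare) block.
    # Everything else carries a Gaussian niche filter (beta_env sharpens
    # it, 0 switches it off) plus mild iid lognormal overdispersion.
    # iid local extinctions (dropout) hit both blocks independently and are
    # the dominant source of abundant-subcommunity richness variation.
    generalist = regional > config.generalist_min
    z = (lat[:, None] - optima[None, :]) / config.niche_width
    weights = np.exp(-config.beta_env * z ** 2)
    if config.compositional_noise_sd > 0:
        weights = weights * np.exp(
            rng.normal(0.0, config.compositional_noise_sd, size=(n, m))
        )
    weights[:, generalist] = 1.0
    if config.dropout > 0:
        weights = weights * (rng.random((n, m)) >= config.dropout)
    p = regional[None, :] * weights
    if generalist.any() and (~generalist).any():
        share = regional[generalist].sum()
        for block, total in ((generalist, share), (~generalist, 1.0 - share)):
            sub = p[:, block]
            sums = sub.sum(axis=1, keepdims=True)
            sums[sums == 0] = 1.0  # every block member dropped: leave empty
            p[:, block] = sub / sums * total
    p /= p.sum(axis=1, keepdims=True)
    depth = config.group_depths[group]
    counts = np.empty((n, m), dtype=np.int64)
    for i in range(n):
        counts[i] = rng.multinomial(depth, p[i])
    return CommunityTable(
        sample_ids=[f"S{i + 1:03d}" for i in range(n)],
        phylotype_ids=[f"{group[:4].upper()}_{j + 1:04d}" for j in range(m)],
        counts=counts,
        group=group,
    )


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    """Generate one dataset; identical config (incl. seed) -> identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]

    lat = np.sort(rng.uniform(*LAT_RANGE, size=n))
    # alternate crops so both span the whole gradient
    crop = ["maize" if i % 2 == 0 else "rice" for i in range(n)]

    tables = {g: _simulate_group(rng, g, lat, config) for g in GROUPS}

    # realized latent drivers: standardized rare/abundant multidiversity
    latent = {}
    for sub in ("rare", "abundant"):
        per_group = []
        for g in GROUPS:
            classes = classify_phylotypes(tables[g], DEFAULT_SCHEME)
            subtab = subset_community(tables[g], classes, sub)
            r = richness(subtab) if subtab.n_phylotypes else np.zeros(n, dtype=int)
            per_group.append(_safe_minmax(r.astype(float)))
        latent[sub] = np.mean(per_group, axis=0)

    lat_z = _zscore(lat)
    signal = (
        config.beta_rare * _zscore(latent["rare"])
        + config.beta_abundant * _zscore(latent["abundant"])
        + config.beta_env_function * lat_z
    )

    function_ids = list(DEFAULT_FUNCTION_SCHEMA)
    values = np.empty((n, len(function_ids)))
    for j, f in enumerate(function_ids):
        _, sign = DEFAULT_FUNCTION_SCHEMA[f]
        raw = signal + rng.normal(0.0, config.noise_sd, size=n)
        # sign -1 functions are stored "less is better": the raw measurement
        # decreases as the latent functioning signal rises.
        values[:, j] = sign * raw

    functions = FunctionTable(
        sample_ids=sample_ids,
        function_ids=function_ids,
        values=values,
        service_group={f: sg for f, (sg, _) in DEFAULT_FUNCTION_SCHEMA.items()},
        sign={f: s for f, (_, s) in DEFAULT_FUNCTION_SCHEMA.items()},
    )

    metadata = SampleMetadata(
        sample_ids=sample_ids,
        latitude=lat,
        crop=crop,
        mat=24.0 - 0.55 * (lat - LAT_RANGE[0]) + rng.normal(0, 1.0, n),
        ph=6.5 + rng.normal(0, 0.8, n),
        total_c=np.exp(rng.normal(2.5, 0.4, n)),
        clay=np.clip(rng.normal(25, 8, n), 2, 60),
        cec=np.exp(rng.normal(2.4, 0.3, n)),
    )

    truth = {
        "config": {
            **{k: v for k, v in asdict(config).items()},
        },
        "latent_rare_multidiversity": latent["rare"].tolist(),
        "latent_abundant_multidiversity": latent["abundant"].tolist(),
        "latitude": lat.tolist(),
    }
    return SyntheticDataset(tables=tables, functions=functions, metadata=metadata, truth=truth)


def write_dataset(ds: SyntheticDataset, directory) -> list[str]:
    """Write the dataset in the layout ``core`` reads; returns filenames."""
    from pathlib import Path

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []
    for g, table in ds.tables.items():
        path = directory / f"community_{g}.tsv"
        write_community_table(table, path)
        written.append(path.name)
    write_function_table(
        ds.functions, directory / "functions.csv", directory / "function_schema.yaml"
    )
    written += ["functions.csv", "function_schema.yaml"]
    write_metadata(ds.metadata, directory / "metadata.csv")
    written.append("metadata.csv")
    with open(directory / "truth.yaml", "w") as fh:
        yaml.safe_dump(ds.truth, fh, sort_keys=False)
    written.append("truth.yaml")
    return written


def read_truth(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
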