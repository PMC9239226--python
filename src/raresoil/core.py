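"""Domain types, file I/O, rarefaction and relative-abundance transforms.

Community tables are dense integer matrices (samples x phylotypes) tagged
with one of the four organism groups.  Files are samples-in-rows by default;
an ``orientation`` flag transposes, because both conventions exist in the
wild.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: The four organism groups handled by the pipeline.
GROUPS = ("archaea", "bacteria", "fungi", "protist")

#: Per-group rarefaction depths of the emulated study design.
DEFAULT_DEPTHS = {
    "archaea": 36_880,
    "bacteria": 27_712,
    "fungi": 30_369,
    "protist": 5_393,
}

#: The four ecosystem-service groups.
SERVICE_GROUPS = (
    "nutrient_provisioning",
    "element_cycling",
    "pathogen_control",
    "symbiosis",
)

#: Default 16-function schema: function id -> (service group, sign).
#: sign -1 marks a "less is better" function that is inverted (x * -1)
#: before min-max standardization.
DEFAULT_FUNCTION_SCHEMA: dict[str, tuple[str, int]] = {
    "beta_glucosidase": ("nutrient_provisioning", 1),
    "saccharase": ("nutrient_provisioning", 1),
    "n_acetylglucosaminidase": ("nutrient_provisioning", 1),
    "phosphatase": ("nutrient_provisioning", 1),
    "dissolved_organic_C": ("nutrient_provisioning", 1),
    "available_N": ("nutrient_provisioning", 1),
    "available_P": ("nutrient_provisioning", 1),
    "microbial_biomass_C": ("nutrient_provisioning", 1),
    "microbial_biomass_N": ("nutrient_provisioning", 1),
    "available_S": ("element_cycling", 1),
    "available_Fe": ("element_cycling", 1),
    "available_Cu": ("element_cycling", 1),
    "available_Zn": ("element_cycling", 1),
    "available_Mn": ("element_cycling", 1),
    "plant_pathogen_abundance": ("pathogen_control", -1),
    "mycorrhizal_abundance": ("symbiosis", 1),
}


class ValidationError(ValueError):
    """Raised when a table violates a structural invariant."""


def _check_unique(ids, what: str) -> None:
    seen = set()
    for x in ids:
        if x in seen:
            raise ValidationError(f"duplicate {what} identifier: {x!r}")
        seen.add(x)


@dataclass
class CommunityTable:
    """Integer sample x phylotype count matrix for one organism group."""

    sample_ids: list[str]
    phylotype_ids: list[str]
    counts: np.ndarray
    group: str

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.phylotype_ids = [str(p) for p in self.phylotype_ids]
        self.counts = np.asarray(self.counts)
        if self.group not in GROUPS:
            raise ValidationError(
                f"unknown organism group {self.group!r}; expected one of {GROUPS}"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.phylotype_ids, "phylotype")
        if self.counts.shape != (len(self.sample_ids), len(self.phylotype_ids)):
            raise ValidationError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.phylotype_ids)} phylotypes"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            as_int = self.counts.astype(np.int64)
            if not np.array_equal(as_int, self.counts):
                bad = np.argwhere(as_int != self.counts)
                i, j = bad[0]
                raise ValidationError(
                    f"non-integer count at sample {self.sample_ids[i]!r}, "
                    f"phylotype {self.phylotype_ids[j]!r}: {self.counts[i, j]}"
                )
            self.counts = as_int
        if (self.counts < 0).any():
            i, j = np.argwhere(self.counts < 0)[0]
            raise ValidationError(
                f"negative count at sample {self.sample_ids[i]!r}, "
                f"phylotype {self.phylotype_ids[j]!r}"
            )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_phylotypes(self) -> int:
        return len(self.phylotype_ids)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def drop_empty_phylotypes(self) -> "CommunityTable":
        """Return a copy with all-zero phylotype columns removed."""
        keep = self.counts.sum(axis=0) > 0
        return CommunityTable(
            sample_ids=list(self.sample_ids),
            phylotype_ids=[p for p, k in zip(self.phylotype_ids, keep) if k],
            counts=self.counts[:, keep].copy(),
            group=self.group,
        )

    def subset_samples(self, sample_ids) -> "CommunityTable":
        index = {s: i for i, s in enumerate(self.sample_ids)}
        rows = [index[s] for s in sample_ids]
        return CommunityTable(
            sample_ids=list(sample_ids),
            phylotype_ids=list(self.phylotype_ids),
            counts=self.counts[rows, :].copy(),
            group=self.group,
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.phylotype_ids
        )


@dataclass
class FunctionTable:
    """Real-valued sample x ecosystem-function matrix with annotations.

    ``service_group`` maps each function to one of the four ecosystem
    services; ``sign`` maps each function to +1 or -1, -1 marking functions
    scored as "less is better" (inverted before standardization).
    """

    sample_ids: list[str]
    function_ids: list[str]
    values: np.ndarray
    service_group: dict[str, str]
    sign: dict[str, int]

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.function_ids, "function")
        if self.values.shape != (len(self.sample_ids), len(self.function_ids)):
            raise ValidationError("values shape does not match ids")
        if np.isnan(self.values).any():
            raise ValidationError("function table contains missing values")
        for f in self.function_ids:
            if f not in self.service_group:
                raise ValidationError(f"function {f!r} has no service group")
            if self.sign.get(f) not in (1, -1):
                raise ValidationError(f"function {f!r} has no +1/-1 sign")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_functions(self) -> int:
        return len(self.function_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.sample_ids, columns=self.function_ids
        )


@dataclass
class SampleMetadata:
    """Per-sample environment and design covariates."""

    sample_ids: list[str]
    latitude: np.ndarray
    crop: list[str]
    mat: np.ndarray
    ph: np.ndarray
    total_c: np.ndarray
    clay: np.ndarray
    cec: np.ndarray

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        _check_unique(self.sample_ids, "sample")
        n = len(self.sample_ids)
        for name in ("latitude", "mat", "ph", "total_c", "clay", "cec"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ValidationError(f"metadata field {name} has wrong length")
            setattr(self, name, arr)
        if not np.isfinite(self.latitude).all():
            raise ValidationError("latitude contains non-finite values")
        if len(self.crop) != n:
            raise ValidationError("crop has wrong length")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "latitude": self.latitude,
                "crop": self.crop,
                "MAT": self.mat,
                "pH": self.ph,
                "total_C": self.total_c,
                "clay": self.clay,
                "CEC": self.cec,
            },
            index=self.sample_ids,
        )


@dataclass
class StandardizedVector:
    """Min-max standardized vector: STD = (X - X_min) / (X_max - X_min)."""

    raw: np.ndarray
    minimum: float
    maximum: float
    std: np.ndarray = field(repr=False)


# ---------------------------------------------------------------------------
# readers / writers


def _read_table_df(path, sep: str) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep=sep, index_col=0, comment="#")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValidationError(f"cannot parse {path}: {exc}") from exc


def read_community_table(
    path,
    group: str,
    format: str = "tsv",
    orientation: str = "samples",
) -> CommunityTable:
    """Read a community count table.

    Parameters
    ----------
    path : str or Path
        Input file.
    group : str
        Organism group of the table.
    format : {"tsv", "biom"}
        ``tsv`` expects a header row of phylotype ids and a first column of
        sample ids.  ``biom`` requires the optional ``biom-format`` package.
    orientation : {"samples", "phylotypes"}
        Which entity the file rows represent; ``phylotypes`` transposes.
    """
    if format == "biom":
        try:
            import biom  # noqa: F401  (optional dependency)
        except ImportError as exc:
            raise ImportError(
                "reading BIOM files requires the optional 'biom-format' package"
            ) from exc
        bt = biom.load_table(str(path))
        df = bt.to_dataframe(dense=True).T  # biom stores observations x samples
    elif format == "tsv":
        df = _read_table_df(path, sep="\t")
    else:
        raise ValueError(f"unknown format {format!r}")
    if orientation == "phylotypes":
        df = df.T
    elif orientation != "samples":
        raise ValueError(f"unknown orientation {orientation!r}")
    values = df.to_numpy()
    if values.dtype == object or not np.issubdtype(values.dtype, np.number):
        raise ValidationError(f"{path}: table contains non-numeric entries")
    rounded = np.rint(values)
    if not np.allclose(values, rounded, atol=0, rtol=0):
        bad_row = df.index[np.argwhere(values != rounded)[0][0]]
        raise ValidationError(f"{path}: non-integer count in row {bad_row!r}")
    if (values < 0).any():
        bad_row = df.index[np.argwhere(values < 0)[0][0]]
        raise ValidationError(f"{path}: negative count in row {bad_row!r}")
    table = CommunityTable(
        sample_ids=list(df.index),
        phylotype_ids=list(df.columns),
        counts=rounded.astype(np.int64),
        group=group,
    ).drop_empty_phylotypes()
    logger.info(
        "read %s community table: %d samples x %d phylotypes",
        group, table.n_samples, table.n_phylotypes,
    )
    return table


def write_community_table(table: CommunityTable, path, header: str | None = None) -> None:
    """Write a community table as TSV (samples in rows)."""
    with open(path, "w") as fh:
        if header:
            for line in header.rstrip("\n").split("\n"):
                fh.write(f"# {line}\n")
        table.to_dataframe().to_csv(fh, sep="\t", index_label="sample_id")


def read_function_table(values_path, schema_path=None, sep: str = ",") -> FunctionTable:
    """Read a function table (CSV/TSV) plus a YAML annotation sidecar.

    The sidecar maps function id -> ``{service_group: ..., sign: +-1}``.
    Without a sidecar the default 16-function schema is assumed.
    """
    df = _read_table_df(values_path, sep=sep)
    if schema_path is not None:
        with open(schema_path) as fh:
            raw = yaml.safe_load(fh)
        service = {f: str(v["service_group"]) for f, v in raw.items()}
        sign = {f: int(v["sign"]) for f, v in raw.items()}
    else:
        service = {f: sg for f, (sg, _) in DEFAULT_FUNCTION_SCHEMA.items()}
        sign = {f: s for f, (_, s) in DEFAULT_FUNCTION_SCHEMA.items()}
    return FunctionTable(
        sample_ids=list(df.index),
        function_ids=list(df.columns),
        values=df.to_numpy(dtype=float),
        service_group=service,
        sign=sign,
    )


def write_function_table(ft: FunctionTable, values_path, schema_path=None) -> None:
    ft.to_dataframe().to_csv(values_path, index_label="sample_id")
    if schema_path is not None:
        schema = {
            f: {"service_group": ft.service_group[f], "sign": int(ft.sign[f])}
            for f in ft.function_ids
        }
        with open(schema_path, "w") as fh:
            yaml.safe_dump(schema, fh, sort_keys=False)


def read_metadata(path, sep: str = ",") -> SampleMetadata:
    df = _read_table_df(path, sep=sep)
    return SampleMetadata(
        sample_ids=list(df.index),
        latitude=df["latitude"].to_numpy(float),
        crop=[str(c) for c in df["crop"]],
        mat=df["MAT"].to_numpy(float),
        ph=df["pH"].to_numpy(float),
        total_c=df["total_C"].to_numpy(float),
        clay=df["clay"].to_numpy(float),
        cec=df["CEC"].to_numpy(float),
    )


def write_metadata(md: SampleMetadata, path) -> None:
    md.to_dataframe().to_csv(path, index_label="sample_id")


# ---------------------------------------------------------------------------
# transforms


def rarefy(table: CommunityTable, depth: int, seed: int) -> CommunityTable:
    """Subsample every sample to ``depth`` reads without replacement.

    Uses multivariate hypergeometric draws per sample; all-zero phylotype
    columns that arise are retained so classification sets remain stable.
    """
    if depth <= 0:
        raise ValueError("depth must be a positive integer")
    totals = table.sample_totals()
    short = [s for s, t in zip(table.sample_ids, totals) if t < depth]
    if short:
        raise ValueError(
            f"samples with fewer than {depth} reads: {', '.join(short)}"
        )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        row = table.counts[i]
        if totals[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return CommunityTable(
        sample_ids=list(table.sample_ids),
        phylotype_ids=list(table.phylotype_ids),
        counts=out,
        group=table.group,
    )


def relative_abundance(table: CommunityTable, level: str = "per_sample") -> np.ndarray:
    """Relative abundances per sample (matrix) or dataset-wide (vector).

    ``per_sample`` divides each row by its total; ``dataset`` returns one
    value per phylotype, its total count over the grand total.
    """
    if table.n_samples == 0 or table.n_phylotypes == 0:
        raise ValueError("empty community table")
    if level == "per_sample":
        totals = table.sample_totals().astype(float)
        if (totals == 0).any():
            raise ValueError("per-sample relative abundance undefined for empty samples")
        return table.counts / totals[:, None]
    if level == "dataset":
        grand = float(table.counts.sum())
        if grand == 0:
            raise ValueError("dataset relative abundance undefined for empty table")
        return table.counts.sum(axis=0) / grand
    raise ValueError(f"unknown level {level!r}")


def align_samples(
    tables: dict[str, CommunityTable],
    functions: FunctionTable | None = None,
    metadata: SampleMetadata | None = None,
):
    """Subset all inputs to their shared samples, in metadata (or first
    table) order.  Returns the aligned ``(tables, functions, metadata)``."""
    sets = [set(t.sample_ids) for t in tables.values()]
    if functions is not None:
        sets.append(set(functions.sample_ids))
    if metadata is not None:
        sets.append(set(metadata.sample_ids))
    shared = set.intersection(*sets)
    ref = metadata.sample_ids if metadata is not None else next(iter(tables.values())).sample_ids
    order = [s for s in ref if s in shared]
    if not order:
        raise ValidationError("no shared samples across inputs")
    tables = {g: t.subset_samples(order) for g, t in tables.items()}
    if functions is not None:
        idx = {s: i for i, s in enumerate(functions.sample_ids)}
        functions = FunctionTable(
            sample_ids=order,
            function_ids=list(functions.function_ids),
            values=functions.values[[idx[s] for s in order], :],
            service_group=dict(functions.service_group),
            sign=dict(functions.sign),
        )
    if metadata is not None:
        idx = {s: i for i, s in enumerate(metadata.sample_ids)}
        rows = [idx[s] for s in order]
        metadata = SampleMetadata(
            sample_ids=order,
            latitude=metadata.latitude[rows],
            crop=[metadata.crop[i] for i in rows],
            mat=metadata.mat[rows],
            ph=metadata.ph[rows],
            total_c=metadata.total_c[rows],
            clay=metadata.clay[rows],
            cec=metadata.cec[rows],
        )
    return tables, functions, metadata
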