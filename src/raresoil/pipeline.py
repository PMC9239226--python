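"""Pipeline orchestration: stages composed over an output directory.

Every stage reads the dataset files (and any upstream stage TSVs it needs)
from the output directory and writes its own TSVs with a provenance header
(version, master seed, config hash).  One master seed is supplied; stage
seeds are derived with a fixed keyed scheme so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import raresoil
from raresoil import assembly as asm
from raresoil import bef as befmod
from raresoil import network as netmod
from raresoil.core import (
    GROUPS,
    CommunityTable,
    SampleMetadata,
    read_community_table,
    read_function_table,
    read_metadata,
)
from raresoil.diversity import diversity_table
from raresoil.multifunctionality import compute_multifunctionality
from raresoil.partition import (
    alternative_schemes,
    classify_phylotypes,
    subset_community,
    write_classification,
)
from raresoil.simulate import SimulationConfig, SyntheticDataset, generate_dataset, write_dataset
from raresoil.windows import make_windows, window_bef_st

logger = logging.getLogger(__name__)

FLOAT_FORMAT = "%.12g"


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    """Validated pipeline settings (YAML-loadable)."""

    output_dir: str = "out"
    seed: int = 0
    simulation: dict | None = None
    inputs: dict | None = None
    scheme: str = "default"
    multifunctionality_method: str = "averaging"
    support_p_cut: float = 0.01
    support_prevalence_min: float = 0.10
    network_prevalence_min: float = 0.20
    network_rho_min: float = 0.6
    network_q_max: float = 0.001
    n_null: int = 1000
    st_bins: int = 19
    window_sizes: list = field(default_factory=lambda: [30, 40])
    window_n_null: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.simulation is None and self.inputs is None:
            raise PipelineError(
                "config must provide either a 'simulation' block or an 'inputs' block"
            )
        if self.inputs is not None:
            required = {"community", "functions", "metadata"}
            missing = required - set(self.inputs)
            if missing:
                raise PipelineError(f"inputs block missing: {sorted(missing)}")
            for g in GROUPS:
                p = self.inputs["community"].get(g)
                if p is None or not Path(p).exists():
                    raise PipelineError(f"community table for {g!r} missing: {p}")
            for key in ("functions", "metadata"):
                if not Path(self.inputs[key]).exists():
                    raise PipelineError(f"input file missing: {self.inputs[key]}")
        if self.multifunctionality_method not in ("averaging", "weighted", "multidimensional"):
            raise PipelineError(
                f"unknown multifunctionality method {self.multifunctionality_method!r}"
            )
        if self.scheme not in {s.name for s in alternative_schemes()}:
            raise PipelineError(f"unknown threshold scheme {self.scheme!r}")

    def config_hash(self) -> str:
        payload = {k: v for k, v in self.__dict__.items() if k != "output_dir"}
        canon = yaml.safe_dump(payload, sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]

    def threshold_scheme(self):
        return {s.name: s for s in alternative_schemes()}[self.scheme]


def stage_seed(master: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the master seed."""
    ss = np.random.SeedSequence([int(master), zlib.crc32(stage.encode())])
    return int(ss.generate_state(1)[0])


def _provenance(config: PipelineConfig, stage: str) -> str:
    return (
        f"raresoil {raresoil.__version__}\n"
        f"stage: {stage}\nseed: {config.seed}\nconfig-hash: {config.config_hash()}"
    )


def write_tsv(df: pd.DataFrame, path, config: PipelineConfig, stage: str, **kwargs) -> None:
    with open(path, "w") as fh:
        for line in _provenance(config, stage).split("\n"):
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", float_format=FLOAT_FORMAT, **kwargs)


def _read_stage_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0, comment="#")


# ---------------------------------------------------------------------------
# dataset handling


def ensure_dataset(config: PipelineConfig) -> Path:
    """Make sure the dataset files exist under <output_dir>/data; simulate
    them if a simulation block is configured and they are absent."""
    out = Path(config.output_dir)
    data = out / "data"
    have = all((data / f"community_{g}.tsv").exists() for g in GROUPS)
    if config.inputs is not None:
        return Path(".")  # paths in config.inputs are used directly
    if not have:
        sim = dict(config.simulation or {})
        sim.setdefault("seed", stage_seed(config.seed, "simulate"))
        ds = generate_dataset(SimulationConfig(**sim))
        write_dataset(ds, data)
        logger.info("simulated dataset written to %s", data)
    return data


def load_dataset(config: PipelineConfig):
    """Load (tables, functions, metadata) from configured inputs or the
    simulated data directory."""
    if config.inputs is not None:
        tables = {
            g: read_community_table(config.inputs["community"][g], group=g)
            for g in GROUPS
        }
        functions = read_function_table(
            config.inputs["functions"], config.inputs.get("function_schema")
        )
        metadata = read_metadata(config.inputs["metadata"])
    else:
        data = ensure_dataset(config)
        tables = {
            g: read_community_table(data / f"community_{g}.tsv", group=g) for g in GROUPS
        }
        functions = read_function_table(data / "functions.csv", data / "function_schema.yaml")
        metadata = read_metadata(data / "metadata.csv")
    return tables, functions, metadata


def _classes(config: PipelineConfig, tables):
    scheme = config.threshold_scheme()
    return {g: classify_phylotypes(t, scheme) for g, t in tables.items()}


def _subcommunities(tables, classes):
    subs = {"whole": tables}
    for label in ("rare", "intermediate", "abundant"):
        subs[label] = {g: subset_community(tables[g], classes[g], label) for g in GROUPS}
    return subs


# ---------------------------------------------------------------------------
# stages


def stage_partition(config: PipelineConfig) -> None:
    tables, _, _ = load_dataset(config)
    classes = _classes(config, tables)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_classification(classes, out / "classification.tsv")


def stage_diversity(config: PipelineConfig) -> None:
    tables, _, _ = load_dataset(config)
    classes = _classes(config, tables)
    dt = diversity_table(_subcommunities(tables, classes))
    write_tsv(
        dt.to_dataframe(),
        Path(config.output_dir) / "diversity.tsv",
        config,
        "diversity",
        index_label="sample_id",
    )


def stage_multifunc(config: PipelineConfig) -> None:
    _, functions, _ = load_dataset(config)
    mf = compute_multifunctionality(functions)
    out = Path(config.output_dir)
    write_tsv(mf.to_dataframe(), out / "multifunctionality.tsv", config, "multifunc",
              index_label="sample_id")
    write_tsv(
        pd.DataFrame({"eigenvalue": mf.eigenvalues}),
        out / "multifunctionality_eigenvalues.tsv",
        config,
        "multifunc",
        index_label="axis",
    )
    write_tsv(mf.standardized, out / "functions_standardized.tsv", config, "multifunc",
              index_label="sample_id")


def stage_bef(config: PipelineConfig) -> None:
    tables, functions, _ = load_dataset(config)
    classes = _classes(config, tables)
    out = Path(config.output_dir)
    div = _read_stage_tsv(out / "diversity.tsv")
    mfdf = _read_stage_tsv(out / "multifunctionality.tsv")
    std = _read_stage_tsv(out / "functions_standardized.tsv")
    mf = mfdf[config.multifunctionality_method].to_numpy()

    rows = []
    for sub in ("whole", "rare", "intermediate", "abundant"):
        x = div[f"multidiversity_{sub}"].to_numpy()
        try:
            fit = befmod.bef_regression(x, mf)
            rows.append({"subcommunity": sub, **fit.__dict__})
        except ValueError as exc:
            logger.warning("BEF regression skipped for %s: %s", sub, exc)
            rows.append({"subcommunity": sub, "slope": np.nan, "standardized_slope": np.nan,
                         "intercept": np.nan, "r_squared": np.nan, "p_value": np.nan,
                         "n": len(mf)})
    write_tsv(pd.DataFrame(rows).set_index("subcommunity"),
              out / "bef_regressions.tsv", config, "bef")

    diversities = {}
    for col in div.columns:
        if col.startswith("richness_"):
            diversities[col.removeprefix("richness_")] = div[col].to_numpy(float)
    corr = befmod.diversity_function_correlations(diversities, std)
    write_tsv(corr.set_index("diversity"), out / "diversity_function_correlations.tsv",
              config, "bef")

    st = befmod.supporting_phylotypes(
        tables, classes, std,
        p_cut=config.support_p_cut,
        prevalence_min=config.support_prevalence_min,
    )
    write_tsv(st.to_dataframe(), out / "support_table.tsv", config, "bef",
              index_label="phylotype_id")
    summary = befmod.support_summary(st)
    write_tsv(summary["per_function"].set_index("function"),
              out / "support_per_function.tsv", config, "bef")
    sub_rows = [
        {"subcommunity": k, **v} for k, v in summary["per_subcommunity"].items()
    ]
    write_tsv(pd.DataFrame(sub_rows).set_index("subcommunity"),
              out / "support_per_subcommunity.tsv", config, "bef")
    try:
        breadth = befmod.compare_support_breadth(st)
    except ValueError as exc:
        logger.warning("breadth comparison skipped: %s", exc)
        breadth = {"error": str(exc)}
    write_tsv(pd.DataFrame([breadth]).set_index(pd.Index([0], name="row")),
              out / "support_breadth_test.tsv", config, "bef")


def stage_network(config: PipelineConfig) -> None:
    tables, _, _ = load_dataset(config)
    classes = _classes(config, tables)
    out = Path(config.output_dir)
    mfdf = _read_stage_tsv(out / "multifunctionality.tsv")
    mf = mfdf[config.multifunctionality_method].to_numpy()
    rows = []
    for label in ("abundant", "rare"):
        try:
            net = netmod.build_network(
                tables, classes, label,
                prevalence_min=config.network_prevalence_min,
                rho_min=config.network_rho_min,
                q_max=config.network_q_max,
            )
            netmod.node_support_scores(net, mf)
            netmod.export_network(net, out / f"network_{label}")
            try:
                fit = netmod.degree_support_regression(net)
                rows.append({"network": label, "n_nodes": len(net.nodes),
                             "n_edges": net.n_edges, **fit.__dict__})
            except ValueError as exc:
                logger.warning("degree regression skipped for %s: %s", label, exc)
                rows.append({"network": label, "n_nodes": len(net.nodes),
                             "n_edges": net.n_edges})
        except ValueError as exc:
            logger.warning("network %s skipped: %s", label, exc)
            rows.append({"network": label, "n_nodes": 0, "n_edges": 0})
    write_tsv(pd.DataFrame(rows).set_index("network"),
              out / "network_degree_support.tsv", config, "network")


def stage_assembly(config: PipelineConfig) -> None:
    tables, _, _ = load_dataset(config)
    classes = _classes(config, tables)
    out = Path(config.output_dir)
    div = _read_stage_tsv(out / "diversity.tsv")
    mfdf = _read_stage_tsv(out / "multifunctionality.tsv")
    mf = mfdf[config.multifunctionality_method].to_numpy()
    seed = stage_seed(config.seed, "assembly")
    for label in ("rare", "abundant"):
        pooled, _ = asm.pool_relative_abundance(tables, classes, label)
        occupied = pooled.sum(axis=1) > 0
        if not occupied.all():
            logger.warning(
                "%d samples without %s taxa excluded from ST analysis",
                int((~occupied).sum()), label,
            )
        for ordering_name, ordering in (
            ("multifunctionality", mf),
            ("multidiversity", div[f"multidiversity_{label}"].to_numpy()),
        ):
            res = asm.st_by_category(
                pooled[occupied], ordering[occupied],
                n_groups=config.st_bins, n_null=config.n_null,
                seed=stage_seed(seed, f"{label}:{ordering_name}"),
            )
            write_tsv(res["bins"].set_index("bin"),
                      out / f"st_bins_{label}_{ordering_name}.tsv", config, "assembly")
            if res["trend"] is not None:
                t = res["trend"]
                tdf = pd.DataFrame(
                    {"coefficient": t["coefficients"], "p_value": t["p_values"]}
                )
                tdf["r_squared"] = t["r_squared"]
                write_tsv(tdf, out / f"st_trend_{label}_{ordering_name}.tsv",
                          config, "assembly", index_label="power")


def stage_window(config: PipelineConfig) -> None:
    tables, _, metadata = load_dataset(config)
    classes = _classes(config, tables)
    out = Path(config.output_dir)
    div = _read_stage_tsv(out / "diversity.tsv")
    mfdf = _read_stage_tsv(out / "multifunctionality.tsv")
    mf_all = mfdf[config.multifunctionality_method]
    seed = stage_seed(config.seed, "window")
    pooled, _ = asm.pool_relative_abundance(tables, classes, "rare")
    occupied = pooled.sum(axis=1) > 0
    if not occupied.all():
        logger.warning(
            "%d samples without rare taxa excluded from window analysis",
            int((~occupied).sum()),
        )
        keep = [s for s, k in zip(metadata.sample_ids, occupied) if k]
        rows = np.flatnonzero(occupied)
        metadata = SampleMetadata(
            sample_ids=keep,
            latitude=metadata.latitude[rows],
            crop=[metadata.crop[i] for i in rows],
            mat=metadata.mat[rows], ph=metadata.ph[rows],
            total_c=metadata.total_c[rows], clay=metadata.clay[rows],
            cec=metadata.cec[rows],
        )
        pooled = pooled[rows]
        div = div.loc[keep]
        mf_all = mf_all.loc[keep]
    sample_index = {s: i for i, s in enumerate(metadata.sample_ids)}
    for size in config.window_sizes:
        ws = make_windows(metadata, size)
        order_idx = [sample_index[s] for s in ws.sample_order]
        res = window_bef_st(
            ws,
            div["multidiversity_rare"].reindex(ws.sample_order).to_numpy(),
            mf_all.reindex(ws.sample_order).to_numpy(),
            pooled[order_idx],
            n_null=config.window_n_null,
            seed=stage_seed(seed, f"size{size}"),
        )
        write_tsv(res["windows"].set_index("window"),
                  out / f"window_{size}.tsv", config, "window")
        write_tsv(
            pd.DataFrame({"sample_id": ws.sample_order}),
            out / f"window_{size}_order.tsv", config, "window", index_label="rank",
        )
        if res["trend"] is not None:
            t = res["trend"]
            tdf = pd.DataFrame({"coefficient": t["coefficients"], "p_value": t["p_values"]})
            tdf["r_squared"] = t["r_squared"]
            write_tsv(tdf, out / f"window_{size}_trend.tsv", config, "window",
                      index_label="power")


STAGES = {
    "partition": stage_partition,
    "diversity": stage_diversity,
    "multifunc": stage_multifunc,
    "bef": stage_bef,
    "network": stage_network,
    "assembly": stage_assembly,
    "window": stage_window,
}

STAGE_ORDER = ["partition", "diversity", "multifunc", "bef", "network", "assembly", "window"]


def run_stage(config: PipelineConfig, name: str) -> None:
    Path(config.output_dir).mkdir(parents=True, exist_ok=True)
    try:
        STAGES[name](config)
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"stage {name!r} failed: {exc}") from exc


def run_all(config: PipelineConfig) -> Path:
    """Execute every stage in order; returns the output directory."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    if config.inputs is None:
        ensure_dataset(config)
    for name in STAGE_ORDER:
        logger.info("running stage %s", name)
        run_stage(config, name)
    return out
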