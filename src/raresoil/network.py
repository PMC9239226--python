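"""Co-occurrence networks of abundant or rare phylotypes.

Edges require pairwise Spearman |rho| > 0.6 and Benjamini-Hochberg
FDR-adjusted q < 0.001 (strict inequalities), the FDR computed across all
tested pairs within one network.  Correlations are computed on per-sample
relative abundances after per-group normalization, so the four organism
groups' different sequencing depths cannot fabricate edges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from raresoil.bef import RegressionResult, bef_regression, _spearman_matrix
from raresoil.core import CommunityTable, relative_abundance
from raresoil.partition import AbundanceClasses

logger = logging.getLogger(__name__)

RHO_MIN = 0.6
Q_MAX = 0.001


@dataclass
class CooccurrenceNetwork:
    """Undirected phylotype co-occurrence network with node annotations."""

    graph: nx.Graph
    label: str
    rho_min: float = RHO_MIN
    q_max: float = Q_MAX
    abundances: pd.DataFrame = field(default=None, repr=False)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def degrees(self) -> dict[str, int]:
        return dict(self.graph.degree())

    def node_table(self) -> pd.DataFrame:
        rows = []
        for node, data in self.graph.nodes(data=True):
            rows.append({"phylotype_id": node, "degree": self.graph.degree(node), **data})
        return pd.DataFrame(rows)

    def edge_table(self) -> pd.DataFrame:
        rows = [
            {"source": u, "target": v, **data}
            for u, v, data in self.graph.edges(data=True)
        ]
        return pd.DataFrame(rows)


def build_network(
    tables: dict[str, CommunityTable],
    classes: dict[str, AbundanceClasses],
    label: str,
    prevalence_min: float = 0.20,
    rho_min: float = RHO_MIN,
    q_max: float = Q_MAX,
) -> CooccurrenceNetwork:
    """Build the co-occurrence network for one abundance class.

    Candidate nodes are the phylotypes of the requested label across all
    four groups that are present in at least ``prevalence_min`` of samples.
    """
    ids: list[str] = []
    node_group: dict[str, str] = {}
    cols = []
    sample_ref = None
    for g, table in tables.items():
        if sample_ref is None:
            sample_ref = table.sample_ids
        elif table.sample_ids != sample_ref:
            raise ValueError("community tables have mismatched samples")
        cls = classes[g]
        wanted = set(cls.ids_with_label(label))
        rel = relative_abundance(table, "per_sample")
        prevalence = (table.counts > 0).mean(axis=0)
        for j, p in enumerate(table.phylotype_ids):
            if p in wanted and prevalence[j] >= prevalence_min:
                ids.append(p)
                node_group[p] = g
                cols.append(rel[:, j])
    if len(ids) < 2:
        raise ValueError(
            f"need >= 2 candidate nodes for the {label!r} network, got {len(ids)}"
        )
    logger.info("%s network: %d candidate nodes", label, len(ids))
    abund = np.column_stack(cols)
    rho, p = _spearman_matrix(abund, abund)
    iu = np.triu_indices(len(ids), k=1)
    pair_rho = rho[iu]
    pair_p = p[iu]
    finite = np.isfinite(pair_p)
    q = np.full_like(pair_p, np.nan)
    if finite.any():
        q[finite] = stats.false_discovery_control(pair_p[finite], method="bh")
    graph = nx.Graph()
    for pid in ids:
        graph.add_node(pid, group=node_group[pid], label=label)
    for k in range(pair_rho.size):
        if not np.isfinite(q[k]):
            continue
        # strict threshold with an epsilon so rho == rho_min never passes
        if abs(pair_rho[k]) > rho_min + 1e-10 and q[k] < q_max:
            u, v = ids[iu[0][k]], ids[iu[1][k]]
            graph.add_edge(u, v, rho=float(pair_rho[k]), q=float(q[k]))
    logger.info("%s network: %d edges", label, graph.number_of_edges())
    return CooccurrenceNetwork(
        graph=graph,
        label=label,
        rho_min=rho_min,
        q_max=q_max,
        abundances=pd.DataFrame(abund, index=sample_ref, columns=ids),
    )


def node_support_scores(net: CooccurrenceNetwork, mf: np.ndarray) -> CooccurrenceNetwork:
    """Attach Pearson correlation with multifunctionality to each node.

    Nodes with r > 0 get ``display=True`` (they support multifunctionality);
    constant-abundance nodes are flagged undefined.
    """
    mf = np.asarray(mf, float)
    if mf.size != len(net.abundances):
        raise ValueError("multifunctionality vector has mismatched length")
    for node in net.graph.nodes:
        x = net.abundances[node].to_numpy()
        if x.std() == 0 or mf.std() == 0:
            net.graph.nodes[node]["support_score"] = float("nan")
            net.graph.nodes[node]["display"] = False
            net.graph.nodes[node]["undefined"] = True
            continue
        r = float(np.corrcoef(x, mf)[0, 1])
        net.graph.nodes[node]["support_score"] = r
        net.graph.nodes[node]["display"] = bool(r > 0)
        net.graph.nodes[node]["undefined"] = False
    return net


def degree_support_regression(net: CooccurrenceNetwork) -> RegressionResult:
    """OLS of node support score on node degree over displayed nodes."""
    deg, score = [], []
    for node, data in net.graph.nodes(data=True):
        if data.get("display"):
            deg.append(net.graph.degree(node))
            score.append(data["support_score"])
    if len(deg) < 3:
        raise ValueError("need >= 3 displayed nodes")
    deg = np.asarray(deg, float)
    if deg.std() == 0:
        raise ValueError("all displayed nodes have equal degree")
    return bef_regression(deg, np.asarray(score))


def export_network(net: CooccurrenceNetwork, basepath) -> list[str]:
    """Write GraphML + GEXF plus node/edge TSVs next to ``basepath``."""
    from pathlib import Path

    base = Path(basepath)
    graph = net.graph.copy()
    for _, data in graph.nodes(data=True):  # graphml cannot store NaN cleanly
        if "support_score" in data and not np.isfinite(data["support_score"]):
            data["support_score"] = 0.0
    paths = [
        base.with_suffix(".graphml"),
        base.with_suffix(".gexf"),
        base.with_suffix(".nodes.tsv"),
        base.with_suffix(".edges.tsv"),
    ]
    nx.write_graphml(graph, paths[0])
    nx.write_gexf(graph, paths[1])
    net.node_table().to_csv(paths[2], sep="\t", index=False)
    net.edge_table().to_csv(paths[3], sep="\t", index=False)
    return [p.name for p in paths]
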