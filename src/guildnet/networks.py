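"""Per-group Spearman co-occurrence networks and their discrepancy analysis.

Each age group gets its own network: taxa passing an abundance/prevalence
filter inside the group become nodes, and an edge is drawn when the
Spearman correlation of two taxa over the group's samples is both strong
(|rho| >= rho_threshold) and significant after BH adjustment
(q < q_threshold).  Cross-group comparison counts shared and group-specific
edges and contrasts closeness and eigenvector centralities of the nodes all
networks have in common.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import RelAbundanceTable, SampleMetadata
from .errors import PreconditionError
from .stats import spearman_matrix

__all__ = ["NetworkComparison", "cooccurrence_network", "compare_networks",
           "eigenvector_centrality", "host_association"]

Edge = tuple[str, str]


def _edge_key(u: str, v: str) -> Edge:
    return (u, v) if u <= v else (v, u)


def cooccurrence_network(rel: RelAbundanceTable, metadata: SampleMetadata,
                         group: str | None = None,
                         min_prevalence: float = 0.2,
                         min_rel_abundance: float = 0.001,
                         rho_threshold: float = 0.7,
                         q_threshold: float = 0.05) -> nx.Graph:
    """Build one group's co-occurrence network.

    Taxa are filtered within the group (relative abundance >=
    min_rel_abundance in at least min_prevalence of the group's samples),
    then all pairs are tested; edges require |rho| >= rho_threshold AND
    q < q_threshold.  Nodes carry the group-mean relative abundance; taxa
    with no retained edge are omitted.
    """
    if group is not None:
        samples = metadata.samples_in_group(group)
        samples = [s for s in samples if s in rel.values.columns]
        sub = rel.values[samples]
    else:
        sub = rel.values
    if sub.shape[1] < 5:
        raise PreconditionError(
            "co-occurrence network needs at least 5 samples")
    hits = ((sub > 0) & (sub >= min_rel_abundance)).sum(axis=1)
    needed = int(np.ceil(min_prevalence * sub.shape[1]))
    kept = sub.loc[hits >= needed]
    net = nx.Graph()
    if kept.shape[0] < 2:
        return net
    table = spearman_matrix(kept)
    mean_ab = kept.mean(axis=1)
    ok = table["valid"] & (table["rho"].abs() >= rho_threshold) \
        & (table["q"] < q_threshold)
    for row in table[ok].itertuples(index=False):
        for t in (row.id_a, row.id_b):
            if t not in net:
                net.add_node(t, mean_abundance=float(mean_ab[t]))
        net.add_edge(row.id_a, row.id_b, weight=float(row.rho),
                     sign="+" if row.rho > 0 else "-")
    return net


def eigenvector_centrality(net: nx.Graph) -> dict[str, float]:
    """Principal eigenvector of the unsigned (binary) adjacency, max-normed.

    Computed by exact symmetric eigendecomposition (the power-iteration
    fixed point), entries reported as magnitudes scaled so the largest is 1.
    """
    nodes = sorted(net.nodes)
    if not nodes:
        return {}
    if len(nodes) == 1:
        return {nodes[0]: 1.0}
    a = nx.to_numpy_array(net, nodelist=nodes, weight=None)
    eigval, eigvec = np.linalg.eigh(a)
    principal = np.abs(eigvec[:, np.argmax(eigval)])
    top = principal.max()
    if top <= 0:
        return {n: 0.0 for n in nodes}
    return {n: float(v / top) for n, v in zip(nodes, principal)}


@dataclass
class NetworkComparison:
    networks: dict[str, nx.Graph]
    shared_edges: set[Edge]
    specific_edges: dict[str, set[Edge]]
    partial_edges: set[Edge]                  # in >1 but not all groups
    discordant_edges: set[Edge] = field(default_factory=set)
    centrality_table: pd.DataFrame | None = None

    def edge_counts(self) -> pd.Series:
        counts = {"shared": len(self.shared_edges),
                  "partial": len(self.partial_edges)}
        for g, edges in self.specific_edges.items():
            counts[f"specific_{g}"] = len(edges)
        return pd.Series(counts, name="n_edges")


def compare_networks(nets: dict[str, nx.Graph]) -> NetworkComparison:
    """Edge overlap and centrality discrepancies across group networks.

    Edge identity is the unordered node pair (sign ignored); an edge whose
    sign differs between two groups that both contain it is additionally
    flagged discordant.  Centralities (Wasserman-Faust closeness,
    max-normalised eigenvector) and their within-group ranks are reported
    for the nodes present in every network.
    """
    if len(nets) < 2:
        raise PreconditionError("need at least 2 networks to compare")
    edge_sets = {g: {_edge_key(u, v) for u, v in net.edges}
                 for g, net in nets.items()}
    shared = set.intersection(*edge_sets.values())
    all_edges = set.union(*edge_sets.values())
    specific = {}
    for g in nets:
        others = set.union(*(edge_sets[h] for h in nets if h != g)) \
            if len(nets) > 1 else set()
        specific[g] = edge_sets[g] - others
    partial = all_edges - shared - set.union(*specific.values())

    discordant = set()
    for e in all_edges:
        signs = {nets[g].edges[e]["sign"] for g in nets if e in edge_sets[g]}
        if len(signs) > 1:
            discordant.add(e)

    common_nodes = set.intersection(*(set(n.nodes) for n in nets.values()))
    rows = []
    for g, net in nets.items():
        closeness = nx.closeness_centrality(net)  # Wasserman-Faust form
        eigen = eigenvector_centrality(net)
        for node in sorted(common_nodes):
            rows.append({"node": node, "group": g,
                         "closeness": closeness[node],
                         "eigenvector": eigen[node]})
    table = pd.DataFrame(rows, columns=["node", "group", "closeness",
                                        "eigenvector"])
    if len(table):
        table["closeness_rank"] = table.groupby("group")["closeness"] \
            .rank(ascending=False, method="average")
        table["eigenvector_rank"] = table.groupby("group")["eigenvector"] \
            .rank(ascending=False, method="average")
    return NetworkComparison(networks=dict(nets), shared_edges=shared,
                             specific_edges=specific, partial_edges=partial,
                             discordant_edges=discordant,
                             centrality_table=table)


def host_association(rel: RelAbundanceTable, metadata: SampleMetadata,
                     taxa: list[str] | None = None,
                     variables: list[str] | None = None,
                     q_threshold: float = 0.05) -> pd.DataFrame:
    """Spearman association of taxa with continuous host variables.

    Every (taxon, variable) pair is tested with pairwise-complete
    observations and BH-adjusted over the full pair family; rows with
    q < q_threshold are flagged significant.  Variables that are entirely
    missing or constant are excluded (flagged invalid) with a warning.
    """
    metadata.require_samples(rel.sample_ids)
    host = metadata.host_vars.loc[rel.sample_ids]
    if variables is not None:
        host = host[variables]
    if host.shape[1] == 0:
        raise PreconditionError("metadata carries no host variables")
    empty = [c for c in host.columns if host[c].notna().sum() == 0]
    if empty:
        warnings.warn(f"host variables with no data excluded: {empty}",
                      RuntimeWarning, stacklevel=2)
        host = host.drop(columns=empty)
    x = rel.values if taxa is None else rel.values.loc[taxa]
    table = spearman_matrix(x, host.T)
    table = table.rename(columns={"id_a": "taxon", "id_b": "variable"})
    table["significant"] = table["valid"] & (table["q"] < q_threshold)
    return table
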