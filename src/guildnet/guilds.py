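"""Co-abundance guild construction and group-level guild comparison.

A guild is a set of taxa whose abundances covary across samples.  The
procedure: keep prevalent taxa, estimate SparCC basis correlations, convert
them to a correlation distance d = 1 - rho, build a Ward minimum-variance
dendrogram, then divide the tree top-down — at every internal node a
PERMANOVA on the node's 1 - rho distance submatrix tests whether the two
child subtrees are separable, recursing while the permutation p-value stays
at or below alpha.  Every tested node is recorded in a division log so the
traversal is auditable.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, TransformerMixin

from .containers import CountTable, RelAbundanceTable, SampleMetadata, SymmetricMatrix
from .errors import ConfigurationError, PreconditionError
from .sparcc import sparcc
from .stats import bh_adjust, permanova

__all__ = ["Dendrogram", "GuildPartition", "prevalence_mask",
           "prevalence_filter", "ward_tree", "divide_tree",
           "guild_abundance", "guild_group_comparison", "guild_network",
           "GuildDetector"]

PAIRS = (("G3", "G2"), ("G2", "G1"), ("G3", "G1"))


def _stage_seed(seed: int | None, salt: str) -> int:
    digest = hashlib.sha256(f"{seed}:{salt}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2 ** 31)


# ---------------------------------------------------------------------------
# prevalence filtering

def prevalence_mask(ct: CountTable, min_prevalence: float = 0.2,
                    min_rel_abundance: float = 0.0) -> pd.Series:
    """Boolean per-taxon retention mask.

    A taxon is retained when its relative abundance is >= min_rel_abundance
    (and its count positive) in at least ceil(min_prevalence * n_samples)
    samples.  With min_rel_abundance = 0 the criterion is plain presence.
    """
    if not 0 < min_prevalence <= 1:
        raise PreconditionError("min_prevalence must lie in (0, 1]")
    if min_rel_abundance < 0:
        raise PreconditionError("min_rel_abundance must be >= 0")
    counts = ct.counts
    rel = counts / counts.sum(axis=0)
    hits = ((counts > 0) & (rel >= min_rel_abundance)).sum(axis=1)
    needed = int(np.ceil(min_prevalence * counts.shape[1]))
    return hits >= needed


def prevalence_filter(ct: CountTable, min_prevalence: float = 0.2,
                      min_rel_abundance: float = 0.0) -> CountTable | None:
    """Filtered table, or None when no taxon passes (explicit empty flag)."""
    mask = prevalence_mask(ct, min_prevalence, min_rel_abundance)
    if not mask.any():
        return None
    return ct.filter_taxa(mask.index[mask])


# ---------------------------------------------------------------------------
# Ward tree over the correlation distance

@dataclass
class Dendrogram:
    """Ward agglomeration over 1 - rho: scipy linkage matrix plus leaf ids."""

    ids: list[str]
    linkage: np.ndarray

    @property
    def n_leaves(self) -> int:
        return len(self.ids)


def ward_tree(rho: SymmetricMatrix) -> Dendrogram:
    """Ward minimum-variance clustering of taxa on d = 1 - rho.

    Taxa are sorted lexicographically before linkage so that equal-height
    merges break ties identically regardless of input order.
    """
    if rho.kind != "correlation":
        raise PreconditionError("ward_tree expects a correlation matrix")
    if rho.n < 2:
        raise PreconditionError("clustering needs at least 2 taxa")
    ids = sorted(rho.ids)
    dist = 1.0 - rho.submatrix(ids).values
    np.fill_diagonal(dist, 0.0)
    z = hierarchy.linkage(squareform(dist, checks=False), method="ward")
    return Dendrogram(ids=ids, linkage=z)


# ---------------------------------------------------------------------------
# PERMANOVA tree division

@dataclass
class GuildPartition:
    guild_of: dict[str, int]
    tree: Dendrogram
    division_log: pd.DataFrame
    guild_abundance: pd.DataFrame | None = None
    alpha: float = 0.001
    n_permutations: int = 9999

    @property
    def n_guilds(self) -> int:
        return len(set(self.guild_of.values()))

    def members(self, guild_id: int) -> list[str]:
        return sorted(t for t, g in self.guild_of.items() if g == guild_id)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"taxon_id": list(self.guild_of),
                             "guild": list(self.guild_of.values())}
                            ).sort_values(["guild", "taxon_id"]).reset_index(drop=True)


def divide_tree(tree: Dendrogram, rho_distance: SymmetricMatrix,
                n_perm: int = 9999, alpha: float = 0.001,
                seed: int | None = 0) -> GuildPartition:
    """Top-down PERMANOVA division of the Ward tree into guilds.

    At each internal node the two child memberships are compared with a
    PERMANOVA over the node's 1 - rho distance submatrix; the split is
    accepted when the permutation p-value is <= alpha (the add-one p has
    floor 1/(n_perm + 1), so alpha at that floor remains attainable) and the
    recursion continues into both children.  A node that fails the test is
    emitted whole as one guild; a child reached as a single taxon becomes a
    singleton guild.
    """
    if set(tree.ids) != set(rho_distance.ids):
        raise PreconditionError("tree and distance matrix ids differ")
    if rho_distance.kind != "distance":
        raise PreconditionError("divide_tree expects a distance matrix")
    if not 0 < alpha < 1:
        raise PreconditionError("alpha must lie in (0, 1)")
    if n_perm < 99:
        raise PreconditionError("n_perm must be at least 99")

    dist = rho_distance.submatrix(tree.ids)
    root, nodes = hierarchy.to_tree(tree.linkage, rd=True)
    leaves_of: dict[int, list[str]] = {}

    def leaves(node) -> list[str]:
        if node.id not in leaves_of:
            leaves_of[node.id] = [tree.ids[i] for i in node.pre_order(lambda x: x.id)]
        return leaves_of[node.id]

    guilds: list[list[str]] = []
    log_rows: list[dict] = []
    stack = [root]
    while stack:
        node = stack.pop()
        if node.is_leaf():
            guilds.append(leaves(node))
            continue
        members = leaves(node)
        left, right = leaves(node.left), leaves(node.right)
        labels = [0 if t in set(left) else 1 for t in members]
        sub = dist.submatrix(members)
        res = permanova(sub, labels, n_perm=n_perm,
                        seed=_stage_seed(seed, f"node{node.id}"),
                        _min_group_size=1)
        accepted = res.p_value <= alpha
        log_rows.append({"node_id": node.id, "n_taxa": len(members),
                         "n_left": len(left), "n_right": len(right),
                         "pseudo_F": res.statistic, "p_value": res.p_value,
                         "split_accepted": accepted})
        if accepted:
            stack.append(node.right)
            stack.append(node.left)
        else:
            guilds.append(members)

    guilds.sort(key=lambda g: min(g))
    guild_of = {t: gid for gid, members in enumerate(guilds, start=1)
                for t in members}
    log = pd.DataFrame(log_rows, columns=["node_id", "n_taxa", "n_left",
                                          "n_right", "pseudo_F", "p_value",
                                          "split_accepted"])
    return GuildPartition(guild_of=guild_of, tree=tree, division_log=log,
                          alpha=alpha, n_permutations=n_perm)


# ---------------------------------------------------------------------------
# guild abundance and group comparison

def guild_abundance(gp: GuildPartition, rel: RelAbundanceTable) -> pd.DataFrame:
    """Per-sample guild abundances: the sum of member relative abundances."""
    rows = {}
    for gid in sorted(set(gp.guild_of.values())):
        members = gp.members(gid)
        rows[gid] = rel.values.loc[members].sum(axis=0)
    out = pd.DataFrame(rows).T
    out.index.name = "guild"
    return out


def guild_group_comparison(gp: GuildPartition, rel: RelAbundanceTable,
                           metadata: SampleMetadata,
                           q_threshold: float = 0.05) -> pd.DataFrame:
    """Kruskal-Wallis across groups and pairwise Wilcoxon rank-sum per guild.

    BH adjustment is applied within each test family (the KW family and each
    pairwise family) across guilds.
    """
    abundance = guild_abundance(gp, rel)
    metadata.require_samples(abundance.columns)
    groups_present = sorted(metadata.groups.unique())
    if len(groups_present) < 2:
        raise ConfigurationError("need at least 2 groups for comparison")
    group_cols = {g: [s for s in abundance.columns
                      if metadata.groups[s] == g] for g in groups_present}

    rows = []
    for gid, values in abundance.iterrows():
        by_group = {g: values[cols].to_numpy() for g, cols in group_cols.items()}
        row: dict = {"guild": gid}
        for g, v in by_group.items():
            row[f"median_{g}"] = float(np.median(v))
        pooled = np.concatenate(list(by_group.values()))
        if np.allclose(pooled, pooled[0]):
            row["kw_p"] = 1.0
        else:
            row["kw_p"] = float(sps.kruskal(*by_group.values()).pvalue)
        for a, b in PAIRS:
            if a not in by_group or b not in by_group:
                continue
            both = np.concatenate([by_group[a], by_group[b]])
            if np.allclose(both, both[0]):
                row[f"p_{a}_{b}"] = 1.0
            else:
                row[f"p_{a}_{b}"] = float(sps.mannwhitneyu(
                    by_group[a], by_group[b], alternative="two-sided").pvalue)
        rows.append(row)
    table = pd.DataFrame(rows).set_index("guild")
    for col in [c for c in table.columns if c.startswith(("kw_p", "p_"))]:
        table[col.replace("p", "q", 1) if col.startswith("p_")
              else "kw_q"] = bh_adjust(table[col].to_numpy())
    table["significant"] = table["kw_q"] < q_threshold
    return table


def guild_network(rho: SymmetricMatrix, gp: GuildPartition,
                  rel: RelAbundanceTable,
                  edge_threshold: float = 0.70) -> nx.Graph:
    """Taxon network with edges where |rho| exceeds the drawing threshold.

    Nodes carry their mean relative abundance and guild id; taxa with no
    super-threshold edge are omitted from the drawn network (they stay in
    the partition).
    """
    if not 0 < edge_threshold < 1:
        raise PreconditionError("edge_threshold must lie in (0, 1)")
    mean_ab = rel.values.mean(axis=1)
    net = nx.Graph()
    ids = rho.ids
    v = rho.values
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if abs(v[i, j]) > edge_threshold:
                for t in (ids[i], ids[j]):
                    if t not in net:
                        net.add_node(t, mean_abundance=float(mean_ab.get(t, 0.0)),
                                     guild=int(gp.guild_of.get(t, -1)))
                net.add_edge(ids[i], ids[j], weight=float(v[i, j]),
                             sign="+" if v[i, j] > 0 else "-")
    return net


# ---------------------------------------------------------------------------
# estimator facade

class GuildDetector(BaseEstimator, TransformerMixin):
    """Feature-clustering estimator: counts in, guild labels and abundances out.

    ``fit(X)`` takes a samples x taxa count matrix, applies the prevalence
    filter, estimates SparCC correlations, builds the Ward tree on 1 - rho
    and divides it by PERMANOVA.  ``labels_`` assigns every input taxon a
    guild id (contiguous from 1) or -1 when the prevalence filter removed
    it.  ``transform(X)`` returns per-sample guild abundances (sums of the
    member relative abundances), in the manner of FeatureAgglomeration's
    pooling transform.
    """

    def __init__(self, min_prevalence: float = 0.2,
                 min_rel_abundance: float = 0.0, pseudocount: float = 0.5,
                 exclusion_threshold: float = 0.8,
                 max_exclusion_rounds: int = 10, n_permutations: int = 9999,
                 alpha: float = 0.001, random_state: int | None = None):
        self.min_prevalence = min_prevalence
        self.min_rel_abundance = min_rel_abundance
        self.pseudocount = pseudocount
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusion_rounds = max_exclusion_rounds
        self.n_permutations = n_permutations
        self.alpha = alpha
        self.random_state = random_state

    def _to_count_table(self, X) -> CountTable:
        if isinstance(X, pd.DataFrame):
            counts = X.T
        else:
            arr = np.asarray(X)
            if arr.ndim != 2:
                raise PreconditionError("X must be 2-dimensional")
            counts = pd.DataFrame(arr.T,
                                  index=[str(i) for i in range(arr.shape[1])],
                                  columns=[f"s{k}" for k in range(arr.shape[0])])
        return CountTable(counts)

    def fit(self, X, y=None):
        ct = self._to_count_table(X)
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray([str(c) for c in X.columns],
                                                dtype=object)
        self.n_features_in_ = ct.shape[0]
        filtered = prevalence_filter(ct, self.min_prevalence,
                                     self.min_rel_abundance)
        if filtered is None or filtered.shape[0] < 2:
            raise PreconditionError(
                "fewer than 2 taxa pass the prevalence filter")
        result = sparcc(filtered, pseudocount=self.pseudocount,
                        exclusion_threshold=self.exclusion_threshold,
                        max_exclusion_rounds=self.max_exclusion_rounds)
        dist = SymmetricMatrix(result.rho.ids,
                               _correlation_distance(result.rho.values),
                               "distance")
        tree = ward_tree(result.rho)
        seed = self.random_state if self.random_state is not None else 0
        partition = divide_tree(tree, dist, n_perm=self.n_permutations,
                                alpha=self.alpha, seed=seed)
        self.sparcc_result_ = result
        self.correlation_ = result.rho
        self.partition_ = partition
        self.division_log_ = partition.division_log
        self.n_guilds_ = partition.n_guilds
        labels = np.full(ct.shape[0], -1, dtype=int)
        pos = {t: i for i, t in enumerate(ct.taxon_ids)}
        for t, g in partition.guild_of.items():
            labels[pos[t]] = g
        self.labels_ = labels
        return self

    def transform(self, X) -> np.ndarray:
        if not hasattr(self, "partition_"):
            raise PreconditionError("GuildDetector is not fitted")
        ct = self._to_count_table(X)
        rel = ct.to_relative()
        abundance = guild_abundance(self.partition_, rel)
        return abundance.T.to_numpy()

    def get_feature_names_out(self, input_features=None):
        return np.asarray([f"guild{g}" for g in
                           sorted(set(self.partition_.guild_of.values()))],
                          dtype=object)


def _correlation_distance(rho_values: np.ndarray) -> np.ndarray:
    d = 1.0 - rho_values
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return d
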