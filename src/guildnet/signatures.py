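"""Differential abundance, bootstrap confirmation and trajectory signatures.

The trajectory of a taxon over the three age groups (G3 young, G2 elderly,
G1 centenarian) is summarised by the three pairwise Wilcoxon rank-sum tests
with BH adjustment.  The significance pattern classifies each taxon:

* rejuvenation - young and centenarian alike, elderly distinct
  (G3vG1 not significant, G2vG1 and G3vG2 significant);
* centenarian - young and elderly alike, centenarian distinct
  (G3vG2 not significant, G2vG1 and G3vG1 significant);
* monotone increase / decrease - consistent directional change with age;
* stable - no pairwise difference; * other - remaining patterns.

Differences flagged by the rank tests are re-confirmed by a bootstrap: 10
samples drawn with replacement from each group, the difference of mean
relative abundances recorded, 1000 times; the difference stands when the
central 90% interval excludes zero.  Stable heritable species are taxa
present in at least half of the multi-generation families with no
significant abundance change across the groups.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import RelAbundanceTable, SampleMetadata
from .errors import PreconditionError
from .stats import bh_adjust

__all__ = ["PAIRS", "CLASSES", "differential_abundance", "bootstrap_confirm",
           "classify_signatures", "signature_class", "stable_species"]

# (younger, older) ordering; direction +1 means larger in the older group
PAIRS = (("G3", "G2"), ("G2", "G1"), ("G3", "G1"))
CLASSES = ("rejuvenation", "centenarian", "monotone_increase",
           "monotone_decrease", "stable", "other")


def _pair_label(pair: tuple[str, str]) -> str:
    return f"{pair[0]}_{pair[1]}"


def _rank_sum_p(a: np.ndarray, b: np.ndarray) -> float:
    pooled = np.concatenate([a, b])
    if np.allclose(pooled, pooled[0]):
        return 1.0
    return float(sps.mannwhitneyu(a, b, alternative="two-sided").pvalue)


def differential_abundance(rel: RelAbundanceTable, metadata: SampleMetadata,
                           q_threshold: float = 0.05) -> pd.DataFrame:
    """Three pairwise Wilcoxon rank-sum tests per taxon, BH within each pair.

    Direction is the sign of (older-group median - younger-group median);
    a constant taxon gets p = 1 and direction 0.
    """
    metadata.require_samples(rel.sample_ids)
    cols = {g: [s for s in rel.sample_ids if metadata.groups[s] == g]
            for g in ("G1", "G2", "G3")}
    for g, samples in cols.items():
        if len(samples) < 3:
            raise PreconditionError(f"group {g} has fewer than 3 samples")

    values = rel.values
    rows = []
    for taxon in rel.taxon_ids:
        v = {g: values.loc[taxon, s].to_numpy() for g, s in cols.items()}
        row: dict = {"taxon": taxon}
        for g in ("G1", "G2", "G3"):
            row[f"median_{g}"] = float(np.median(v[g]))
            row[f"mean_{g}"] = float(np.mean(v[g]))
        for young, old in PAIRS:
            label = _pair_label((young, old))
            row[f"p_{label}"] = _rank_sum_p(v[young], v[old])
            diff = row[f"median_{old}"] - row[f"median_{young}"]
            row[f"dir_{label}"] = int(np.sign(diff))
        rows.append(row)
    table = pd.DataFrame(rows).set_index("taxon")
    for pair in PAIRS:
        label = _pair_label(pair)
        table[f"q_{label}"] = bh_adjust(table[f"p_{label}"].to_numpy())
        table[f"sig_{label}"] = table[f"q_{label}"] < q_threshold
    return table


def bootstrap_confirm(rel: RelAbundanceTable, metadata: SampleMetadata,
                      taxa: list[str] | None = None,
                      pair: tuple[str, str] = ("G3", "G1"),
                      n_boot: int = 1000, subsample_size: int = 10,
                      ci_level: float = 0.90,
                      seed: int | None = 0) -> pd.DataFrame:
    """Bootstrap confirmation of a pairwise mean-abundance difference.

    Per replicate, ``subsample_size`` samples are drawn with replacement
    from each group and the difference of the two subsample means
    (older minus younger) recorded; the difference is confirmed when the
    empirical central ``ci_level`` interval of the n_boot replicates
    excludes zero.
    """
    if not 0 < ci_level < 1:
        raise PreconditionError("ci_level must lie in (0, 1)")
    metadata.require_samples(rel.sample_ids)
    young, old = pair
    idx = {g: [s for s in rel.sample_ids if metadata.groups[s] == g]
           for g in (young, old)}
    for g, samples in idx.items():
        if len(samples) == 0:
            raise PreconditionError(f"group {g} has no samples")
        if len(samples) < 3:
            warnings.warn(f"group {g} has fewer than 3 samples; bootstrap "
                          "intervals will be unstable", RuntimeWarning,
                          stacklevel=2)
    taxa = list(taxa) if taxa is not None else rel.taxon_ids
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (1 - ci_level) / 2, 1 - (1 - ci_level) / 2
    x_young = rel.values.loc[taxa, idx[young]].to_numpy()
    x_old = rel.values.loc[taxa, idx[old]].to_numpy()

    rows = []
    for i, taxon in enumerate(taxa):
        draw_y = rng.integers(0, x_young.shape[1], (n_boot, subsample_size))
        draw_o = rng.integers(0, x_old.shape[1], (n_boot, subsample_size))
        diffs = x_old[i][draw_o].mean(axis=1) - x_young[i][draw_y].mean(axis=1)
        ci_low = float(np.quantile(diffs, lo_q))
        ci_high = float(np.quantile(diffs, hi_q))
        rows.append({"taxon": taxon, "pair": _pair_label(pair),
                     "ci_low": ci_low, "ci_high": ci_high,
                     "mean_diff": float(diffs.mean()),
                     "confirmed": ci_low > 0 or ci_high < 0,
                     "n_boot": n_boot, "subsample_size": subsample_size,
                     "ci_level": ci_level})
    return pd.DataFrame(rows).set_index("taxon")


def signature_class(sig_g3_g2: bool, sig_g2_g1: bool, sig_g3_g1: bool,
                    dir_g3_g2: int, dir_g2_g1: int, dir_g3_g1: int) -> str:
    """Trajectory class from the pairwise significance/direction pattern.

    Rules apply in priority order; exactly one class fires for any input.
    """
    if sig_g3_g2 and sig_g2_g1 and not sig_g3_g1:
        return "rejuvenation"
    if sig_g2_g1 and sig_g3_g1 and not sig_g3_g2:
        return "centenarian"
    if (sig_g3_g2 and sig_g2_g1 and dir_g3_g2 > 0 and dir_g2_g1 > 0) or \
            (sig_g3_g1 and not sig_g3_g2 and not sig_g2_g1 and dir_g3_g1 > 0):
        return "monotone_increase"
    if (sig_g3_g2 and sig_g2_g1 and dir_g3_g2 < 0 and dir_g2_g1 < 0) or \
            (sig_g3_g1 and not sig_g3_g2 and not sig_g2_g1 and dir_g3_g1 < 0):
        return "monotone_decrease"
    if not (sig_g3_g2 or sig_g2_g1 or sig_g3_g1):
        return "stable"
    return "other"


def classify_signatures(diff: pd.DataFrame,
                        q_threshold: float = 0.05) -> pd.DataFrame:
    """Assign every tested taxon its trajectory signature class."""
    out = diff.copy()
    classes = []
    for taxon, row in diff.iterrows():
        classes.append(signature_class(
            bool(row["q_G3_G2"] < q_threshold),
            bool(row["q_G2_G1"] < q_threshold),
            bool(row["q_G3_G1"] < q_threshold),
            int(row["dir_G3_G2"]), int(row["dir_G2_G1"]),
            int(row["dir_G3_G1"])))
    out["signature"] = classes
    return out


def stable_species(rel: RelAbundanceTable, metadata: SampleMetadata,
                   min_family_fraction: float = 0.5,
                   p_threshold: float = 0.05,
                   adjust: bool = False) -> pd.DataFrame:
    """Family-based stable-species rule.

    Eligible families have sampled members in at least two distinct age
    groups; a taxon is "present" in a family when any member carries it
    (relative abundance > 0).  A taxon is stable when present in at least
    ``min_family_fraction`` of the eligible families AND the Kruskal-Wallis
    test across the three groups shows no significant difference
    (p >= p_threshold; an absence-of-evidence criterion, by design
    unadjusted unless ``adjust=True``).
    """
    metadata.require_samples(rel.sample_ids)
    fam = metadata.family_ids.loc[rel.sample_ids]
    groups = metadata.groups.loc[rel.sample_ids]
    eligible = []
    for family in sorted(set(fam.dropna())):
        members = fam.index[fam == family]
        if groups[members].nunique() >= 2:
            eligible.append(family)
    if len(eligible) < 2:
        raise PreconditionError(
            "need at least 2 families sampled in 2 or more groups")

    group_cols = {g: list(groups.index[groups == g]) for g in
                  sorted(groups.unique())}
    rows = []
    for taxon in rel.taxon_ids:
        v = rel.values.loc[taxon]
        present = sum(1 for family in eligible
                      if (v[fam.index[fam == family]] > 0).any())
        frac = present / len(eligible)
        by_group = [v[s].to_numpy() for s in group_cols.values()]
        pooled = np.concatenate(by_group)
        if np.allclose(pooled, pooled[0]):
            kw_p = 1.0
        else:
            kw_p = float(sps.kruskal(*by_group).pvalue)
        rows.append({"taxon": taxon, "family_presence_fraction": frac,
                     "kw_p": kw_p})
    table = pd.DataFrame(rows).set_index("taxon")
    table["kw_q"] = bh_adjust(table["kw_p"].to_numpy())
    p_col = "kw_q" if adjust else "kw_p"
    table["stable"] = (table["family_presence_fraction"] >= min_family_fraction) \
        & (table[p_col] >= p_threshold)
    table.attrs["n_eligible_families"] = len(eligible)
    return table
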