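"""Permutation and diversity statistics implemented from first principles.

These primitives back every stage of the pipeline: alpha diversity (Shannon,
observed richness), Bray-Curtis dissimilarity with classical PCoA, the two
distance-matrix permutation tests (ANOSIM and PERMANOVA in Anderson's
formulation), mid-rank Spearman correlation with Benjamini-Hochberg
adjustment, and the shared add-one permutation p-value convention
``p = (1 + #{permuted >= observed}) / (1 + B)`` which can never be zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .containers import RelAbundanceTable, SymmetricMatrix
from .errors import PreconditionError

__all__ = [
    "PermutationTestResult", "PCoAResult", "shannon", "observed_richness",
    "diversity_table", "bray_curtis", "pcoa", "anosim", "permanova",
    "spearman_matrix", "bh_adjust",
]


# ---------------------------------------------------------------------------
# alpha diversity

def shannon(rel_column) -> float:
    """Shannon entropy H = -sum p_i ln p_i (natural log) of one composition."""
    p = np.asarray(rel_column, dtype=float)
    if np.any(p < 0):
        raise PreconditionError("relative abundances must be non-negative")
    if abs(p.sum() - 1.0) > 1e-9:
        raise PreconditionError("composition must sum to 1")
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def observed_richness(count_column) -> int:
    """Number of taxa observed (count > 0) in one sample."""
    c = np.asarray(count_column)
    if np.any(c < 0):
        raise PreconditionError("counts must be non-negative")
    return int((c > 0).sum())


def diversity_table(counts_df: pd.DataFrame) -> pd.DataFrame:
    """Per-sample Shannon index and observed richness from raw counts."""
    rel = counts_df / counts_df.sum(axis=0)
    return pd.DataFrame({
        "shannon": [shannon(rel[s]) for s in counts_df.columns],
        "observed_richness": [observed_richness(counts_df[s])
                              for s in counts_df.columns],
    }, index=pd.Index(counts_df.columns, name="sample_id"))


# ---------------------------------------------------------------------------
# beta diversity

def bray_curtis(rel: RelAbundanceTable) -> SymmetricMatrix:
    """Bray-Curtis dissimilarity between all sample pairs.

    d(u, v) = sum |u_i - v_i| / sum (u_i + v_i); on closed compositions the
    denominator is 2, so entries lie in [0, 1].
    """
    x = rel.values.to_numpy().T  # samples x taxa
    diff = np.abs(x[:, None, :] - x[None, :, :]).sum(axis=2)
    tot = (x[:, None, :] + x[None, :, :]).sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(tot > 0, diff / tot, 0.0)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    return SymmetricMatrix(rel.sample_ids, d, "distance")


@dataclass
class PCoAResult:
    """Classical-scaling ordination of a distance matrix."""

    coordinates: pd.DataFrame          # samples x retained axes
    eigenvalues: np.ndarray            # all eigenvalues, descending
    proportion_explained: np.ndarray   # relative to the positive spectrum
    truncated: bool = False            # True when fewer axes than requested


def pcoa(dist: SymmetricMatrix, k: int = 2) -> PCoAResult:
    """Principal coordinate analysis (Gower double-centring + eigh).

    Axes are ordered by descending eigenvalue; negative eigenvalues are
    reported in ``eigenvalues`` but their axes are never returned.
    """
    if dist.kind != "distance":
        raise PreconditionError("pcoa requires a distance matrix")
    if k < 1:
        raise PreconditionError("k must be >= 1")
    d2 = dist.values ** 2
    n = dist.n
    centre = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centre @ d2 @ centre
    eigval, eigvec = np.linalg.eigh((b + b.T) / 2.0)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    tol = max(abs(eigval[0]), 1.0) * 1e-10 if n else 0.0
    positive = eigval > tol
    n_pos = int(positive.sum())
    n_axes = min(k, n_pos)
    coords = eigvec[:, :n_axes] * np.sqrt(eigval[:n_axes])
    pos_sum = eigval[positive].sum()
    prop = np.where(positive, eigval / pos_sum, 0.0) if pos_sum > 0 else np.zeros(n)
    frame = pd.DataFrame(coords, index=dist.ids,
                         columns=[f"PCo{i+1}" for i in range(n_axes)])
    return PCoAResult(frame, eigval, prop, truncated=n_axes < k)


# ---------------------------------------------------------------------------
# distance-matrix permutation tests

@dataclass
class PermutationTestResult:
    statistic: float
    p_value: float
    n_permutations: int
    seed: int | None
    method: str = ""
    extras: dict = field(default_factory=dict)


def _group_codes(groups) -> tuple[np.ndarray, int]:
    codes, uniques = pd.factorize(np.asarray(list(groups)))
    return codes, len(uniques)


def _within_pair_sums(matrix: np.ndarray, label_rows: np.ndarray,
                      n_groups: int) -> np.ndarray:
    """Sum of matrix entries over unordered within-group pairs, per label row.

    ``label_rows`` is (B, n); the result is (B, n_groups).
    """
    out = np.empty((label_rows.shape[0], n_groups))
    for g in range(n_groups):
        mask = (label_rows == g).astype(float)
        out[:, g] = np.einsum("bi,ij,bj->b", mask, matrix, mask) / 2.0
    return out


def _multiset_permutations(codes: tuple[int, ...]):
    """All distinct arrangements of a label multiset, lexicographic order."""
    counts = {}
    for c in codes:
        counts[c] = counts.get(c, 0) + 1
    n = len(codes)
    out: list[int] = []

    def rec():
        if len(out) == n:
            yield tuple(out)
            return
        for c in sorted(counts):
            if counts[c]:
                counts[c] -= 1
                out.append(c)
                yield from rec()
                out.pop()
                counts[c] += 1

    yield from rec()


def _n_distinct_arrangements(codes: np.ndarray) -> int:
    from math import factorial
    total = factorial(len(codes))
    for size in np.bincount(codes):
        total //= factorial(int(size))
    return total


def _permutation_rows(codes: np.ndarray, n_perm: int,
                      rng: np.random.Generator) -> tuple[np.ndarray, bool]:
    """Label rows for the null distribution.

    When every distinct relabelling can be enumerated within the requested
    budget the test becomes exact: all arrangements except one instance of
    the observed labelling are used, so the add-one p equals the exhaustive
    proportion #{stat >= observed}/total.  Otherwise n_perm random shuffles.
    """
    total = _n_distinct_arrangements(codes)
    if total - 1 <= n_perm and len(codes) <= 12:
        observed = tuple(codes)
        rows = [p for p in _multiset_permutations(observed)]
        rows.remove(observed)
        return np.array(rows, dtype=codes.dtype), True
    tiled = np.tile(codes, (n_perm, 1))
    return rng.permuted(tiled, axis=1), False


def anosim(dist: SymmetricMatrix, groups, n_perm: int = 999,
           seed: int | None = 0) -> PermutationTestResult:
    """Analysis of similarities on ranked pairwise distances.

    R = (mean rank between - mean rank within) / (M/2) with M = n(n-1)/2,
    mid-ranks for ties; the null distribution comes from free label
    permutation.
    """
    codes, n_groups = _group_codes(groups)
    n = dist.n
    if len(codes) != n:
        raise PreconditionError("labels do not match the distance matrix")
    if n_groups < 2:
        raise PreconditionError("ANOSIM needs at least 2 groups")
    if np.min(np.bincount(codes)) < 2:
        raise PreconditionError("every group needs at least 2 samples")

    ranks_flat = sps.rankdata(dist.condensed())
    rank_matrix = np.zeros((n, n))
    rank_matrix[np.triu_indices(n, k=1)] = ranks_flat
    rank_matrix = rank_matrix + rank_matrix.T

    m_pairs = n * (n - 1) // 2
    sizes = np.bincount(codes, minlength=n_groups)
    n_within = int((sizes * (sizes - 1) // 2).sum())
    n_between = m_pairs - n_within
    total = ranks_flat.sum()

    def r_stat(label_rows: np.ndarray) -> np.ndarray:
        within = _within_pair_sums(rank_matrix, label_rows, n_groups).sum(axis=1)
        mean_w = within / n_within
        mean_b = (total - within) / n_between
        return (mean_b - mean_w) / (m_pairs / 2.0)

    observed = float(r_stat(codes[None, :])[0])
    rng = np.random.default_rng(seed)
    rows, exact = _permutation_rows(codes, n_perm, rng)
    perm_stats = r_stat(rows)
    p = (1.0 + np.sum(perm_stats >= observed - 1e-12)) / (1.0 + len(rows))
    return PermutationTestResult(observed, float(p), len(rows), seed,
                                 "anosim", {"exact": exact})


def permanova(dist: SymmetricMatrix, groups, n_perm: int = 999,
              seed: int | None = 0,
              _min_group_size: int = 2) -> PermutationTestResult:
    """Permutational multivariate ANOVA (pseudo-F on squared distances).

    SS_total = sum_{i<j} d_ij^2 / n; SS_within = sum_g sum_{i<j in g}
    d_ij^2 / n_g; pseudo-F = (SS_between/(a-1)) / (SS_within/(n-a)); the p
    value comes from unrestricted label permutation.
    """
    codes, n_groups = _group_codes(groups)
    n = dist.n
    if len(codes) != n:
        raise PreconditionError("labels do not match the distance matrix")
    if n_groups < 2:
        raise PreconditionError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(codes, minlength=n_groups)
    if np.min(sizes) < _min_group_size:
        raise PreconditionError(
            f"every group needs at least {_min_group_size} samples")

    d2 = dist.values ** 2
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    inv_sizes = 1.0 / sizes

    def pseudo_f(label_rows: np.ndarray) -> np.ndarray:
        within = _within_pair_sums(d2, label_rows, n_groups)
        ss_w = within @ inv_sizes
        ss_b = ss_total - ss_w
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_b / (n_groups - 1)) / (ss_w / (n - n_groups))
        f = np.where(ss_w <= 0, np.where(ss_b <= 1e-12, 0.0, np.inf), f)
        return f

    observed = float(pseudo_f(codes[None, :])[0])
    if ss_total <= 1e-12:  # all distances equal zero: nothing to test
        return PermutationTestResult(0.0, 1.0, n_perm, seed, "permanova")
    rng = np.random.default_rng(seed)
    rows, exact = _permutation_rows(codes, n_perm, rng)
    perm_stats = pseudo_f(rows)
    p = (1.0 + np.sum(perm_stats >= observed - 1e-12)) / (1.0 + len(rows))
    return PermutationTestResult(observed, float(p), len(rows), seed,
                                 "permanova", {"exact": exact})


# ---------------------------------------------------------------------------
# Spearman correlation with BH adjustment

_EXACT_MAX_N = 9
_perm_cache: dict[int, np.ndarray] = {}


def _all_permutations(n: int) -> np.ndarray:
    if n not in _perm_cache:
        _perm_cache[n] = np.array(list(itertools.permutations(range(n))),
                                  dtype=np.intp)
    return _perm_cache[n]


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc ** 2).sum() * (yc ** 2).sum())
    if denom == 0:
        return np.nan
    return float((xc * yc).sum() / denom)


def _spearman_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float, int]:
    """Mid-rank Spearman rho and two-sided p for one pair.

    Exact permutation enumeration for n <= 9 (accurate at the smallest group
    sizes the cohort design produces), t-approximation otherwise.
    """
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 5:
        return np.nan, np.nan, n
    rx, ry = sps.rankdata(x), sps.rankdata(y)
    rho = _pearson(rx, ry)
    if not np.isfinite(rho):
        return np.nan, np.nan, n
    if n <= _EXACT_MAX_N:
        perms = _all_permutations(n)
        ry_perm = ry[perms]
        rxc = rx - rx.mean()
        ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
        rho_perm = (ryc @ rxc) / denom
        p = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * sps.t.sf(abs(t), df=n - 2))
    return rho, min(p, 1.0), n


def spearman_matrix(x: pd.DataFrame, y: pd.DataFrame | None = None,
                    ) -> pd.DataFrame:
    """Spearman rho / p / BH-q for every variable pair.

    Rows of ``x`` (and ``y``) are variables, columns are shared observations.
    With ``y=None`` all unordered pairs of ``x`` rows are tested; otherwise
    every (x row, y row) pair.  Missing values are dropped pairwise; pairs
    with fewer than 5 complete observations or a constant vector are flagged
    ``valid=False`` and excluded from the BH family.
    """
    if y is None:
        ids = list(x.index)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]
        get = {i: x.loc[i].to_numpy(dtype=float) for i in ids}
        get_b = get
    else:
        shared = [c for c in x.columns if c in y.columns]
        x, y = x[shared], y[shared]
        pairs = [(a, b) for a in x.index for b in y.index]
        get = {i: x.loc[i].to_numpy(dtype=float) for i in x.index}
        get_b = {i: y.loc[i].to_numpy(dtype=float) for i in y.index}

    rows = []
    for a, b in pairs:
        rho, p, n = _spearman_pair(get[a], get_b[b])
        rows.append({"id_a": a, "id_b": b, "rho": rho, "p": p, "n": n,
                     "valid": np.isfinite(rho)})
    table = pd.DataFrame(rows, columns=["id_a", "id_b", "rho", "p", "n", "valid"])
    table["q"] = np.nan
    if table["valid"].any():
        mask = table["valid"].to_numpy()
        table.loc[mask, "q"] = bh_adjust(table.loc[mask, "p"].to_numpy())
    return table


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} p_(j) * m / j, capped at 1; invariant to input
    ordering and never smaller than the raw p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise PreconditionError("p must be a 1-d vector")
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise PreconditionError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
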