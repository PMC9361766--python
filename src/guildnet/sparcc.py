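"""SparCC: basis correlations of absolute abundances from compositional counts.

Relative abundances are closed (columns sum to 1), so naive correlations
between taxa are distorted by the shared denominator.  SparCC instead works
from the variances of pairwise log-ratios, which are invariant to closure:

    t_ij = Var_k[ ln(x_i / x_j) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j)

where w_i is the (unobserved) basis variance of taxon i on the log scale and
rho_ij the basis correlation we want.  Under the sparsity assumption that
correlations average out (sum_j rho_ij sqrt(w_i w_j) ~ 0), summing over j
gives a linear system for the basis variances,

    Lambda w = t 1,   Lambda = (D - 2) I + 1 1^T,   D = number of taxa,

from which rho_ij = (w_i + w_j - t_ij) / (2 sqrt(w_i w_j)).  Strongly
correlated pairs violate the sparsity assumption, so the estimator
iteratively removes the most correlated pair from the row sums and the
system and re-solves until no |rho| exceeds the exclusion threshold.

Exposed both as functions (:func:`log_ratio_variances`, :func:`solve_basis`,
:func:`sparcc`) and as the scikit-learn style estimator :class:`SparCC`
(``fit(X)`` with samples as rows, taxa as columns, in the manner of the
covariance estimators).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .containers import CountTable, SymmetricMatrix
from .errors import PreconditionError

__all__ = ["SparccResult", "log_ratio_variances", "solve_basis", "sparcc",
           "SparCC"]


@dataclass
class SparccResult:
    """Outcome of a SparCC estimation over the retained taxa."""

    rho: SymmetricMatrix                       # kind="correlation"
    basis_variance: pd.Series                  # w_i per taxon, > 0
    n_iterations: int                          # exclusion rounds performed
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)
    pseudocount: float = 0.5
    converged: bool = True
    n_clipped: int = 0                         # |rho| > 1 clip events


def _counts_frame(counts) -> pd.DataFrame:
    if isinstance(counts, CountTable):
        return counts.counts.astype(float)
    return pd.DataFrame(counts).astype(float)


def log_ratio_variances(counts, pseudocount: float = 0.5) -> SymmetricMatrix:
    """Sample variances t_ij of ln(x_i / x_j) over samples.

    Counts get the pseudocount added before closure so zeros never reach the
    logarithm.  The result is symmetric with an exactly zero diagonal.
    """
    if pseudocount <= 0:
        raise PreconditionError("pseudocount must be > 0")
    df = _counts_frame(counts)
    if df.shape[1] < 4:
        raise PreconditionError("log-ratio variances need at least 4 samples")
    x = df.to_numpy() + pseudocount
    frac = x / x.sum(axis=0, keepdims=True)
    log_frac = np.log(frac)
    # Var(L_i - L_j) = v_i + v_j - 2 cov_ij, computed once from the row
    # covariance instead of a per-pair loop.
    cov = np.cov(log_frac, ddof=1)
    cov = np.atleast_2d(cov)
    v = np.diag(cov)
    t = v[:, None] + v[None, :] - 2.0 * cov
    t = (t + t.T) / 2.0
    np.fill_diagonal(t, 0.0)
    t = np.maximum(t, 0.0)
    return SymmetricMatrix(list(df.index), t, "distance")


def solve_basis(t: SymmetricMatrix, exclusion_threshold: float = 0.8,
                max_exclusion_rounds: int = 10,
                pseudocount: float = 0.5) -> SparccResult:
    """Solve the basis-variance system and apply iterative pair exclusion."""
    ids = t.ids
    d = t.n
    if d < 3:
        raise PreconditionError("the basis system needs at least 3 taxa")
    tv = t.values
    m = np.ones((d, d)) + (d - 2.0) * np.eye(d)
    row_sum = tv.sum(axis=1)
    excluded: list[tuple[int, int]] = []
    excluded_mask = np.zeros((d, d), dtype=bool)
    converged = True
    n_clipped = 0

    def solve_once():
        w = np.linalg.solve(m, row_sum)
        w_floor = np.maximum(w, 1e-12)
        denom = 2.0 * np.sqrt(np.outer(w_floor, w_floor))
        rho = (w_floor[:, None] + w_floor[None, :] - tv) / denom
        np.fill_diagonal(rho, 1.0)
        return w, np.asarray((rho + rho.T) / 2.0)

    w, rho = solve_once()
    rounds = 0
    if d >= 4:
        for rounds in range(1, max_exclusion_rounds + 1):
            candidates = np.abs(rho.copy())
            np.fill_diagonal(candidates, 0.0)
            candidates[excluded_mask] = 0.0
            i, j = np.unravel_index(np.argmax(candidates), candidates.shape)
            if candidates[i, j] <= exclusion_threshold:
                rounds -= 1
                break
            excluded.append((min(i, j), max(i, j)))
            excluded_mask[i, j] = excluded_mask[j, i] = True
            m[i, i] -= 1.0
            m[j, j] -= 1.0
            m[i, j] -= 1.0
            m[j, i] -= 1.0
            row_sum[i] -= tv[i, j]
            row_sum[j] -= tv[i, j]
            retained = int(np.sum(~excluded_mask.all(axis=1)))
            if retained < 4 or np.any(np.diag(m) <= 0):
                converged = False
                break
            try:
                w, rho = solve_once()
            except np.linalg.LinAlgError:
                converged = False
                break
        else:
            converged = not (np.abs(rho) - np.eye(d) > exclusion_threshold).any()

    over = np.abs(rho) > 1.0
    n_clipped = int(over.sum() // 2)
    if n_clipped:
        warnings.warn(f"clipped {n_clipped} basis correlations to [-1, 1]",
                      RuntimeWarning, stacklevel=2)
    rho = np.clip(rho, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    return SparccResult(
        rho=SymmetricMatrix(ids, rho, "correlation"),
        basis_variance=pd.Series(np.maximum(w, 1e-12), index=ids, name="w"),
        n_iterations=rounds,
        excluded_pairs=[(ids[i], ids[j]) for i, j in excluded],
        pseudocount=pseudocount,
        converged=converged,
        n_clipped=n_clipped,
    )


def sparcc(counts, pseudocount: float = 0.5, exclusion_threshold: float = 0.8,
           max_exclusion_rounds: int = 10, n_restarts: int = 1,
           seed: int | None = 0) -> SparccResult:
    """Full SparCC estimate from a count table.

    With ``n_restarts == 1`` (default) the estimate is deterministic:
    fractions are (counts + pseudocount) closed per sample.  With more
    restarts, per-sample fractions are re-drawn from a
    Dirichlet(counts + pseudocount) posterior each time and the correlation
    estimates are averaged; exclusion bookkeeping then comes from the
    deterministic pass.
    """
    df = _counts_frame(counts)
    t = log_ratio_variances(df, pseudocount)
    base = solve_basis(t, exclusion_threshold, max_exclusion_rounds, pseudocount)
    if n_restarts <= 1:
        return base
    rng = np.random.default_rng(seed)
    acc = np.zeros_like(base.rho.values)
    alpha = df.to_numpy() + pseudocount
    for _ in range(n_restarts):
        frac = np.empty_like(alpha)
        for k in range(alpha.shape[1]):
            frac[:, k] = rng.dirichlet(alpha[:, k])
        log_frac = np.log(frac)
        cov = np.atleast_2d(np.cov(log_frac, ddof=1))
        v = np.diag(cov)
        tv = v[:, None] + v[None, :] - 2.0 * cov
        tv = np.maximum((tv + tv.T) / 2.0, 0.0)
        np.fill_diagonal(tv, 0.0)
        res = solve_basis(SymmetricMatrix(list(df.index), tv, "distance"),
                          exclusion_threshold, max_exclusion_rounds, pseudocount)
        acc += res.rho.values
    rho = np.clip(acc / n_restarts, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    rho = (rho + rho.T) / 2.0
    return SparccResult(
        rho=SymmetricMatrix(list(df.index), rho, "correlation"),
        basis_variance=base.basis_variance,
        n_iterations=base.n_iterations,
        excluded_pairs=base.excluded_pairs,
        pseudocount=pseudocount,
        converged=base.converged,
        n_clipped=base.n_clipped,
    )


class SparCC(BaseEstimator):
    """Basis-correlation estimator with the covariance-estimator interface.

    Parameters
    ----------
    pseudocount : float, default 0.5
        Added to every count before closure.
    exclusion_threshold : float, default 0.8
        |rho| above which the strongest pair is removed from the sparsity
        system and the basis variances re-solved.
    max_exclusion_rounds : int, default 10
    n_restarts : int, default 1
        >1 averages correlations over Dirichlet-resampled fractions.
    random_state : int or None
        Seed for the resampling; unused when ``n_restarts == 1``.

    Attributes
    ----------
    correlation_ : ndarray (n_features, n_features)
    basis_variance_ : ndarray (n_features,)
    excluded_pairs_ : list of (int, int) feature-index pairs
    n_iterations_ : int
    converged_ : bool
    """

    def __init__(self, pseudocount: float = 0.5,
                 exclusion_threshold: float = 0.8,
                 max_exclusion_rounds: int = 10, n_restarts: int = 1,
                 random_state: int | None = None):
        self.pseudocount = pseudocount
        self.exclusion_threshold = exclusion_threshold
        self.max_exclusion_rounds = max_exclusion_rounds
        self.n_restarts = n_restarts
        self.random_state = random_state

    def fit(self, X, y=None):
        """Estimate basis correlations from X (samples x taxa, counts)."""
        if isinstance(X, pd.DataFrame):
            names = [str(c) for c in X.columns]
            arr = X.to_numpy(dtype=float)
            self.feature_names_in_ = np.asarray(names, dtype=object)
        else:
            arr = np.asarray(X, dtype=float)
            if arr.ndim != 2:
                raise PreconditionError("X must be 2-dimensional")
            names = [str(i) for i in range(arr.shape[1])]
        if np.any(arr < 0) or np.any(~np.isfinite(arr)):
            raise PreconditionError("counts must be finite and non-negative")
        self.n_features_in_ = arr.shape[1]
        counts = pd.DataFrame(arr.T, index=names)
        result = sparcc(counts, self.pseudocount, self.exclusion_threshold,
                        self.max_exclusion_rounds, self.n_restarts,
                        self.random_state if self.random_state is not None else 0)
        pos = {t: i for i, t in enumerate(names)}
        self.correlation_ = result.rho.values
        self.basis_variance_ = result.basis_variance.to_numpy()
        self.excluded_pairs_ = [(pos[a], pos[b]) for a, b in result.excluded_pairs]
        self.n_iterations_ = result.n_iterations
        self.converged_ = result.converged
        self.result_ = result
        return self
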