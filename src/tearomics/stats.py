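"""Self-contained implementations of the generic statistics the pipeline uses.

Each function is a pure computation on plain numpy/pandas inputs: Welch's t
from group summaries, two-sided Fisher's exact test by hypergeometric
enumeration, Pearson chi-squared on 2x2 tables, Benjamini-Hochberg step-up
adjustment, the Shannon diversity index, PCA via SVD, and PERMANOVA on a
distance matrix.  They are deliberately dependency-light so the rest of the
package (and its tests) can treat them as a reference surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from scipy.special import xlogy

__all__ = [
    "TwoSampleSummary",
    "ContingencyTable2x2",
    "PermanovaResult",
    "welch_t_test",
    "two_sample_summary",
    "fisher_exact_2x2",
    "pearson_chi2_2x2",
    "bh_adjust",
    "shannon_index",
    "pca",
    "permanova",
]


@dataclass(frozen=True)
class TwoSampleSummary:
    """Sufficient statistics for a two-group mean comparison."""

    n1: int
    n2: int
    mean1: float
    mean2: float
    var1: float
    var2: float

    def __post_init__(self) -> None:
        if self.n1 < 2 or self.n2 < 2:
            raise ValueError("each group needs n >= 2")
        if self.var1 < 0 or self.var2 < 0:
            raise ValueError("variances must be non-negative")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """2x2 count table; rows = groups, columns = positive/negative."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        cells = (self.a, self.b, self.c, self.d)
        if any(x < 0 or x != int(x) for x in cells):
            raise ValueError("cell counts must be non-negative integers")
        if sum(cells) == 0:
            raise ValueError("at least one margin must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    ss_between: float
    ss_within: float


def two_sample_summary(x1, x2) -> TwoSampleSummary:
    """Summarize two raw samples (ddof=1 variances) for :func:`welch_t_test`."""
    x1 = np.asarray(x1, dtype=float)
    x2 = np.asarray(x2, dtype=float)
    return TwoSampleSummary(
        n1=len(x1), n2=len(x2),
        mean1=float(np.mean(x1)), mean2=float(np.mean(x2)),
        var1=float(np.var(x1, ddof=1)), var2=float(np.var(x2, ddof=1)),
    )


def welch_t_test(s: TwoSampleSummary) -> tuple[float, float, float]:
    """Welch's unequal-variance t test from group summaries.

    Returns ``(t, df, p)`` with t = (mean2 - mean1) / sqrt(var1/n1 + var2/n2)
    and Welch-Satterthwaite degrees of freedom.  Degenerate zero-variance
    inputs follow the convention p = 1 for identical means, p = 0 (with a
    warning) for different means.
    """
    se2 = s.var1 / s.n1 + s.var2 / s.n2
    if se2 == 0.0:
        if s.mean1 == s.mean2:
            return 0.0, float(s.n1 + s.n2 - 2), 1.0
        warnings.warn("zero variance in both groups with unequal means; p = 0")
        return np.inf if s.mean2 > s.mean1 else -np.inf, float(s.n1 + s.n2 - 2), 0.0
    t = (s.mean2 - s.mean1) / np.sqrt(se2)
    df = se2**2 / (
        (s.var1 / s.n1) ** 2 / (s.n1 - 1) + (s.var2 / s.n2) ** 2 / (s.n2 - 1)
    )
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(min(p, 1.0))


def fisher_exact_2x2(t: ContingencyTable2x2) -> float:
    """Two-sided Fisher's exact test by full hypergeometric enumeration.

    With margins fixed, the first cell ``a`` follows a hypergeometric law;
    the two-sided p-value sums the probabilities of every table whose
    probability does not exceed that of the observed table (relative tie
    tolerance 1e-7).
    """
    a, b, c, d = t.a, t.b, t.c, t.d
    row1, row2 = a + b, c + d
    col1 = a + c
    n = row1 + row2
    if row1 == 0 or row2 == 0 or col1 == 0 or (b + d) == 0:
        return 1.0
    lo = max(0, col1 - row2)
    hi = min(row1, col1)
    support = np.arange(lo, hi + 1)
    pmf = sps.hypergeom.pmf(support, n, row1, col1)
    p_obs = pmf[support == a][0]
    include = pmf <= p_obs * (1.0 + 1e-7)
    if include.all():
        return 1.0
    return min(float(pmf[include].sum()), 1.0)


def pearson_chi2_2x2(t: ContingencyTable2x2, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-squared test of independence on a 2x2 table (df = 1).

    ``yates`` applies the continuity correction.  All four expected counts
    must be positive.
    """
    obs = t.as_array().astype(float)
    n = obs.sum()
    expected = np.outer(obs.sum(axis=1), obs.sum(axis=0)) / n
    if (expected <= 0).any():
        i, j = np.argwhere(expected <= 0)[0]
        raise ValueError(f"zero expected count in cell ({i}, {j})")
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    chi2 = float((diff**2 / expected).sum())
    p = float(sps.chi2.sf(chi2, df=1))
    return chi2, p


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up FDR adjustment, returned in input order.

    q_(i) = min over j >= i of p_(j) * m / j, capped at 1.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be 1-dimensional")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def shannon_index(abundances) -> float:
    """Shannon entropy H = -sum p_i ln p_i of one composition (natural log).

    Abundances are renormalized, zeros contribute nothing; an all-zero
    sample is an error.
    """
    x = np.asarray(abundances, dtype=float)
    if np.any(x < 0):
        raise ValueError("abundances must be non-negative")
    total = x.sum()
    if total <= 0:
        raise ValueError("all-zero sample has no diversity")
    p = x / total
    return float(-xlogy(p, p).sum())


def pca(X, scale: bool = False) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a samples x features matrix via SVD of the centered data.

    Zero-variance features are dropped before (optional) unit scaling.
    Returns ``(scores, loadings, explained_variance_ratio)``; loadings are
    features x components.  Sign convention: the largest-magnitude loading
    of each component is made positive.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with >= 2 samples")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if keep.sum() < 2:
        raise ValueError("fewer than 2 features with nonzero variance")
    Xc = X[:, keep] - X[:, keep].mean(axis=0)
    if scale:
        Xc = Xc / sd[keep]
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    # fix signs: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    scores = U * S
    var = S**2
    evr = var / var.sum() if var.sum() > 0 else var
    loadings_kept = Vt.T
    loadings = np.zeros((X.shape[1], Vt.shape[0]))
    loadings[keep] = loadings_kept
    return scores, loadings, evr


def _ss_decomposition(d2: np.ndarray, codes: np.ndarray, n_groups: int):
    """Total/within sums of squared distances from squared-distance matrix."""
    n = d2.shape[0]
    ss_total = d2[np.triu_indices(n, k=1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ng = len(idx)
        sub = d2[np.ix_(idx, idx)]
        ss_within += sub[np.triu_indices(ng, k=1)].sum() / ng
    return ss_total, ss_within


def permanova(D, labels, n_perm: int = 1000, seed: int | None = 0) -> PermanovaResult:
    """One-way PERMANOVA: permutation test of group separation on distances.

    pseudo-F = (SS_between / (a-1)) / (SS_within / (n-a)) with
    SS_total = (1/n) sum_{i<j} d_ij^2 and SS_within the analogous per-group
    sums; the p-value uses the add-one permutation formula
    (#{F_perm >= F_obs} + 1) / (n_perm + 1), so p >= 1/(n_perm+1).
    """
    D = np.asarray(D, dtype=float)
    n = D.shape[0]
    if D.ndim != 2 or D.shape[1] != n:
        raise ValueError("D must be square")
    if not np.allclose(D, D.T, atol=1e-8):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-8):
        raise ValueError("distance matrix must have zero diagonal")
    labels = np.asarray(labels)
    if len(labels) != n:
        raise ValueError("labels length must match D")
    uniq, codes = np.unique(labels, return_inverse=True)
    a = len(uniq)
    if a < 2:
        raise ValueError("need >= 2 groups")
    counts = np.bincount(codes)
    if (counts < 2).any():
        raise ValueError("every group needs >= 2 members")

    d2 = D**2
    ss_total, ss_within = _ss_decomposition(d2, codes, a)
    ss_between = ss_total - ss_within
    f_obs = (ss_between / (a - 1)) / (ss_within / (n - a))

    rng = np.random.default_rng(seed)
    perms = np.empty((n_perm, n), dtype=np.int64)
    for i in range(n_perm):
        perms[i] = rng.permutation(codes)
    # einsum over group indicators: within-group SS for all permutations at once
    ss_within_perm = np.zeros(n_perm)
    for g in range(a):
        Z = (perms == g).astype(float)
        ss_within_perm += (np.einsum("pi,ij,pj->p", Z, d2, Z) / 2.0) / counts[g]
    ss_between_perm = ss_total - ss_within_perm
    f_perm = (ss_between_perm / (a - 1)) / (ss_within_perm / (n - a))
    p = (np.count_nonzero(f_perm >= f_obs) + 1) / (n_perm + 1)

    return PermanovaResult(
        pseudo_F=float(f_obs),
        p_value=float(p),
        n_permutations=n_perm,
        ss_between=float(ss_between),
        ss_within=float(ss_within),
    )
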