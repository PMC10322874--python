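"""Group-comparison statistics for community CAZyme profiles.

Covers the comparative toolkit used on sample x family abundance matrices:
Wilcoxon-Mann-Whitney rank-sum tests (exact by enumeration for small
tie-free samples, tie-corrected normal approximation otherwise),
Benjamini-Hochberg screening of per-family differences, Bray-Curtis
dissimilarity, classical principal-coordinates analysis, and PERMANOVA with
seeded label permutations.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import norm, rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "WilcoxonResult",
    "wilcoxon_rank_sum",
    "wilcoxon_screen",
    "bray_curtis",
    "PCoAResult",
    "pcoa",
    "GroupDesign",
    "PermanovaResult",
    "permanova",
]


# ---------------------------------------------------------------------------
# Wilcoxon-Mann-Whitney
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WilcoxonResult:
    U: float
    p_value: float
    method: str  # "exact" or "asymptotic"


def _exact_u_counts(n: int, m: int) -> np.ndarray:
    """Number of rank arrangements giving each Mann-Whitney U value.

    ``counts[u]`` is the number of ways to choose the ``n`` ranks of x out of
    ``n + m`` so that U(x) = u; computed by the classic recursion
    f(n, m, u) = f(n-1, m, u-m) + f(n, m-1, u), independent of the
    brute-force enumeration used to test it.
    """
    table: dict[tuple[int, int], np.ndarray] = {}

    def f(a: int, b: int) -> np.ndarray:
        if (a, b) in table:
            return table[(a, b)]
        if a == 0 or b == 0:
            out = np.zeros(a * b + 1 if a * b else 1, dtype=np.int64)
            out[0] = 1
        else:
            out = np.zeros(a * b + 1, dtype=np.int64)
            fa = f(a - 1, b)  # largest item is an x: contributes b to U
            out[b : b + fa.size] += fa
            fb = f(a, b - 1)  # largest item is a y: contributes 0
            out[: fb.size] += fb
        table[(a, b)] = out
        return out

    return f(n, m)


def wilcoxon_rank_sum(
    x: Sequence[float],
    y: Sequence[float],
    alternative: str = "two-sided",
    exact_limit: int = 12,
) -> WilcoxonResult:
    """Wilcoxon-Mann-Whitney rank-sum test.

    Uses the exact null distribution of U (all ``C(n+m, n)`` rank
    arrangements) when ``n + m <= exact_limit`` and there are no ties;
    otherwise the normal approximation with mid-ranks, tie-corrected variance
    and a 0.5 continuity correction. The two-sided exact p is
    ``min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    n, m = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)  # mid-ranks for ties
    U = float(ranks[:n].sum() - n * (n + 1) / 2.0)
    has_ties = np.unique(combined).size < combined.size

    if n + m <= exact_limit and not has_ties:
        counts = _exact_u_counts(n, m).astype(float)
        total = counts.sum()
        u = int(round(U))
        cdf = counts[: u + 1].sum() / total
        sf = counts[u:].sum() / total
        if alternative == "two-sided":
            p = min(1.0, 2.0 * min(cdf, sf))
        elif alternative == "greater":
            p = sf
        else:
            p = cdf
        return WilcoxonResult(U=U, p_value=float(p), method="exact")

    N = n + m
    mu = n * m / 2.0
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (N * (N - 1))
    sigma2 = n * m / 12.0 * ((N + 1) - tie_term)
    sigma = np.sqrt(sigma2)
    if sigma == 0:
        # all observations identical: no evidence of a shift either way
        return WilcoxonResult(U=U, p_value=1.0, method="asymptotic")
    if alternative == "two-sided":
        z = (abs(U - mu) - 0.5) / sigma
        p = min(1.0, 2.0 * norm.sf(z))
    elif alternative == "greater":
        p = norm.sf((U - mu - 0.5) / sigma)
    else:
        p = norm.cdf((U - mu + 0.5) / sigma)
    return WilcoxonResult(U=U, p_value=float(p), method="asymptotic")


def wilcoxon_screen(
    matrix: pd.DataFrame,
    design: Mapping[str, str],
    alpha: float = 0.05,
    exact_limit: int = 12,
) -> pd.DataFrame:
    """Per-feature two-group Wilcoxon screen with Benjamini-Hochberg control.

    ``matrix`` is samples x features; ``design`` maps each sample to one of
    exactly two group labels. Returns a DataFrame indexed by feature with U,
    raw p, BH-adjusted q, the direction of the difference (sign of the median
    shift, group1 - group2) and a boolean ``significant`` column at ``alpha``.
    """
    groups = sorted(set(design[s] for s in matrix.index))
    if len(groups) != 2:
        raise ValueError(f"wilcoxon_screen needs exactly 2 groups, got {groups}")
    g1 = [s for s in matrix.index if design[s] == groups[0]]
    g2 = [s for s in matrix.index if design[s] == groups[1]]
    rows = []
    for feat in matrix.columns:
        x = matrix.loc[g1, feat].to_numpy()
        y = matrix.loc[g2, feat].to_numpy()
        res = wilcoxon_rank_sum(x, y, exact_limit=exact_limit)
        rows.append(
            {
                "feature": feat,
                "U": res.U,
                "p": res.p_value,
                "method": res.method,
                "direction": float(np.sign(np.median(x) - np.median(y))),
            }
        )
    out = pd.DataFrame(rows).set_index("feature")
    reject, q, _, _ = multipletests(out["p"].to_numpy(), alpha=alpha, method="fdr_bh")
    out["q"] = q
    out["significant"] = reject
    out.attrs["groups"] = tuple(groups)
    out.attrs["alpha"] = alpha
    return out


# ---------------------------------------------------------------------------
# Bray-Curtis
# ---------------------------------------------------------------------------

def bray_curtis(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Bray-Curtis dissimilarity between matrix rows (samples).

    ``d(x, y) = sum |x - y| / sum (x + y)``, in [0, 1]. Undefined between two
    all-zero rows, which is an error.
    """
    values = np.asarray(matrix, dtype=float)
    if values.ndim != 2 or values.shape[0] < 2:
        raise ValueError("bray_curtis needs a 2-D matrix with >= 2 rows")
    if np.any(values < 0):
        raise ValueError("bray_curtis requires non-negative values")
    zero_rows = np.flatnonzero(values.sum(axis=1) == 0)
    if zero_rows.size >= 2:
        labels = [matrix.index[i] for i in zero_rows] if hasattr(matrix, "index") else list(zero_rows)
        raise ValueError(f"dissimilarity undefined between all-zero rows: {labels}")
    dm = squareform(pdist(values, metric="braycurtis"))
    labels = list(matrix.index) if hasattr(matrix, "index") else list(range(values.shape[0]))
    return pd.DataFrame(dm, index=labels, columns=labels)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PCoAResult:
    coordinates: pd.DataFrame  # samples x axes (positive-eigenvalue axes only)
    eigenvalues: np.ndarray  # all eigenvalues, descending
    proportion_explained: np.ndarray  # per retained axis
    negative_eigenvalues: np.ndarray  # reported, axes dropped


def _check_distance_matrix(dm: pd.DataFrame) -> np.ndarray:
    D = np.asarray(dm, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distance matrix must be square")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if not np.allclose(np.diag(D), 0.0, atol=1e-9):
        raise ValueError("distance matrix must have a zero diagonal")
    return D


def pcoa(dm: pd.DataFrame, k: Optional[int] = None) -> PCoAResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Double-centers ``-0.5 * D**2`` and eigendecomposes; axes are ordered by
    descending eigenvalue and scaled by ``sqrt(eigenvalue)``. Axes with
    negative eigenvalues (non-Euclidean input) are dropped from the
    embedding but their eigenvalues are reported.
    """
    D = _check_distance_matrix(dm)
    N = D.shape[0]
    A = -0.5 * D**2
    J = np.eye(N) - np.ones((N, N)) / N
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-9 * abs(eigvals[0])) if eigvals.size else 0.0
    pos = eigvals > tol
    neg = eigvals[eigvals < -tol]
    lam = eigvals[pos]
    V = eigvecs[:, pos]
    if k is not None:
        lam, V = lam[:k], V[:, :k]
    coords = V * np.sqrt(lam)[None, :]
    labels = list(dm.index) if hasattr(dm, "index") else list(range(N))
    axes = [f"PC{i + 1}" for i in range(coords.shape[1])]
    pos_sum = eigvals[pos].sum()
    prop = lam / pos_sum if pos_sum > 0 else np.zeros_like(lam)
    return PCoAResult(
        coordinates=pd.DataFrame(coords, index=labels, columns=axes),
        eigenvalues=eigvals,
        proportion_explained=prop,
        negative_eigenvalues=neg,
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

GroupDesign = Mapping[str, str]


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    R2: float
    p_value: float
    n_permutations: int
    seed: int


def _ss_within(D2: np.ndarray, labels: np.ndarray, groups: np.ndarray) -> float:
    ss = 0.0
    for g in groups:
        idx = np.flatnonzero(labels == g)
        ss += D2[np.ix_(idx, idx)].sum() / (2.0 * idx.size)
    return ss


def permanova(
    dm: pd.DataFrame,
    design: GroupDesign,
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA on a distance matrix (Anderson's pseudo-F).

    ``SS_total = sum_{i<j} d_ij^2 / N``; ``SS_within`` sums the within-group
    pair terms weighted by group size; ``pseudo-F = (SS_between / (a - 1)) /
    (SS_within / (N - a))``. The p-value is ``(1 + #{F_perm >= F_obs}) /
    (1 + n_permutations)`` under free permutation of group labels, seeded for
    reproducibility. Every group needs >= 2 samples.
    """
    D = _check_distance_matrix(dm)
    sample_ids = list(dm.index) if hasattr(dm, "index") else list(range(D.shape[0]))
    labels = np.asarray([design[s] for s in sample_ids])
    groups, counts = np.unique(labels, return_counts=True)
    if groups.size < 2:
        raise ValueError("PERMANOVA requires >= 2 groups")
    if counts.min() < 2:
        small = [g for g, c in zip(groups, counts) if c < 2]
        raise ValueError(f"every group needs >= 2 samples; singleton group(s): {small}")
    N = D.shape[0]
    a = groups.size
    D2 = D**2
    ss_total = D2.sum() / (2.0 * N)

    def pseudo_f(lab: np.ndarray) -> float:
        ss_w = _ss_within(D2, lab, groups)
        ss_b = ss_total - ss_w
        return (ss_b / (a - 1)) / (ss_w / (N - a))

    f_obs = pseudo_f(labels)
    ss_w_obs = _ss_within(D2, labels, groups)
    r2 = (ss_total - ss_w_obs) / ss_total

    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_permutations):
        perm = rng.permutation(labels)
        if pseudo_f(perm) >= f_obs:
            hits += 1
    p = (1 + hits) / (1 + n_permutations)
    return PermanovaResult(
        pseudo_F=float(f_obs),
        R2=float(r2),
        p_value=float(p),
        n_permutations=n_permutations,
        seed=seed,
    )
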