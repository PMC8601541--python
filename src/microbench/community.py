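"""Community-level tests: multivariate ANOVA effect decomposition (shared by
ASCA and the 50-50 MANOVA), ASCA permutation testing with per-term PCA,
the 50-50 MANOVA community F-test, PERMANOVA on distance matrices, and
one-way ANOSIM.

All permutation tests use free permutation of sample rows and the add-one
p-value convention ``(1 + b) / (1 + n_perm)``; passing ``n_perm="exact"``
enumerates every ordering of the samples (small n only), in which case the
p-value is the exact fraction of orderings with a statistic at least as
large as the observed one.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from .design import DesignMatrices

logger = logging.getLogger("microbench")

__all__ = [
    "EffectDecomposition",
    "AscaResult",
    "DistanceMatrix",
    "AnosimResult",
    "anova_partition",
    "asca",
    "ffmanova_community",
    "distance",
    "permanova",
    "anosim",
]


# ---------------------------------------------------------------------------
# permutation plumbing

def _perm_indices(n: int, n_perm, seed: int):
    """Yield permutation index arrays; "exact" enumerates all orderings."""
    if n_perm == "exact":
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 samples")
        for p in _iter_permutations(range(n)):
            yield np.asarray(p)
    else:
        if not isinstance(n_perm, (int, np.integer)) or n_perm < 1:
            raise ValueError("n_perm must be a positive integer or 'exact'")
        rng = np.random.default_rng(seed)
        for _ in range(n_perm):
            yield rng.permutation(n)


def _perm_pvalue(obs: float, perm_stats: np.ndarray, exact: bool) -> float:
    tol = 1e-9 * max(abs(obs), 1e-12)  # relative, so exact ties always count
    ge = np.sum(perm_stats >= obs - tol)
    if exact:
        return float(ge) / perm_stats.size  # identity ordering is included
    return float(1 + ge) / (1 + perm_stats.size)


# ---------------------------------------------------------------------------
# results containers

@dataclass
class EffectDecomposition:
    """Per-term sums of squares, explained variance and p-values."""

    table: pd.DataFrame  # index: term names; columns df, ssq, explained_variance_pct, p_value[, pseudo_f]
    residual_ssq: float
    residual_df: int
    total_ssq: float
    effects: dict[str, pd.DataFrame] | None = None
    residual: pd.DataFrame | None = None

    @property
    def residual_pct(self) -> float:
        return 100.0 * self.residual_ssq / self.total_ssq


@dataclass
class AscaResult:
    """ANOVA-simultaneous component analysis output: the decomposition plus
    per-term principal-component scores and loadings."""

    decomposition: EffectDecomposition
    scores: dict[str, pd.DataFrame] = field(default_factory=dict)
    loadings: dict[str, pd.DataFrame] = field(default_factory=dict)
    component_variance: dict[str, np.ndarray] = field(default_factory=dict)


@dataclass
class DistanceMatrix:
    values: np.ndarray
    ids: list[str]
    metric: str

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("distance matrix must be square")
        if not np.allclose(V, V.T, atol=1e-9):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(V), 0.0, atol=1e-9):
            raise ValueError("distance matrix must have zero diagonal")
        if np.any(V < -1e-12):
            raise ValueError("distance matrix must be non-negative")
        self.values = V

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class AnosimResult:
    r: float
    p_value: float
    n_perm: object = None


# ---------------------------------------------------------------------------
# ANOVA partition

def anova_partition(
    X: pd.DataFrame,
    D: DesignMatrices,
    ss_type: str = "sequential",
    keep_effects: bool = True,
) -> EffectDecomposition:
    """Project a (centered or autoscaled) response matrix onto the design.

    ``sequential`` (Type I) enters terms in model order; ``partial``
    adjusts each term for all other terms.  The total sum of squares is
    the column-mean-corrected Frobenius norm, so explained-variance
    percentages are comparable across methods.
    """
    if ss_type not in {"sequential", "partial"}:
        raise ValueError(f"unknown ss_type {ss_type!r}")
    if X.shape[0] != D.n:
        raise ValueError("rows of X do not match the design")
    Xa = X.to_numpy(dtype=float)
    Xc = Xa - Xa.mean(axis=0, keepdims=True)
    total = float(np.sum(Xc * Xc))

    rows = []
    effects: dict[str, pd.DataFrame] = {}
    seq_fit = np.zeros_like(Xc)
    for i, term in enumerate(D.terms):
        B_seq = D.sequential_basis(i)
        seq_fit += B_seq @ (B_seq.T @ Xa)
        B = B_seq if ss_type == "sequential" else D.partial_basis(i)
        E = B @ (B.T @ Xa)
        ssq = float(np.sum(E * E))
        rows.append({"term": term.name, "df": B.shape[1], "ssq": ssq,
                     "explained_variance_pct": 100.0 * ssq / total,
                     "p_value": np.nan})
        if keep_effects:
            effects[term.name] = pd.DataFrame(E, index=X.index, columns=X.columns)

    resid = Xc - seq_fit
    residual_ssq = float(np.sum(resid * resid))
    table = pd.DataFrame(rows).set_index("term")
    return EffectDecomposition(
        table=table,
        residual_ssq=residual_ssq,
        residual_df=D.residual_df,
        total_ssq=total,
        effects=effects if keep_effects else None,
        residual=pd.DataFrame(resid, index=X.index, columns=X.columns) if keep_effects else None,
    )


# ---------------------------------------------------------------------------
# ASCA

def asca(
    X: pd.DataFrame,
    D: DesignMatrices,
    n_perm=999,
    seed: int = 0,
    ss_type: str = "sequential",
    compute_pca: bool = True,
) -> AscaResult:
    """ASCA: ANOVA partition of the centered clr matrix with permutation
    p-values per term and PCA (scores/loadings) of each effect matrix.

    The permutation statistic for a term is its sum of squares under free
    permutation of the sample rows.
    """
    decomp = anova_partition(X, D, ss_type=ss_type, keep_effects=True)
    Xa = X.to_numpy(dtype=float)
    G = Xa @ Xa.T
    exact = n_perm == "exact"

    projectors = []
    for i in range(len(D.terms)):
        B = D.sequential_basis(i) if ss_type == "sequential" else D.partial_basis(i)
        projectors.append(B @ B.T)

    perm_stats = {t.name: [] for t in D.terms}
    for idx in _perm_indices(D.n, n_perm, seed):
        Gp = G[np.ix_(idx, idx)]
        for t, P in zip(D.terms, projectors):
            perm_stats[t.name].append(float(np.sum(P * Gp)))
    for t in D.terms:
        obs = decomp.table.loc[t.name, "ssq"]
        decomp.table.loc[t.name, "p_value"] = _perm_pvalue(
            obs, np.asarray(perm_stats[t.name]), exact
        )

    result = AscaResult(decomposition=decomp)
    if compute_pca:
        for name, E in decomp.effects.items():
            U, s, Vt = np.linalg.svd(E.to_numpy(), full_matrices=False)
            rank = int(np.sum(s > 1e-10 * (s[0] if s.size else 1.0)))
            comps = [f"PC{k + 1}" for k in range(rank)]
            result.scores[name] = pd.DataFrame(
                U[:, :rank] * s[:rank], index=X.index, columns=comps
            )
            result.loadings[name] = pd.DataFrame(
                Vt[:rank].T, index=X.columns, columns=comps
            )
            result.component_variance[name] = s[:rank] ** 2
    return result


# ---------------------------------------------------------------------------
# 50-50 MANOVA

def _stat_5050(G: np.ndarray, P_t: np.ndarray, P_te: np.ndarray,
               var_fraction: float = 0.5) -> float:
    """50-50 F-like ratio for one term, computed in the sample (Gram) space.

    The hypothesis (H) and error (E) matrices are projected onto the
    principal components of their sum M = H + E.  Components carrying the
    first >= 50% of M's variance form the test space; a buffer of
    ceil(q/2) further components is excluded, and the remaining tail is
    pooled into the error sum of squares.  The statistic is SSH/SSE on
    that split; degree-of-freedom constants cancel under permutation.
    """
    A = P_te @ G @ P_te  # = M M^T
    lam, U = np.linalg.eigh(A)
    order = np.argsort(lam)[::-1]
    lam = np.clip(lam[order], 0.0, None)
    U = U[:, order]
    total = lam.sum()
    if total <= 0:
        return 0.0
    rank = int(np.sum(lam > 1e-12 * lam[0]))
    lam, U = lam[:rank], U[:, :rank]
    cum = np.cumsum(lam) / total
    q = int(np.searchsorted(cum, var_fraction) + 1)
    q = min(q, rank)
    buffer = int(np.ceil(q / 2))
    tail = slice(q + buffer, rank)

    C = G @ P_te @ U[:, :q] / np.sqrt(lam[:q])  # M' coords of comps, lifted
    ssh = float(np.sum((P_t @ C) ** 2))
    P_e = P_te - P_t
    sse = float(np.sum((P_e @ C) ** 2)) + float(np.sum(lam[tail]))
    if sse <= 0:
        return np.inf
    return ssh / sse


def ffmanova_community(
    X: pd.DataFrame,
    D: DesignMatrices,
    n_perm=999,
    seed: int = 0,
    var_fraction: float = 0.5,
) -> EffectDecomposition:
    """50-50 MANOVA community test on the autoscaled clr matrix.

    Explained variances come from partial (adjusted) sums of squares;
    the community p-value per term is a permutation test of the 50-50
    F statistic (hypothesis vs. error sums of squares over a principal-
    component test space of the term's hypothesis + error data).
    """
    decomp = anova_partition(X, D, ss_type="partial", keep_effects=False)
    if D.residual_df < 1:
        raise ValueError("no residual degrees of freedom")
    Xa = X.to_numpy(dtype=float)
    G = Xa @ Xa.T
    n = D.n
    full = D.full_basis()
    P_model = full @ full.T
    P_resid = np.eye(n) - np.ones((n, n)) / n - P_model
    exact = n_perm == "exact"

    for i, term in enumerate(D.terms):
        B = D.partial_basis(i)
        P_t = B @ B.T
        P_te = P_t + P_resid
        obs = _stat_5050(G, P_t, P_te, var_fraction)
        perm = [
            _stat_5050(G[np.ix_(idx, idx)], P_t, P_te, var_fraction)
            for idx in _perm_indices(n, n_perm, seed)
        ]
        decomp.table.loc[term.name, "p_value"] = _perm_pvalue(
            obs, np.asarray(perm), exact
        )
        decomp.table.loc[term.name, "stat_5050"] = obs
    return decomp


# ---------------------------------------------------------------------------
# distance-based tests

def distance(X: pd.DataFrame, metric: str = "euclidean") -> DistanceMatrix:
    """Pairwise sample distances: Euclidean (for clr data) or Bray-Curtis
    (for non-negative relative abundances)."""
    Xa = X.to_numpy(dtype=float)
    if metric == "euclidean":
        V = squareform(pdist(Xa, metric="euclidean"))
    elif metric in {"bray-curtis", "braycurtis"}:
        if np.any(Xa < 0):
            raise ValueError("Bray-Curtis requires non-negative input")
        V = squareform(pdist(Xa, metric="braycurtis"))
        metric = "bray-curtis"
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return DistanceMatrix(values=V, ids=list(X.index), metric=metric)


def _gower_center(Dm: np.ndarray) -> np.ndarray:
    n = Dm.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * J @ (Dm ** 2) @ J


def permanova(
    dist: DistanceMatrix,
    D: DesignMatrices,
    n_perm=999,
    seed: int = 0,
) -> EffectDecomposition:
    """PERMANOVA: sequential partition of a Gower-centered distance matrix.

    For Euclidean distances on column-centered data this reproduces the
    direct ANOVA partition of the data matrix exactly.  Per-term p-values
    permute the samples of the distance matrix and use the pseudo-F
    statistic.
    """
    if dist.n != D.n:
        raise ValueError("distance matrix does not match the design")
    G = _gower_center(dist.values)
    eigs = np.linalg.eigvalsh(G)
    if eigs.min() < -1e-8 * max(eigs.max(), 1.0):
        logger.warning(
            "permanova: distance matrix is not Euclidean-embeddable "
            "(min eigenvalue %.3g); proceeding", eigs.min()
        )
    total = float(np.trace(G))
    projectors = [
        D.sequential_basis(i) @ D.sequential_basis(i).T for i in range(len(D.terms))
    ]
    df_res = D.residual_df
    exact = n_perm == "exact"

    def stats_for(Gm: np.ndarray) -> tuple[np.ndarray, float]:
        ssqs = np.array([float(np.sum(P * Gm)) for P in projectors])
        res = total - ssqs.sum()
        return ssqs, res

    obs_ssq, obs_res = stats_for(G)
    dfs = np.array([D.sequential_basis(i).shape[1] for i in range(len(D.terms))])
    obs_f = (obs_ssq / dfs) / (obs_res / df_res)

    perm_f = np.empty((0, len(D.terms)))
    acc = []
    for idx in _perm_indices(D.n, n_perm, seed):
        Gp = G[np.ix_(idx, idx)]
        ssqs, res = stats_for(Gp)
        acc.append((ssqs / dfs) / (res / df_res))
    perm_f = np.asarray(acc)

    rows = []
    for j, term in enumerate(D.terms):
        rows.append({
            "term": term.name,
            "df": int(dfs[j]),
            "ssq": obs_ssq[j],
            "explained_variance_pct": 100.0 * obs_ssq[j] / total,
            "pseudo_f": obs_f[j],
            "p_value": _perm_pvalue(obs_f[j], perm_f[:, j], exact),
        })
    table = pd.DataFrame(rows).set_index("term")
    return EffectDecomposition(
        table=table, residual_ssq=obs_res, residual_df=df_res, total_ssq=total
    )


def anosim(
    dist: DistanceMatrix,
    groups,
    n_perm=999,
    seed: int = 0,
) -> AnosimResult:
    """One-way ANOSIM on ranked distances.

    R = (mean between-group rank - mean within-group rank) / (M/2) with
    M = n(n-1)/2; significance by permutation of the group labels.
    """
    labels = np.asarray(pd.Series(list(groups)).astype(str))
    n = dist.n
    if labels.shape[0] != n:
        raise ValueError("group labels do not match the distance matrix")
    counts = pd.Series(labels).value_counts()
    if len(counts) < 2 or counts.min() < 2:
        raise ValueError("ANOSIM needs >=2 groups with >=2 samples each")

    iu = np.triu_indices(n, k=1)
    ranks = rankdata(dist.values[iu])
    M = ranks.size

    def r_stat(lab: np.ndarray) -> float:
        within = lab[iu[0]] == lab[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (M / 2.0)

    obs = r_stat(labels)
    exact = n_perm == "exact"
    perm = np.array([r_stat(labels[idx]) for idx in _perm_indices(n, n_perm, seed)])
    return AnosimResult(r=obs, p_value=_perm_pvalue(obs, perm, exact), n_perm=n_perm)
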