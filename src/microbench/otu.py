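"""OTU-level differential-abundance procedures and their ranking statistics.

Each procedure returns a :class:`RankingTable`: one statistic per OTU, an
evidence rank (1 = strongest evidence), and a significance flag under the
method's own decision rule:

* SIMPER — permutation p of per-OTU Bray-Curtis contributions (p < 0.01);
* rotation tests — per-OTU F p-values with a max-statistic familywise
  adjustment from random rotations of the residual space (raw p < 0.01);
* PLS-DA / VIP with UVE — variable-importance thresholding against
  appended noise variables (selected in > 95% of repetitions);
* ANCOM — W statistic counting rejected pairwise log-ratio tests
  (W at or above the 60th percentile of the empirical W distribution);
* Dirichlet Monte-Carlo clr test — expected linear-model p over posterior
  compositions (expected raw p < 0.01);
* negative-binomial GLM Wald test — size-factor offsets, moderated
  dispersions, Wald p for a level contrast (raw p < 0.01).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import permutations as _iter_permutations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.linalg import null_space
from scipy.optimize import nnls
from scipy.stats import rankdata
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import StratifiedKFold

from .design import DesignMatrices, build_design

logger = logging.getLogger("microbench")

__all__ = [
    "RankingTable",
    "rank_table",
    "simper",
    "rotation_pvalues",
    "plsda_vip",
    "uve_select",
    "ancom_w",
    "dirichlet_clr_test",
    "nbglm_test",
    "size_factors",
    "benjamini_hochberg",
]


@dataclass
class RankingTable:
    """Per-OTU statistic, evidence rank and significance flag for one
    method/contrast — the unit of cross-method comparison."""

    method: str
    contrast: str
    polarity: str  # "lower" (p-like) or "higher" (W, |coefficient|)
    table: pd.DataFrame  # index: otu_id; columns: statistic, rank, significant, ...

    @property
    def evidence_rank(self) -> pd.Series:
        """Rank with 1 = strongest evidence, polarity harmonized."""
        return self.table["rank"]

    @property
    def significant(self) -> pd.Series:
        return self.table["significant"]


def rank_table(
    statistics: pd.Series,
    polarity: str,
    significant: pd.Series | None = None,
    method: str = "",
    contrast: str = "",
    extra: dict[str, pd.Series] | None = None,
    p_threshold: float | None = None,
) -> RankingTable:
    """Assemble a RankingTable: average-tie evidence ranks plus flags.

    ``p_threshold`` applies the p < threshold rule when ``significant`` is
    not supplied (only meaningful for lower-is-more-evidence statistics).
    """
    if polarity not in {"lower", "higher"}:
        raise ValueError(f"unknown polarity {polarity!r}")
    missing = statistics.index[statistics.isna()]
    if len(missing):
        raise ValueError(f"missing statistics for OTUs: {list(missing)}")
    vals = statistics.to_numpy(dtype=float)
    ranks = rankdata(vals if polarity == "lower" else -vals, method="average")
    if significant is None:
        if p_threshold is not None:
            if polarity != "lower":
                raise ValueError("p_threshold needs a lower-is-more-evidence statistic")
            significant = statistics < p_threshold
        else:
            significant = pd.Series(False, index=statistics.index)
    tab = pd.DataFrame(
        {"statistic": statistics, "rank": ranks, "significant": significant.astype(bool)},
        index=statistics.index,
    )
    for name, col in (extra or {}).items():
        tab[name] = col
    return RankingTable(method=method, contrast=contrast, polarity=polarity, table=tab)


def benjamini_hochberg(p: np.ndarray, axis: int = -1) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values along an axis."""
    p = np.asarray(p, dtype=float)
    p = np.moveaxis(p, axis, -1)
    m = p.shape[-1]
    order = np.argsort(p, axis=-1)
    ranked = np.take_along_axis(p, order, axis=-1)
    adj = ranked * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(adj[..., ::-1], axis=-1)[..., ::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty_like(adj)
    np.put_along_axis(out, order, adj, axis=-1)
    return np.moveaxis(out, -1, axis)


# ---------------------------------------------------------------------------
# SIMPER

def simper(
    rel: pd.DataFrame,
    groups: pd.Series,
    level_pair: tuple[str, str],
    n_perm=999,
    seed: int = 0,
    alpha: float = 0.01,
) -> RankingTable:
    """SIMPER: per-OTU contributions to the mean between-group Bray-Curtis
    dissimilarity, with permutation p-values.

    The p-value of an OTU is the probability of a larger contribution
    under random permutation of the group labels; contributions over all
    OTUs sum exactly to the mean between-group dissimilarity.
    """
    a_lab, b_lab = map(str, level_pair)
    lab = groups.astype(str).reindex(rel.index)
    sel = lab.isin([a_lab, b_lab])
    sub = rel.loc[sel]
    sub_lab = lab.loc[sel].to_numpy()
    n = sub.shape[0]
    if (sub_lab == a_lab).sum() < 2 or (sub_lab == b_lab).sum() < 2:
        raise ValueError("both levels need at least 2 samples")

    X = sub.to_numpy(dtype=float)
    # precompute all pairwise |x_k - x_l| / (row_k + row_l) contributions
    diffs = np.abs(X[:, None, :] - X[None, :, :])
    denom = X.sum(axis=1)[:, None] + X.sum(axis=1)[None, :]
    R = diffs / denom[:, :, None]

    def contrib(is_a: np.ndarray) -> np.ndarray:
        block = R[np.ix_(is_a, ~is_a)]
        return block.mean(axis=(0, 1))

    obs = contrib(sub_lab == a_lab)
    n_a = int((sub_lab == a_lab).sum())
    exact = n_perm == "exact"
    if exact:
        if n > 8:
            raise ValueError("exact enumeration limited to n <= 8 samples")
        perms = [np.asarray(p) for p in _iter_permutations(range(n))]
    else:
        rng = np.random.default_rng(seed)
        perms = [rng.permutation(n) for _ in range(int(n_perm))]
    ge = np.zeros(X.shape[1])
    tol = 1e-9 * np.maximum(np.abs(obs), 1e-15)  # relative, ties count
    for idx in perms:
        is_a = np.zeros(n, dtype=bool)
        is_a[idx[:n_a]] = True
        ge += contrib(is_a) >= obs - tol
    if exact:
        p = ge / len(perms)
    else:
        p = (1.0 + ge) / (1.0 + len(perms))

    stats = pd.Series(p, index=rel.columns, name="p")
    return rank_table(
        stats, "lower", method="simper", contrast=f"{a_lab} vs {b_lab}",
        p_threshold=alpha,
        extra={"contribution": pd.Series(obs, index=rel.columns)},
    )


# ---------------------------------------------------------------------------
# rotation tests (per-OTU F with familywise max-statistic adjustment)

def rotation_pvalues(
    X: pd.DataFrame,
    D: DesignMatrices,
    term: str,
    n_rot=999,
    seed: int = 0,
    alpha: float = 0.01,
) -> RankingTable:
    """Per-OTU F-tests for one model term with rotation-based adjustment.

    Raw p-values are classical F-test p-values (term adjusted for all
    other terms).  Familywise-adjusted p-values come from a step-down
    max-F procedure over random orthogonal rotations of the part of the
    data orthogonal to the nuisance terms; the adjusted p is clipped to
    be no smaller than the raw p.
    """
    names = D.term_names
    if term not in names:
        raise ValueError(f"term {term!r} not in design terms {names}")
    i = names.index(term)
    B = D.partial_basis(i)
    df_t = B.shape[1]
    df_e = D.residual_df
    if df_e < 2:
        raise ValueError("need at least 2 residual degrees of freedom")

    n = D.n
    nuisance = [np.ones((n, 1)) / np.sqrt(n)] + [
        D.sequential_basis(j) for j in range(len(names)) if j != i
    ]
    Q = np.hstack([b for b in nuisance if b.shape[1]])
    C = null_space(Q.T)  # complement of the nuisance space, n × d
    d = C.shape[1]
    Z = C.T @ X.to_numpy(dtype=float)  # d × m
    Bt = C.T @ B  # hypothesis directions inside the complement (orthonormal)

    tot = np.sum(Z * Z, axis=0)
    num = np.sum((Bt.T @ Z) ** 2, axis=0)
    den = np.clip(tot - num, 1e-300, None)
    F = (num / df_t) / (den / df_e)
    raw_p = sps.f.sf(F, df_t, df_e)

    if n_rot == "exact":
        raise ValueError("rotation tests have no exact enumeration")
    rng = np.random.default_rng(seed)
    m = Z.shape[1]
    ge_raw = np.zeros(m)
    order = np.argsort(F)[::-1]  # step-down over decreasing F
    ge_max = np.zeros(m)
    for _ in range(int(n_rot)):
        W, _ = np.linalg.qr(rng.standard_normal((d, df_t)))
        num_r = np.sum((W.T @ Z) ** 2, axis=0)
        F_r = (num_r / df_t) / (np.clip(tot - num_r, 1e-300, None) / df_e)
        ge_raw += F_r >= F - 1e-12
        # successive maxima over the step-down ordering
        succ_max = np.maximum.accumulate(F_r[order][::-1])[::-1]
        ge_max[order] += succ_max >= F[order] - 1e-12
    mc_raw = (1.0 + ge_raw) / (1.0 + int(n_rot))
    adj = (1.0 + ge_max) / (1.0 + int(n_rot))
    adj_sorted = np.maximum.accumulate(adj[order])  # enforce monotonicity
    adj_p = np.empty(m)
    adj_p[order] = adj_sorted
    adj_p = np.maximum(adj_p, raw_p)

    stats = pd.Series(raw_p, index=X.columns, name="raw_p")
    return rank_table(
        stats, "lower", method="rotation", contrast=term, p_threshold=alpha,
        extra={
            "F": pd.Series(F, index=X.columns),
            "adj_p": pd.Series(adj_p, index=X.columns),
            "mc_raw_p": pd.Series(mc_raw, index=X.columns),
        },
    )


# ---------------------------------------------------------------------------
# PLS-DA / VIP / UVE

def _dummy_response(labels: pd.Series, level_pair: tuple[str, str]) -> np.ndarray:
    lab = labels.astype(str).to_numpy()
    a, b = map(str, level_pair)
    if not (np.any(lab == a) and np.any(lab == b)):
        raise ValueError(f"levels {level_pair} not both present")
    y = np.where(lab == a, 1.0, -1.0)
    return y


def _fit_pls(Xa: np.ndarray, y: np.ndarray, n_components: int):
    n_components = int(min(n_components, Xa.shape[0] - 1, Xa.shape[1]))
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xa, y.reshape(-1, 1))
    return pls


def _vip_from_pls(pls) -> np.ndarray:
    W = pls.x_weights_            # p × A
    T = pls.x_scores_             # n × A
    Q = pls.y_loadings_           # 1 × A
    ssy = (Q[0] ** 2) * np.sum(T ** 2, axis=0)   # response variance per component
    Wn = W / np.linalg.norm(W, axis=0, keepdims=True)
    p = W.shape[0]
    vip = np.sqrt(p * (Wn ** 2 @ ssy) / ssy.sum())
    return vip


def plsda_vip(
    X: pd.DataFrame,
    labels: pd.Series,
    level_pair: tuple[str, str],
    n_components: int = 2,
) -> tuple[pd.Series, pd.Series]:
    """PLS-DA of a two-level response on (effect + residual) data.

    Returns per-OTU VIP scores (mean VIP² = 1) and regression
    coefficients.  ``n_components`` is truncated (with a warning) if it
    exceeds the data rank.
    """
    sel = labels.astype(str).isin([str(level_pair[0]), str(level_pair[1])])
    Xs = X.loc[sel.index[sel]]
    y = _dummy_response(labels.loc[sel.index[sel]], level_pair)
    max_rank = min(Xs.shape[0] - 1, Xs.shape[1])
    if n_components > max_rank:
        logger.warning("plsda_vip: n_components truncated from %d to %d", n_components, max_rank)
        n_components = max_rank
    pls = _fit_pls(Xs.to_numpy(dtype=float), y, n_components)
    vip = pd.Series(_vip_from_pls(pls), index=X.columns, name="vip")
    coef = pd.Series(np.asarray(pls.coef_).reshape(-1), index=X.columns, name="coef")
    return vip, coef


def choose_n_components(
    X: pd.DataFrame,
    labels: pd.Series,
    level_pair: tuple[str, str],
    max_components: int = 5,
    n_folds: int = 10,
    seed: int = 0,
) -> int:
    """Pick the PLS component count by cross-validated classification error."""
    sel = labels.astype(str).isin([str(level_pair[0]), str(level_pair[1])])
    Xs = X.loc[sel.index[sel]].to_numpy(dtype=float)
    y = _dummy_response(labels.loc[sel.index[sel]], level_pair)
    max_components = int(min(max_components, Xs.shape[0] - 2, Xs.shape[1]))
    n_folds = min(n_folds, int(np.min(np.unique(y, return_counts=True)[1])))
    if n_folds < 2 or max_components < 2:
        return max(1, max_components)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errors = []
    for a in range(1, max_components + 1):
        err = 0
        for tr, te in skf.split(Xs, y):
            pls = _fit_pls(Xs[tr], y[tr], a)
            pred = pls.predict(Xs[te]).reshape(-1)
            err += np.sum(np.sign(pred) != y[te])
        errors.append(err)
    return int(np.argmin(errors)) + 1


def uve_select(
    X: pd.DataFrame,
    labels: pd.Series,
    level_pair: tuple[str, str],
    n_rep: int = 100,
    keep_rate: float = 0.95,
    seed: int = 0,
    n_components: int | None = None,
    ranking_statistic: pd.Series | None = None,
) -> RankingTable:
    """Uninformative-variable-elimination significance for PLS-DA VIPs.

    Each repetition appends one permuted (noise) copy of every real
    column, fits PLS-DA, and marks real OTUs whose VIP exceeds the
    maximal noise VIP.  OTUs marked in more than ``keep_rate`` of the
    repetitions are significant.  The ranking statistic defaults to the
    absolute PLS-DA regression coefficient; pass e.g. absolute ASCA
    loadings via ``ranking_statistic`` for two-level designs.
    """
    if n_rep < 1:
        raise ValueError("n_rep must be >= 1")
    sel = labels.astype(str).isin([str(level_pair[0]), str(level_pair[1])])
    Xs = X.loc[sel.index[sel]]
    y = _dummy_response(labels.loc[sel.index[sel]], level_pair)
    Xa = Xs.to_numpy(dtype=float)
    n, m = Xa.shape
    if n_components is None:
        n_components = choose_n_components(X, labels, level_pair, seed=seed)
    n_components = int(min(n_components, n - 1, m))

    rng = np.random.default_rng(seed)
    hits = np.zeros(m)
    for _ in range(int(n_rep)):
        noise = np.empty_like(Xa)
        for j in range(m):
            noise[:, j] = Xa[rng.permutation(n), j]
        aug = np.hstack([Xa, noise])
        pls = _fit_pls(aug, y, n_components)
        vip = _vip_from_pls(pls)
        thr = vip[m:].max()
        hits += vip[:m] > thr
    freq = hits / n_rep
    significant = pd.Series(freq > keep_rate, index=X.columns)

    if ranking_statistic is None:
        pls = _fit_pls(Xa, y, n_components)
        ranking_statistic = pd.Series(
            np.abs(np.asarray(pls.coef_).reshape(-1)), index=X.columns
        )
    else:
        ranking_statistic = ranking_statistic.abs().reindex(X.columns)
    return rank_table(
        ranking_statistic, "higher", significant=significant,
        method="asca-uve", contrast=f"{level_pair[0]} vs {level_pair[1]}",
        extra={"selection_freq": pd.Series(freq, index=X.columns)},
    )


# ---------------------------------------------------------------------------
# ANCOM

def ancom_w(
    rel: pd.DataFrame,
    factor: pd.Series,
    covariates: pd.DataFrame | None = None,
    alpha: float = 0.05,
    w_fraction: float = 0.60,
    threshold_mode: str = "max_fraction",
) -> RankingTable:
    """ANCOM W statistic from all pairwise log-ratio tests.

    For every ordered pair (i, j != i) a linear model of log(x_i / x_j)
    on the factor (adjusted for optional covariate terms) yields an
    omnibus F p-value; within OTU i the m-1 p-values are BH-adjusted and
    W_i counts rejections at ``alpha``.

    The default decision rule flags OTUs with W at or above
    ``w_fraction`` of the maximum attainable count m-1 (the cutoff used
    by the reference ANCOM 2.0 code).  ``threshold_mode="percentile"``
    instead thresholds at the ``w_fraction`` empirical quantile of the W
    distribution; note that rule flags at least ``1 - w_fraction`` of
    all OTUs by construction, so its specificity is bounded.
    """
    m = rel.shape[1]
    if m < 3:
        raise ValueError("ANCOM needs at least 3 OTUs")
    X = rel.to_numpy(dtype=float)
    if np.any(X <= 0):
        raise ValueError("ANCOM needs strictly positive abundances; zero-replace first")
    factor = factor.astype(str).reindex(rel.index)
    meta = pd.DataFrame({"__factor__": factor})
    terms: list[tuple[str, ...]] = []
    if covariates is not None:
        for c in covariates.columns:
            meta[c] = covariates[c].astype(str).reindex(rel.index)
            terms.append((c,))
    terms.append(("__factor__",))
    D = build_design(meta, tuple(terms))
    i_t = D.term_names.index("__factor__")
    B = D.partial_basis(i_t)
    df_t = B.shape[1]
    df_e = D.residual_df
    if df_e < 1:
        raise ValueError("no residual degrees of freedom for the log-ratio models")

    L = np.log(X)
    full = D.full_basis()
    n = D.n
    H = B.T @ L                                       # df_t × m
    R = L - np.ones((n, 1)) * L.mean(axis=0) - full @ (full.T @ L)
    A = H.T @ H                                       # hypothesis cross-products
    E = R.T @ R                                       # residual cross-products
    a_d, e_d = np.diag(A), np.diag(E)
    num = a_d[:, None] + a_d[None, :] - 2 * A
    den = e_d[:, None] + e_d[None, :] - 2 * E
    den = np.clip(den, 1e-300, None)
    F = (num / df_t) / (den / df_e)
    P = sps.f.sf(F, df_t, df_e)
    np.fill_diagonal(P, np.nan)

    # BH within each OTU's m-1 tests
    W = np.zeros(m, dtype=int)
    mask = ~np.eye(m, dtype=bool)
    pvals = P[mask].reshape(m, m - 1)
    q = benjamini_hochberg(pvals, axis=1)
    W = (q <= alpha).sum(axis=1)

    if threshold_mode == "max_fraction":
        thr = w_fraction * (m - 1)
    elif threshold_mode == "percentile":
        thr = float(np.quantile(W, w_fraction))
    else:
        raise ValueError(f"unknown threshold_mode {threshold_mode!r}")
    stats = pd.Series(W.astype(float), index=rel.columns, name="W")
    significant = stats >= thr
    return rank_table(
        stats, "higher", significant=significant, method="ancom",
        contrast=f"{factor.name or 'factor'} (omnibus)",
        extra={"w_threshold": pd.Series(thr, index=rel.columns)},
    )


# ---------------------------------------------------------------------------
# Dirichlet Monte-Carlo clr test

def dirichlet_clr_test(
    counts: pd.DataFrame,
    D: DesignMatrices,
    term: str | None = None,
    n_mc: int = 128,
    seed: int = 0,
    prior: float = 0.5,
    alpha: float = 0.01,
) -> RankingTable:
    """Monte-Carlo Dirichlet posterior clr test on raw counts.

    Per sample, ``n_mc`` compositions are drawn from Dirichlet(counts +
    prior); each instance is clr-transformed and a per-OTU F-test for the
    requested term computed.  The reported statistics are the expected
    raw p and expected BH-adjusted p across instances.
    """
    if n_mc < 2:
        raise ValueError("n_mc must be >= 2")
    term = term or D.term_names[0]
    i_t = D.term_names.index(term)
    B = D.partial_basis(i_t)
    df_t, df_e = B.shape[1], D.residual_df
    full = D.full_basis()
    n, m = counts.shape
    if D.n != n:
        raise ValueError("design does not match the count table")

    rng = np.random.default_rng(seed)
    alpha_post = counts.to_numpy(dtype=float) + prior
    G = rng.standard_gamma(alpha_post[None, :, :], size=(int(n_mc), n, m))
    comp = G / G.sum(axis=2, keepdims=True)
    L = np.log(comp)
    Z = L - L.mean(axis=2, keepdims=True)             # clr per instance

    num = np.einsum("nq,inm->iqm", B, Z)
    num = np.sum(num ** 2, axis=1)                    # n_mc × m
    Zc = Z - Z.mean(axis=1, keepdims=True)
    fit = np.einsum("nr,inm->irm", full, Z)
    den = np.sum(Zc ** 2, axis=1) - np.sum(fit ** 2, axis=1)
    den = np.clip(den, 1e-300, None)
    F = (num / df_t) / (den / df_e)
    P = sps.f.sf(F, df_t, df_e)
    exp_p = P.mean(axis=0)
    exp_q = benjamini_hochberg(P, axis=1).mean(axis=0)

    stats = pd.Series(exp_p, index=counts.columns, name="expected_p")
    return rank_table(
        stats, "lower", method="dirichlet-clr", contrast=term, p_threshold=alpha,
        extra={"expected_bh_p": pd.Series(exp_q, index=counts.columns)},
    )


# ---------------------------------------------------------------------------
# negative-binomial GLM

def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios size factors with a geometric-mean reference.

    OTUs with a zero count in any sample are excluded from the reference;
    if none remain, the reference falls back to per-OTU geometric means
    over positive counts only (logged).
    """
    Y = counts.to_numpy(dtype=float)
    allpos = np.all(Y > 0, axis=0)
    if allpos.any():
        logg = np.log(Y[:, allpos])
        ref = logg.mean(axis=0)
        s = np.exp(np.median(logg - ref, axis=1))
    else:
        logger.warning("size_factors: no OTU with all-positive counts; using positive-count geometric means")
        with np.errstate(divide="ignore"):
            logy = np.where(Y > 0, np.log(Y), np.nan)
        ref = np.nanmean(logy, axis=0)
        ratios = logy - ref
        s = np.exp(np.nanmedian(ratios, axis=1))
    s = s / np.exp(np.mean(np.log(s)))
    return pd.Series(s, index=counts.index, name="size_factor")


def _nb_deviance(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-OTU NB2 deviance (columns of Y); y log(y/mu) taken as 0 at y=0."""
    with np.errstate(divide="ignore", invalid="ignore"):
        t1 = np.where(Y > 0, Y * np.log(np.clip(Y, 1e-300, None) / mu), 0.0)
    r = 1.0 / alpha[None, :]
    t2 = (Y + r) * np.log((1.0 + alpha[None, :] * Y) / (1.0 + alpha[None, :] * mu))
    return 2.0 * np.sum(t1 - t2, axis=0)


def _nb_irls(Y: np.ndarray, X: np.ndarray, offset: np.ndarray,
             alpha: np.ndarray, n_iter: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized IRLS for per-OTU NB2 GLMs with log link.

    Fisher-scoring steps are damped by per-OTU step halving on the NB
    deviance, which keeps quasi-separated OTUs (a factor level with all
    zero counts) from diverging.  Returns (beta: p × m, cov: m × p × p).
    """
    n, m = Y.shape
    p = X.shape[1]

    def mu_of(b: np.ndarray) -> np.ndarray:
        return np.clip(np.exp(np.clip(X @ b + offset[:, None], -30, 30)), 1e-10, None)

    pseudo = np.log((Y + 0.5) / np.exp(offset)[:, None])
    beta, *_ = np.linalg.lstsq(X, pseudo, rcond=None)
    dev = _nb_deviance(Y, mu_of(beta), alpha)
    for _ in range(n_iter):
        eta = np.clip(X @ beta + offset[:, None], -30, 30)
        mu = np.clip(np.exp(eta), 1e-10, None)
        W = mu / (1.0 + alpha[None, :] * mu)
        z = (eta - offset[:, None]) + (Y - mu) / mu
        XtWX = np.einsum("np,nm,nq->mpq", X, W, X)
        XtWz = np.einsum("np,nm,nm->mp", X, W, z)
        new = np.linalg.solve(XtWX + 1e-8 * np.eye(p)[None], XtWz[:, :, None])[:, :, 0].T
        step = new - beta
        lam = np.ones(m)
        cand_dev = dev
        for _h in range(12):
            cand = beta + step * lam[None, :]
            cand_dev = _nb_deviance(Y, mu_of(cand), alpha)
            worse = cand_dev > dev + 1e-8
            if not worse.any():
                break
            lam[worse] *= 0.5
        beta = beta + step * lam[None, :]
        improved = dev - cand_dev
        dev = np.minimum(dev, cand_dev)
        if np.max(np.abs(step * lam[None, :])) < 1e-8 or np.max(improved) < 1e-10:
            break
    mu = mu_of(beta)
    W = mu / (1.0 + alpha[None, :] * mu)
    XtWX = np.einsum("np,nm,nq->mpq", X, W, X)
    cov = np.linalg.inv(XtWX + 1e-8 * np.eye(p)[None])
    return beta, cov


def _nb_loglik(Y: np.ndarray, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Per-OTU NB2 log-likelihood; alpha broadcast over a grid axis."""
    r = 1.0 / alpha
    from scipy.special import gammaln

    ll = (
        gammaln(Y + r) - gammaln(r) - gammaln(Y + 1.0)
        + r * np.log(r / (r + mu))
        + Y * np.log(np.clip(mu / (r + mu), 1e-300, None))
    )
    return ll.sum(axis=-2)


def nbglm_test(
    counts: pd.DataFrame,
    metadata: pd.DataFrame,
    formula: str | tuple[tuple[str, ...], ...],
    contrast: tuple[str, str, str],
    dispersion: float | np.ndarray | None = None,
    shrink_weight: float = 0.5,
    alpha_threshold: float = 0.01,
) -> RankingTable:
    """Negative-binomial GLM Wald test on raw counts.

    Size factors use median-of-ratios; each OTU gets an NB2 GLM with log
    link and size-factor offsets.  Dispersions are estimated per OTU by
    profile maximum likelihood and moderated toward a fitted parametric
    mean-dispersion trend ``a0 + a1 / mean`` by log-scale averaging with
    weight ``shrink_weight``.  The Wald test is on the population-average
    contrast between two levels of one factor; outputs the log2 fold
    change and the raw p-value.  ``dispersion`` overrides estimation
    (scalar or per-OTU) — useful for oracle cross-checks.
    """
    factor, lvl_a, lvl_b = contrast
    D = build_design(metadata, formula)
    Y = counts.to_numpy(dtype=float)
    n, m = Y.shape
    sf = size_factors(counts).to_numpy()
    offset = np.log(sf)
    X = np.hstack([np.ones((n, 1)) / np.sqrt(n)] +
                  [D.sequential_basis(i) for i in range(len(D.terms))])
    lab = metadata[factor].astype(str).to_numpy()
    in_a, in_b = lab == str(lvl_a), lab == str(lvl_b)
    if not (in_a.any() and in_b.any()):
        raise ValueError(f"contrast levels {lvl_a!r}/{lvl_b!r} not both present")
    c = X[in_a].mean(axis=0) - X[in_b].mean(axis=0)

    if dispersion is not None:
        disp = np.broadcast_to(np.asarray(dispersion, dtype=float), (m,)).copy()
    else:
        # initial Poisson fit, then profile-likelihood dispersion on a grid
        beta0, _ = _nb_irls(Y, X, offset, np.full(m, 1e-8))
        mu0 = np.clip(np.exp(np.clip(X @ beta0 + offset[:, None], -30, 30)), 1e-10, None)
        grid = np.exp(np.linspace(np.log(1e-5), np.log(20.0), 45))
        ll = np.stack([_nb_loglik(Y, mu0, np.full(m, a)) for a in grid])  # grid × m
        disp_ml = grid[np.argmax(ll, axis=0)]
        # parametric trend alpha = a0 + a1/mean (non-negative coefficients)
        mean_norm = (Y / sf[:, None]).mean(axis=0)
        ok = mean_norm > 0
        A_ls = np.column_stack([np.ones(ok.sum()), 1.0 / mean_norm[ok]])
        coef, _ = nnls(A_ls, disp_ml[ok])
        trend = np.clip(coef[0] + coef[1] / np.clip(mean_norm, 1e-12, None), 1e-8, None)
        disp = np.exp((1 - shrink_weight) * np.log(np.clip(disp_ml, 1e-8, None))
                      + shrink_weight * np.log(trend))

    beta, cov = _nb_irls(Y, X, offset, disp)
    est = c @ beta
    se = np.sqrt(np.einsum("p,mpq,q->m", c, cov, c))
    z = est / np.clip(se, 1e-300, None)
    p = 2.0 * sps.norm.sf(np.abs(z))
    log2fc = est / np.log(2.0)

    stats = pd.Series(p, index=counts.columns, name="p")
    return rank_table(
        stats, "lower", method="nbglm", contrast=f"{factor}: {lvl_a} vs {lvl_b}",
        p_threshold=alpha_threshold,
        extra={
            "log2fc": pd.Series(log2fc, index=counts.columns),
            "wald_z": pd.Series(z, index=counts.columns),
            "dispersion": pd.Series(disp, index=counts.columns),
        },
    )
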