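"""Compositional preprocessing chain: closure, OTU filtering, multiplicative
zero replacement and the centred log-ratio (clr) transform.

Every downstream method consumes the output of this chain.  The order is
fixed: counts → relative abundance → prevalence/abundance filter →
multiplicative zero replacement → clr → (optional) column centering or
autoscaling.
"""

from __future__ import annotations

import logging
from typing import Iterable

import numpy as np
import pandas as pd

from .data import CountMatrix

logger = logging.getLogger("microbench")

__all__ = [
    "to_relative",
    "filter_otus",
    "replace_zeros_czm",
    "clr",
    "scale_columns",
]


def to_relative(counts: CountMatrix | pd.DataFrame) -> pd.DataFrame:
    """Close each sample to 1 (counts divided by library size).

    Zeros are preserved; an all-zero sample is an error because it carries
    no compositional information.
    """
    df = counts.values if isinstance(counts, CountMatrix) else counts
    totals = df.sum(axis=1)
    if np.any(totals.to_numpy() <= 0):
        bad = list(totals.index[totals <= 0])
        raise ValueError(f"samples with zero total abundance: {bad}")
    return df.div(totals, axis=0).astype(float)


def filter_otus(
    rel: pd.DataFrame,
    groups: pd.Series | Iterable[str],
    min_rel: float = 5e-5,
    prevalence: float = 0.5,
) -> pd.DataFrame:
    """Keep OTUs that are non-negligible and consistently present in a group.

    An OTU is retained iff

    a) its relative abundance exceeds ``min_rel`` (strict ``>``) in at
       least one sample, and
    b) it is present (abundance > 0) in at least a ``prevalence`` fraction
       (inclusive ``>=``) of the samples of at least one group.

    Groups are design cells (e.g. diet × dose combinations); evaluating
    prevalence within groups keeps group-specific taxa that would fail a
    global prevalence cut.
    """
    groups = pd.Series(list(groups), index=rel.index) if not isinstance(groups, pd.Series) else groups
    if not groups.index.equals(rel.index):
        groups = groups.reindex(rel.index)
    if groups.isna().any():
        raise ValueError("group labels do not cover all samples")

    abundant = (rel > min_rel).any(axis=0)
    present_in_group = pd.Series(False, index=rel.columns)
    for _, idx in groups.groupby(groups).groups.items():
        frac = (rel.loc[idx] > 0).mean(axis=0)
        present_in_group |= frac >= prevalence
    keep = abundant & present_in_group
    if not keep.any():
        raise ValueError("filter removed every OTU")
    removed = list(rel.columns[~keep])
    if removed:
        logger.info("filter_otus: removed %d of %d OTUs", len(removed), rel.shape[1])
        logger.debug("filter_otus: removed ids: %s", removed)
    return rel.loc[:, keep]


def replace_zeros_czm(
    rel: pd.DataFrame,
    library_sizes: pd.Series | np.ndarray | None = None,
    delta_frac: float = 0.65,
) -> pd.DataFrame:
    """Count-zero multiplicative (CZM) replacement.

    Each zero in sample *i* becomes ``delta_i = delta_frac * DL_i`` where
    the detection limit ``DL_i`` is ``1 / library_size_i`` when depths are
    known and otherwise the smallest positive value of the row.  Non-zero
    parts are multiplied by ``1 - z_i * delta_i`` (``z_i`` = number of
    zeros in the row), which preserves closure and all ratios between
    originally non-zero parts.
    """
    X = rel.to_numpy(dtype=float).copy()
    n, m = X.shape
    row_sums = X.sum(axis=1)
    if np.any(row_sums <= 0):
        raise ValueError("row of all zeros cannot be zero-replaced")
    if not np.allclose(row_sums, 1.0, atol=1e-9):
        raise ValueError("input must be closed to 1 (use to_relative first)")

    zero_mask = X == 0
    z = zero_mask.sum(axis=1)
    if library_sizes is not None:
        ls = np.asarray(library_sizes, dtype=float)
        if ls.shape != (n,) or np.any(ls <= 0):
            raise ValueError("library_sizes must be positive, one per sample")
        dl = 1.0 / ls
    else:
        masked = np.where(zero_mask, np.inf, X)
        dl = masked.min(axis=1)
    delta = delta_frac * dl

    min_nonzero = np.where(zero_mask, np.inf, X).min(axis=1)
    bad = (z > 0) & (delta >= min_nonzero)
    if np.any(bad):
        logger.warning(
            "replace_zeros_czm: replacement value exceeds an observed part in %d samples",
            int(bad.sum()),
        )

    shrink = 1.0 - z * delta
    if np.any(shrink <= 0):
        raise ValueError("zero-replacement mass exceeds 1; lower delta_frac")
    out = X * shrink[:, None]
    rows, cols = np.nonzero(zero_mask)
    out[rows, cols] = delta[rows]
    return pd.DataFrame(out, index=rel.index, columns=rel.columns)


def clr(rel: pd.DataFrame) -> pd.DataFrame:
    """Centred log-ratio transform: log of each part over the row's
    geometric mean.  Rows of the output sum to zero; input must be
    strictly positive (zero-replace first)."""
    X = rel.to_numpy(dtype=float)
    if np.any(X <= 0):
        raise ValueError("clr requires strictly positive entries; zero-replace first")
    L = np.log(X)
    out = L - L.mean(axis=1, keepdims=True)
    return pd.DataFrame(out, index=rel.index, columns=rel.columns)


def scale_columns(X: pd.DataFrame, mode: str = "center") -> pd.DataFrame:
    """Column-center, or autoscale to unit sample standard deviation.

    Columns with sd < 1e-12 are left centered only (and logged) to avoid
    dividing by zero on degenerate OTUs.
    """
    if mode not in {"center", "autoscale"}:
        raise ValueError(f"unknown scaling mode {mode!r}")
    out = X - X.mean(axis=0)
    if mode == "autoscale":
        sd = X.std(axis=0, ddof=1)
        degenerate = sd < 1e-12
        if degenerate.any():
            logger.warning(
                "scale_columns: %d constant columns left centered only",
                int(degenerate.sum()),
            )
        sd = sd.where(~degenerate, 1.0)
        out = out / sd
    return out
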