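"""Model design matrices with sum-to-zero contrasts, and the projection
machinery shared by the ANOVA-type decompositions.

Terms are coded with sum-to-zero contrasts (a k-level factor yields k-1
columns); interaction codings are element-wise products of the parents'
columns.  Columns that are linearly dependent on earlier terms (e.g. a
subject factor nested in diet in a crossover design) are dropped with a
log entry so the full model matrix has full column rank.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd

logger = logging.getLogger("microbench")

__all__ = ["Term", "DesignMatrices", "build_design", "parse_formula"]

_RANK_TOL = 1e-8


@dataclass
class Term:
    """One model term: its name, parent factors and coding columns."""

    name: str
    factors: tuple[str, ...]
    columns: np.ndarray  # n × q coding matrix, columns sum to zero
    n_dropped: int = 0

    @property
    def df(self) -> int:
        return self.columns.shape[1]


@dataclass
class DesignMatrices:
    """Coded model terms plus cached orthonormal bases for projections."""

    terms: list[Term]
    n: int
    balanced: bool
    _seq_bases: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if not self._seq_bases:
            self._seq_bases = _sequential_bases(self.n, [t.columns for t in self.terms])

    @property
    def term_names(self) -> list[str]:
        return [t.name for t in self.terms]

    def sequential_basis(self, i: int) -> np.ndarray:
        """Orthonormal basis of term i's subspace after removing terms < i."""
        return self._seq_bases[i]

    def partial_basis(self, i: int) -> np.ndarray:
        """Orthonormal basis of term i's subspace adjusted for all others."""
        others = [t.columns for j, t in enumerate(self.terms) if j != i]
        bases = _sequential_bases(self.n, others + [self.terms[i].columns])
        return bases[-1]

    def full_basis(self) -> np.ndarray:
        if self._seq_bases:
            return np.hstack(self._seq_bases)
        return np.zeros((self.n, 0))

    def projector(self, basis: np.ndarray) -> np.ndarray:
        return basis @ basis.T

    @property
    def model_df(self) -> int:
        return sum(b.shape[1] for b in self._seq_bases)

    @property
    def residual_df(self) -> int:
        return self.n - 1 - self.model_df


def parse_formula(formula: str) -> tuple[tuple[str, ...], ...]:
    """Parse a minimal model formula into an ordered tuple of terms.

    Supports '+' separated terms, ':' interactions and '*' crossing
    (``a*b`` expands to ``a + b + a:b``).  Example::

        parse_formula("fiber*dose + subject")
        -> (("fiber",), ("dose",), ("fiber", "dose"), ("subject",))
    """
    terms: list[tuple[str, ...]] = []

    def add(t: tuple[str, ...]) -> None:
        if t not in terms:
            terms.append(t)

    for chunk in formula.split("+"):
        chunk = chunk.strip()
        if not chunk:
            continue
        if "*" in chunk:
            parts = tuple(p.strip() for p in re.split(r"\*", chunk))
            for p in parts:
                add((p,))
            for r in range(2, len(parts) + 1):
                from itertools import combinations

                for combo in combinations(parts, r):
                    add(combo)
        elif ":" in chunk:
            add(tuple(p.strip() for p in chunk.split(":")))
        else:
            add((chunk,))
    return tuple(terms)


def _sum_coding(labels: pd.Series) -> np.ndarray:
    """Sum-to-zero contrast coding: k levels → n × (k-1) matrix."""
    levels = sorted(map(str, pd.unique(labels)))
    if len(levels) < 2:
        raise ValueError(f"factor {labels.name!r} has a single level")
    lab = labels.astype(str).to_numpy()
    k = len(levels)
    C = np.zeros((len(lab), k - 1))
    for j, lev in enumerate(levels[:-1]):
        C[lab == lev, j] = 1.0
    C[lab == levels[-1], :] = -1.0
    return C


def _orthonormal_increment(Q: np.ndarray, A: np.ndarray) -> np.ndarray:
    """Orthonormal basis of span(A) beyond span(Q) (columns may be aliased)."""
    if A.shape[1] == 0:
        return np.zeros((A.shape[0], 0))
    R = A - Q @ (Q.T @ A) if Q.shape[1] else A.copy()
    U, s, _ = np.linalg.svd(R, full_matrices=False)
    scale = max(s[0], 1.0) if s.size else 1.0
    keep = s > _RANK_TOL * scale
    return U[:, keep]


def _sequential_bases(n: int, columns: list[np.ndarray]) -> list[np.ndarray]:
    """Per-term orthonormal bases after the intercept and all earlier terms."""
    Q = np.ones((n, 1)) / np.sqrt(n)  # intercept
    bases = []
    for A in columns:
        B = _orthonormal_increment(Q, A)
        bases.append(B)
        if B.shape[1]:
            Q = np.hstack([Q, B])
    return bases


def build_design(
    metadata: pd.DataFrame,
    terms: str | tuple[tuple[str, ...], ...],
) -> DesignMatrices:
    """Build sum-to-zero coded design matrices from sample metadata.

    ``terms`` is a formula string (``"fiber*dose + subject"``) or an
    already-parsed tuple of factor-name tuples, in model order.
    """
    if isinstance(terms, str):
        terms = parse_formula(terms)
    built: list[Term] = []
    for t in terms:
        for f in t:
            if f not in metadata.columns:
                raise ValueError(f"factor {f!r} not in metadata columns {list(metadata.columns)}")
        codes = [_sum_coding(metadata[f]) for f in t]
        C = codes[0]
        for nxt in codes[1:]:
            C = np.hstack([C[:, [i]] * nxt for i in range(C.shape[1])])
        built.append(Term(name=":".join(t), factors=t, columns=C))

    n = len(metadata)
    bases = _sequential_bases(n, [t.columns for t in built])
    for t, B in zip(built, bases):
        full_df = t.columns.shape[1]
        t.n_dropped = full_df - B.shape[1]
        if t.n_dropped:
            logger.info(
                "build_design: term %s aliased with earlier terms, dropped %d of %d columns",
                t.name, t.n_dropped, full_df,
            )
        if B.shape[1] == 0:
            raise ValueError(f"term {t.name} is fully aliased with earlier terms")

    factors_used = sorted({f for t in built for f in t.factors})
    cells = metadata[factors_used].astype(str).agg(".".join, axis=1)
    balanced = cells.value_counts().nunique() == 1
    return DesignMatrices(terms=built, n=n, balanced=balanced, _seq_bases=bases)
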