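"""Data model and file I/O for OTU count tables and study metadata.

The central in-memory containers are thin wrappers around pandas objects:

* :class:`CountMatrix` — a samples × OTUs table of non-negative integer
  counts (or relative abundances when ``relative=True``).
* sample metadata — a plain :class:`pandas.DataFrame` indexed by sample id,
  with one categorical column per experimental factor.
* :class:`StudyDesign` — the declared factors/levels and the model terms
  (main effects, interactions, fixed subject blocks).
* :class:`Dataset` — counts + metadata + design with sample ids aligned.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("microbench")

__all__ = [
    "FormatError",
    "AlignmentError",
    "CountMatrix",
    "StudyDesign",
    "Dataset",
    "read_count_table",
    "read_metadata",
    "align",
    "write_results",
    "read_results",
]


class FormatError(ValueError):
    """Raised when an input table violates the count-matrix contract."""


class AlignmentError(ValueError):
    """Raised when count and metadata sample ids cannot be reconciled."""


@dataclass
class CountMatrix:
    """Samples × OTUs abundance table.

    Parameters
    ----------
    values
        DataFrame with sample ids as the index and OTU ids as columns.
        Entries must be non-negative; integers unless ``relative=True``.
    relative
        When True the matrix holds relative abundances and no library
        sizes are defined.
    """

    values: pd.DataFrame
    relative: bool = False

    def __post_init__(self) -> None:
        v = self.values
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise FormatError("count matrix needs at least 2 samples and 2 OTUs")
        if v.index.has_duplicates or v.columns.has_duplicates:
            raise FormatError("duplicate sample or OTU ids")
        arr = v.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise FormatError("non-numeric entries in count table")
        if np.any(arr < 0):
            raise FormatError("negative entries in count table")
        if not self.relative:
            if not np.allclose(arr, np.round(arr)):
                raise FormatError(
                    "non-integer counts; pass relative=True for abundance tables"
                )
            self.values = v.astype(np.int64)
            if np.any(self.library_sizes <= 0):
                raise FormatError("sample with zero total count")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_otus(self) -> int:
        return self.values.shape[1]

    @property
    def library_sizes(self) -> pd.Series | None:
        """Per-sample sequencing depth (row sums); None for relative data."""
        if self.relative:
            return None
        return self.values.sum(axis=1)

    def subset_samples(self, ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.values.loc[list(ids)], relative=self.relative)


@dataclass
class StudyDesign:
    """Experimental factors and model terms.

    ``factors`` maps factor name → ordered level labels.  ``terms`` is an
    ordered tuple of model terms, each a tuple of factor names: a 1-tuple
    is a main effect (or a fixed subject block), an n-tuple an interaction.
    """

    factors: dict[str, list[str]]
    terms: tuple[tuple[str, ...], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for term in self.terms:
            for f in term:
                if f not in self.factors:
                    raise ValueError(f"term references undeclared factor {f!r}")
            if len(term) > 1 and len(set(term)) < 2:
                raise ValueError(f"interaction term {term} repeats a factor")

    @staticmethod
    def from_metadata(
        metadata: pd.DataFrame, terms: tuple[tuple[str, ...], ...] = ()
    ) -> "StudyDesign":
        factors = {
            c: sorted(map(str, pd.unique(metadata[c]))) for c in metadata.columns
        }
        return StudyDesign(factors=factors, terms=terms)

    def combined_factor(self, metadata: pd.DataFrame, names: Sequence[str] | None = None) -> pd.Series:
        """Concatenate factor levels into one grouping label per sample.

        Used by one-way methods (ANOSIM) that cannot model several factors,
        and to define design cells for the simulator and OTU filter.
        """
        names = list(names) if names is not None else list(self.factors)
        lab = metadata[names[0]].astype(str)
        for n in names[1:]:
            lab = lab + "." + metadata[n].astype(str)
        lab.name = ".".join(names)
        return lab


@dataclass
class Dataset:
    """Counts, metadata and design with identical sample order."""

    counts: CountMatrix
    metadata: pd.DataFrame
    design: StudyDesign | None = None

    def __post_init__(self) -> None:
        if list(self.counts.values.index) != list(self.metadata.index):
            raise AlignmentError("counts and metadata sample ids differ; use align()")


def _read_table(path: str | Path, sheet: str | int | None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".xlsx", ".xls"}:
        return pd.read_excel(path, sheet_name=sheet if sheet is not None else 0, index_col=0)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    return pd.read_csv(path, sep=sep, index_col=0)


def read_count_table(
    path: str | Path,
    orientation: str = "samples-in-rows",
    relative: bool = False,
    sheet: str | int | None = None,
) -> CountMatrix:
    """Read a count (or relative-abundance) table from TSV/CSV/XLSX.

    ``orientation`` is ``samples-in-rows`` or ``otus-in-rows``; wide
    spreadsheets with one sheet per study are addressed via ``sheet``.
    """
    if orientation not in {"samples-in-rows", "otus-in-rows"}:
        raise ValueError(f"unknown orientation {orientation!r}")
    df = _read_table(path, sheet)
    if orientation == "otus-in-rows":
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"non-numeric body in {path}: {exc}") from exc
    return CountMatrix(df, relative=relative)


def read_metadata(path: str | Path, sheet: str | int | None = None) -> pd.DataFrame:
    """Read a sample metadata table (sample id in the first column)."""
    df = _read_table(path, sheet)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        raise FormatError("duplicate sample ids in metadata")
    return df


def align(
    counts: CountMatrix,
    metadata: pd.DataFrame,
    design: StudyDesign | None = None,
) -> Dataset:
    """Restrict counts and metadata to their common samples, in count order.

    Sample order follows the count table so that downstream permutation
    seeds are reproducible regardless of metadata row order.
    """
    common = [s for s in counts.sample_ids if s in metadata.index]
    if not common:
        raise AlignmentError("no samples in common between counts and metadata")
    dropped = (set(counts.sample_ids) | set(metadata.index)) - set(common)
    if dropped:
        logger.warning("align: dropping %d unmatched samples: %s", len(dropped), sorted(dropped))
    return Dataset(
        counts=counts.subset_samples(common),
        metadata=metadata.loc[common],
        design=design,
    )


def write_results(table: pd.DataFrame, path: str | Path, format: str = "tsv") -> None:
    """Write a finished result table to TSV or JSON (≥6 significant digits)."""
    path = Path(path)
    if format == "tsv":
        table.to_csv(path, sep="\t", float_format="%.9g")
    elif format == "json":
        table.to_json(path, orient="table", double_precision=12)
    else:
        raise ValueError(f"unknown format {format!r}")


def read_results(path: str | Path, format: str = "tsv") -> pd.DataFrame:
    path = Path(path)
    if format == "tsv":
        return pd.read_csv(path, sep="\t", index_col=0)
    if format == "json":
        return pd.read_json(path, orient="table")
    raise ValueError(f"unknown format {format!r}")
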