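"""Shared data containers and exception types.

The pipeline's interchange objects are deliberately thin: a validated
count matrix with its sample design, and plain :class:`pandas.DataFrame`
tables with documented required columns for everything downstream
(differential-expression tables, ranked profiles, enrichment results).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RanksetError",
    "ConfigError",
    "ValidationError",
    "FormatError",
    "CountMatrix",
    "DE_COLUMNS",
    "validate_de_table",
]


class RanksetError(Exception):
    """Base class for all errors raised by this package."""


class ConfigError(RanksetError, ValueError):
    """An invalid configuration value; the message names the field."""


class ValidationError(RanksetError, ValueError):
    """Input data violates a documented invariant."""


class FormatError(RanksetError, ValueError):
    """A file could not be parsed; the message carries the location."""


@dataclass
class CountMatrix:
    """Non-negative integer gene x sample count table with a sample design.

    Parameters
    ----------
    counts:
        DataFrame indexed by gene identifier with one column per sample.
        Entries must be non-negative integers.
    design:
        Series mapping sample identifier to group label, in sample order.
        Must cover exactly the columns of ``counts``.
    """

    counts: pd.DataFrame
    design: pd.Series

    def __post_init__(self) -> None:
        counts = self.counts
        if counts.index.has_duplicates:
            dupes = counts.index[counts.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene identifiers: {dupes[:5]}")
        upper = counts.index.str.upper()
        if upper.has_duplicates:
            dupes = upper[upper.duplicated()].unique().tolist()
            raise ValidationError(
                f"gene identifiers collide after case normalization: {dupes[:5]}"
            )
        if counts.columns.has_duplicates:
            raise ValidationError("duplicate sample identifiers")
        values = counts.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValidationError("counts must be integer-valued")
            counts = counts.round().astype(np.int64)
            self.counts = counts
            values = counts.to_numpy()
        if (values < 0).any():
            raise ValidationError("counts must be non-negative")
        missing = [s for s in counts.columns if s not in self.design.index]
        if missing:
            raise ValidationError(f"samples missing from design: {missing}")
        extra = [s for s in self.design.index if s not in counts.columns]
        if extra:
            raise ValidationError(f"design samples absent from counts: {extra}")
        # canonical ordering: samples as listed in the design
        self.counts = counts.loc[:, self.design.index]

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def samples_in_group(self, group: str) -> list[str]:
        """Sample identifiers assigned to ``group``, in design order."""
        return list(self.design.index[self.design == group])

    def subset_genes(self, gene_ids) -> "CountMatrix":
        """New matrix restricted to ``gene_ids`` (order preserved)."""
        return CountMatrix(self.counts.loc[gene_ids], self.design.copy())


#: Required columns of a differential-expression table.
DE_COLUMNS = ("gene_id", "log2fc", "p", "fdr", "ave_expr")


def validate_de_table(de: pd.DataFrame, *, require_fdr: bool = True) -> pd.DataFrame:
    """Check a DE table's invariants and return it unchanged.

    Required columns: ``gene_id`` (unique, upper-case), ``log2fc``
    (finite), ``p`` in (0, 1]; ``fdr`` and ``ave_expr`` when present must
    be finite, with ``fdr`` in (0, 1].
    """
    for col in ("gene_id", "log2fc", "p"):
        if col not in de.columns:
            raise ValidationError(f"DE table missing required column {col!r}")
    if require_fdr and "fdr" not in de.columns:
        raise ValidationError("DE table missing required column 'fdr'")
    if de["gene_id"].duplicated().any():
        dupes = de.loc[de["gene_id"].duplicated(), "gene_id"].unique().tolist()
        raise ValidationError(f"duplicate gene identifiers in DE table: {dupes[:5]}")
    lfc = de["log2fc"].to_numpy(dtype=float)
    if not np.isfinite(lfc).all():
        raise ValidationError("log2fc contains non-finite values")
    p = de["p"].to_numpy(dtype=float)
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1] with no missing values")
    if "fdr" in de.columns:
        q = de["fdr"].to_numpy(dtype=float)
        if np.isnan(q).any() or (q <= 0).any() or (q > 1).any():
            raise ValidationError("fdr values must lie in (0, 1]")
    return de
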