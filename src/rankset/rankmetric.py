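"""Directional significance scores and centered scaled ranks.

The score combines the direction of the fold change with the
significance of the test: ``s = sign(log2fc) * (-log10 p)``, so large
positive scores are confidently up-regulated genes and large negative
scores confidently down-regulated ones.

Note on the literal formula ``sign(log2fc) / log10(p)``: it does not
order genes from most up- to most down-regulated (an up-regulated gene
at p = 1e-10 would score -0.1 while one at p = 0.9 scores -21.9). The
default implementation therefore uses ``sign * (-log10 p)``, which
induces the same ordering as ``sign / p`` and matches the score's stated
purpose; the literal arithmetic is available behind ``literal=True``
for audit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .datatypes import ValidationError, validate_de_table

__all__ = ["score_genes", "rank_profile"]

#: Default floor applied to p-values before taking log10.
P_FLOOR = 1e-300


def score_genes(
    de: pd.DataFrame,
    p_floor: float = P_FLOOR,
    *,
    literal: bool = False,
    use_fdr: bool = False,
) -> pd.DataFrame:
    """Per-gene directional significance score from a DE table.

    ``s = sign(log2fc) * (-log10 max(p, p_floor))``; zero when
    ``log2fc == 0`` or ``p == 1``. ``use_fdr=True`` substitutes the fdr
    column for the raw p (available without endorsement). Returns a
    DataFrame with columns ``gene_id`` and ``score``.
    """
    validate_de_table(de, require_fdr=use_fdr)
    if p_floor <= 0:
        raise ValidationError("p_floor must be > 0")
    p = de["fdr" if use_fdr else "p"].to_numpy(dtype=float)
    if (p <= 0).any():
        raise ValidationError("p-values must be > 0 (floor zeros upstream)")
    sign = np.sign(de["log2fc"].to_numpy(dtype=float))
    logp = np.log10(np.maximum(p, p_floor))
    if literal:
        with np.errstate(divide="ignore"):
            score = np.where(logp == 0.0, 0.0, sign / logp)
    else:
        score = sign * (-logp)
    # normalize -0.0 to 0.0 for clean serialization
    score = score + 0.0
    return pd.DataFrame({"gene_id": de["gene_id"].to_numpy(), "score": score})


def rank_profile(scored: pd.DataFrame) -> pd.DataFrame:
    """Integer (tie-averaged) and centered scaled ranks of scored genes.

    Rank N is the largest score (most up-regulated), rank 1 the
    smallest; ties receive the average of their rank range. The scaled
    rank is ``(rank - (N + 1) / 2) / N``, lying in (-0.5, 0.5) and
    summing to zero exactly.
    """
    if "score" not in scored.columns or "gene_id" not in scored.columns:
        raise ValidationError("expected columns 'gene_id' and 'score'")
    n = len(scored)
    if n < 2:
        raise ValidationError("need at least 2 genes to rank")
    score = scored["score"].to_numpy(dtype=float)
    if not np.isfinite(score).all():
        raise ValidationError("scores must be finite")
    rank = rankdata(score, method="average")
    scaled = (rank - (n + 1) / 2.0) / n
    return pd.DataFrame(
        {
            "gene_id": scored["gene_id"].to_numpy(),
            "score": score,
            "rank": rank,
            "scaled_rank": scaled,
        }
    )
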