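"""Pre-ranked gene-set enrichment analysis, classic (unweighted) mode.

The enrichment score is the Kolmogorov-Smirnov-style extremal deviation
of a running sum that walks the ranked gene list from most up-regulated
to most down-regulated, stepping up by ``1/Nh`` at set members and down
by ``1/(N - Nh)`` elsewhere. Significance comes from a gene-tag
permutation null (random same-size member sets), with normalized
enrichment scores and a signed FDR computed against the pooled null.

Phenotype permutation is not offered: the statistic is computed from an
externally ranked list, with no per-sample data in sight.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Sequence

import numpy as np
import pandas as pd

from .datatypes import ValidationError
from .formats import GeneSetCollection

logger = logging.getLogger(__name__)

__all__ = ["running_es", "running_profile", "gsea_preranked", "order_ranked_list"]

#: Tolerance for deciding a positive/negative extremum magnitude tie.
_ES_TIE_TOL = 1e-12


def order_ranked_list(profile: pd.DataFrame) -> list[str]:
    """Gene identifiers ordered from most up- to most down-regulated.

    Ties in score are broken lexicographically by gene identifier so the
    walk (and everything downstream) is deterministic.
    """
    ordered = profile.sort_values(
        ["score", "gene_id"], ascending=[False, True], kind="mergesort"
    )
    return list(ordered["gene_id"])


def _es_from_positions(pos: np.ndarray, n: int) -> tuple[float, int, int]:
    """ES, extremum walk index, and extremum hit index from member positions.

    ``pos`` holds the 0-based positions of the ``nh`` members within the
    ranked list of length ``n``, sorted ascending. The walk's local
    maxima occur immediately after hits and its local minima immediately
    before hits, so only those 2*nh values need inspection.
    """
    nh = pos.size
    j = np.arange(1, nh + 1)
    miss_weight = 1.0 / (n - nh)
    val_after = j / nh - (pos + 1 - j) * miss_weight
    val_before = (j - 1) / nh - (pos - (j - 1)) * miss_weight
    # earliest hit attaining each extremum within tolerance (accumulated
    # rounding must not push the selection to a later duplicate)
    jmax = int(np.argmax(val_after >= val_after.max() - _ES_TIE_TOL))
    jmin = int(np.argmax(val_before <= val_before.min() + _ES_TIE_TOL))
    es_pos, es_neg = float(val_after[jmax]), float(val_before[jmin])
    idx_pos = int(pos[jmax])  # walk index where the max is attained
    idx_neg = int(pos[jmin]) - 1  # just before the hit
    # magnitude comparison with float tolerance: step sums accumulate
    # rounding, and an exact tie must not be decided by the last ulp
    diff = abs(es_pos) - abs(es_neg)
    if diff > _ES_TIE_TOL:
        return es_pos, idx_pos, jmax
    if diff < -_ES_TIE_TOL:
        return es_neg, idx_neg, jmin
    # tie in magnitude: take the deviation encountered first in the walk
    logger.debug("ES magnitude tie (|ES|=%.6g); taking the earlier extremum", es_pos)
    if idx_pos <= idx_neg:
        return es_pos, idx_pos, jmax
    return es_neg, idx_neg, jmin


def running_es(
    ranked_genes: Sequence[str], member_genes: Iterable[str]
) -> tuple[float, int, list[str]]:
    """Classic-mode enrichment score of one set against one ranked list.

    Returns ``(es, extremum_index, leading_edge)`` where
    ``extremum_index`` is the 0-based position in the walk at which the
    extremal deviation is attained and ``leading_edge`` the member genes
    at or before it (positive ES) or at or after the minimum (negative
    ES), in list order.
    """
    ranked = list(ranked_genes)
    n = len(ranked)
    if len(set(ranked)) != n:
        raise ValidationError("ranked list contains duplicate genes")
    members = {str(g).upper() for g in member_genes}
    pos = np.array([i for i, g in enumerate(ranked) if g in members], dtype=np.int64)
    nh = pos.size
    if nh == 0:
        raise ValidationError("gene set has no overlap with the ranked list")
    if nh == n:
        raise ValidationError("gene set covers the whole ranked list; ES undefined")
    es, idx, jext = _es_from_positions(pos, n)
    if es >= 0:
        leading = [ranked[i] for i in pos[: jext + 1]]
    else:
        leading = [ranked[i] for i in pos[jext:]]
    return es, idx, leading


def running_profile(ranked_genes: Sequence[str], member_genes: Iterable[str]) -> pd.DataFrame:
    """Full running-sum walk, exported as a table (for plotting elsewhere)."""
    ranked = list(ranked_genes)
    members = {str(g).upper() for g in member_genes}
    hits = np.array([g in members for g in ranked])
    nh = int(hits.sum())
    n = len(ranked)
    if nh == 0 or nh == n:
        raise ValidationError("member overlap must satisfy 0 < Nh < N")
    steps = np.where(hits, 1.0 / nh, -1.0 / (n - nh))
    return pd.DataFrame(
        {"gene_id": ranked, "hit": hits.astype(int), "running_sum": np.cumsum(steps)}
    )


def _es_batch(pos: np.ndarray, n: int) -> np.ndarray:
    """Vectorized ES for a batch of member-position rows (each sorted)."""
    b, nh = pos.shape
    j = np.arange(1, nh + 1)
    miss_weight = 1.0 / (n - nh)
    val_after = j / nh - (pos + 1 - j) * miss_weight
    val_before = (j - 1) / nh - (pos - (j - 1)) * miss_weight
    jmax = np.argmax(val_after >= val_after.max(axis=1, keepdims=True) - _ES_TIE_TOL, axis=1)
    jmin = np.argmax(val_before <= val_before.min(axis=1, keepdims=True) + _ES_TIE_TOL, axis=1)
    rows = np.arange(b)
    es_pos = val_after[rows, jmax]
    es_neg = val_before[rows, jmin]
    idx_pos = pos[rows, jmax]
    idx_neg = pos[rows, jmin] - 1
    diff = np.abs(es_pos) - np.abs(es_neg)
    take_pos = diff > _ES_TIE_TOL
    tie = np.abs(diff) <= _ES_TIE_TOL
    take_pos |= tie & (idx_pos <= idx_neg)
    return np.where(take_pos, es_pos, es_neg)


def gsea_preranked(
    profile: pd.DataFrame,
    sets: GeneSetCollection,
    min_size: int = 10,
    max_size: int = 5000,
    nperm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Classic-mode pre-ranked GSEA over a gene-set collection.

    Parameters
    ----------
    profile:
        Ranked profile with columns ``gene_id`` and ``score``.
    sets:
        Gene-set collection; sets are intersected with the profile's
        genes and filtered to ``[min_size, max_size]`` before testing.
    nperm:
        Number of gene-tag permutations (random same-size member sets)
        per set; must be >= 100.
    seed:
        Seed for the permutation generator; same seed, same results.

    Returns
    -------
    DataFrame with one row per tested set: ``set_name, size, es, nes,
    p, fdr_q, leading_edge`` (comma-joined gene identifiers), sorted by
    nominal p then set name.
    """
    if nperm < 100:
        raise ValidationError("nperm must be >= 100")
    ranked = order_ranked_list(profile)
    n = len(ranked)
    index_of = {g: i for i, g in enumerate(ranked)}
    tested = sets.restrict(universe=ranked, min_size=max(min_size, 1), max_size=max_size)
    if len(tested) == 0:
        raise ValidationError("no gene set passes the size filter against this profile")
    dropped = [name for name in sets if name not in tested]
    if dropped:
        logger.info("gsea: %d sets dropped by overlap/size filter", len(dropped))

    rng = np.random.default_rng(seed)
    # one shared permutation matrix; size-Nh null subsets are its first Nh columns
    perms = rng.permuted(
        np.tile(np.arange(n, dtype=np.int32), (nperm, 1)), axis=1
    )

    null_by_size: dict[int, np.ndarray] = {}

    def null_es(nh: int) -> np.ndarray:
        if nh not in null_by_size:
            null_by_size[nh] = _es_batch(np.sort(perms[:, :nh], axis=1), n)
        return null_by_size[nh]

    rows = []
    null_nes_pool: list[np.ndarray] = []
    for name, members in tested.items():
        pos = np.sort(np.array([index_of[g] for g in members], dtype=np.int64))
        es, _, jext = _es_from_positions(pos, n)
        if es >= 0:
            leading = [ranked[i] for i in pos[: jext + 1]]
        else:
            leading = [ranked[i] for i in pos[jext:]]
        null = null_es(pos.size)
        same_sign = null >= 0 if es >= 0 else null < 0
        n_same = int(same_sign.sum())
        if n_same == 0:
            logger.warning("gsea: set %s has no same-sign null values; p/NES missing", name)
            p = np.nan
            nes = np.nan
        else:
            p = (1 + int((np.abs(null[same_sign]) >= abs(es)).sum())) / (1 + n_same)
            nes = es / float(np.abs(null[same_sign]).mean())
        pos_null = null[null >= 0]
        neg_null = null[null < 0]
        nes_null = np.concatenate(
            [
                pos_null / pos_null.mean() if pos_null.size else pos_null,
                neg_null / np.abs(neg_null).mean() if neg_null.size else neg_null,
            ]
        )
        null_nes_pool.append(nes_null)
        rows.append(
            {
                "set_name": name,
                "size": pos.size,
                "es": es,
                "nes": nes,
                "p": p,
                "leading_edge": ",".join(leading),
            }
        )

    result = pd.DataFrame(rows)
    result["fdr_q"] = _signed_fdr(
        result["nes"].to_numpy(), np.concatenate(null_nes_pool) if null_nes_pool else np.empty(0)
    )
    result = result.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)
    return result[["set_name", "size", "es", "nes", "p", "fdr_q", "leading_edge"]]


def _signed_fdr(obs_nes: np.ndarray, null_nes: np.ndarray) -> np.ndarray:
    """GSEA-style FDR q: pooled-null tail fraction over observed tail fraction."""
    q = np.full(obs_nes.shape, np.nan)
    finite = np.isfinite(obs_nes)
    null_pos = null_nes[null_nes >= 0]
    null_neg = null_nes[null_nes < 0]
    obs_pos = obs_nes[finite & (obs_nes >= 0)]
    obs_neg = obs_nes[finite & (obs_nes < 0)]
    for i, nes in enumerate(obs_nes):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            if null_pos.size == 0 or obs_pos.size == 0:
                continue
            num = (null_pos >= nes).mean()
            den = (obs_pos >= nes).mean()
        else:
            if null_neg.size == 0 or obs_neg.size == 0:
                continue
            num = (null_neg <= nes).mean()
            den = (obs_neg <= nes).mean()
        q[i] = min(1.0, num / den) if den > 0 else np.nan
    return q
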