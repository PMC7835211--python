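"""Two-dimensional rank-rank gene-set association.

Two differential-expression contrasts are joined on their common gene
universe; each gene gets a centered scaled rank per contrast, placing it
in the square (-0.5, 0.5)^2. A gene set's coordinated displacement away
from the uniform background is summarized by per-dimension enrichment
scores and tested with a two-group (members vs. rest) one-way MANOVA of
the rank coordinates. For two groups Pillai's trace has an exact F and
is equivalent to Hotelling's T-squared:

    T2 = (k (N - k) / N) * dbar' S^-1 dbar
    F  = T2 (N - 3) / (2 (N - 2))   on (2, N - 3) df

with ``dbar`` the member-minus-rest mean rank vector and ``S`` the
pooled within-group covariance. Being rank-based, the test is invariant
to any order-preserving transform of the underlying scores.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from .datatypes import ValidationError, validate_de_table
from .diffexpr import bh_adjust
from .formats import GeneSetCollection
from .rankmetric import P_FLOOR, rank_profile, score_genes

logger = logging.getLogger(__name__)

__all__ = [
    "join_contrasts",
    "set_scores_2d",
    "manova_rank_test",
    "enrich2d_all",
    "density_grid",
]

#: Minimum joined universe size for the rank asymptotics to make sense.
MIN_UNIVERSE = 10


def _dedupe(de: pd.DataFrame, which: str) -> pd.DataFrame:
    """Resolve duplicate gene rows by keeping the smallest p (logged)."""
    if not de["gene_id"].duplicated().any():
        return de
    dupes = de.loc[de["gene_id"].duplicated(), "gene_id"].unique()
    for g in dupes:
        logger.info("join_contrasts: %s duplicated in %s; keeping smallest p", g, which)
    return de.sort_values("p", kind="mergesort").drop_duplicates("gene_id").sort_index()


def join_contrasts(
    de1: pd.DataFrame,
    de2: pd.DataFrame,
    p_floor: float = P_FLOOR,
    *,
    literal: bool = False,
) -> pd.DataFrame:
    """Join two DE tables into a two-dimensional rank table.

    The gene universe is the intersection of the two tables' gene
    identifiers; directional scores are computed on each table restricted
    to that universe and scaled ranks recomputed within it. Swapping the
    inputs swaps the (s1, r1) and (s2, r2) columns.

    Returns a DataFrame with columns ``gene_id, s1, s2, r1, r2``.
    """
    de1 = _dedupe(de1.reset_index(drop=True), "first table")
    de2 = _dedupe(de2.reset_index(drop=True), "second table")
    validate_de_table(de1, require_fdr=False)
    validate_de_table(de2, require_fdr=False)
    universe = pd.Index(de1["gene_id"]).intersection(pd.Index(de2["gene_id"]))
    if len(universe) < MIN_UNIVERSE:
        raise ValidationError(
            f"joined gene universe has {len(universe)} genes; need >= {MIN_UNIVERSE}"
        )
    parts = []
    for dim, de in enumerate((de1, de2), start=1):
        sub = de[de["gene_id"].isin(universe)].reset_index(drop=True)
        ranked = rank_profile(score_genes(sub, p_floor, literal=literal))
        parts.append(
            ranked.rename(columns={"score": f"s{dim}", "scaled_rank": f"r{dim}"})[
                ["gene_id", f"s{dim}", f"r{dim}"]
            ].set_index("gene_id")
        )
    joint = parts[0].join(parts[1], how="inner").reset_index()
    return joint[["gene_id", "s1", "s2", "r1", "r2"]]


def _member_mask(joint: pd.DataFrame, member_genes: Iterable[str]) -> np.ndarray:
    members = {str(g).upper() for g in member_genes}
    return joint["gene_id"].isin(members).to_numpy()


def set_scores_2d(
    joint: pd.DataFrame, member_genes: Iterable[str]
) -> tuple[float, float, float]:
    """Per-dimension enrichment scores ``s_d = 2 * mean(r_d)`` over members.

    The factor 2 makes a set occupying an extreme flank approach +/-1
    regardless of universe size (|s_d| <= (N - k) / N exactly). Returns
    ``(s1_set, s2_set, s_dist)``.
    """
    mask = _member_mask(joint, member_genes)
    k = int(mask.sum())
    if k < 2:
        raise ValidationError(f"set has {k} members in the joined universe; need >= 2")
    if k >= len(joint):
        raise ValidationError("set covers the whole universe; scores undefined")
    s1 = 2.0 * float(joint.loc[mask, "r1"].mean())
    s2 = 2.0 * float(joint.loc[mask, "r2"].mean())
    return s1, s2, float(np.hypot(s1, s2))


def manova_rank_test(
    joint: pd.DataFrame, member_genes: Iterable[str]
) -> tuple[float, float, tuple[int, int], float]:
    """Two-group MANOVA (members vs. rest) on the (r1, r2) rank coordinates.

    Returns ``(pillai, F, (df_num, df_den), p)``. Raises when the pooled
    covariance is singular, naming the degenerate dimension.
    """
    mask = _member_mask(joint, member_genes)
    n = len(joint)
    k = int(mask.sum())
    if k < 2:
        raise ValidationError(f"set has {k} members in the joined universe; need >= 2")
    if n - k < 3:
        raise ValidationError("need at least 3 non-member genes")
    x = joint[["r1", "r2"]].to_numpy(dtype=float)
    xm, xr = x[mask], x[~mask]
    dbar = xm.mean(axis=0) - xr.mean(axis=0)
    within = (xm - xm.mean(axis=0)).T @ (xm - xm.mean(axis=0)) + (
        xr - xr.mean(axis=0)
    ).T @ (xr - xr.mean(axis=0))
    s_pooled = within / (n - 2)
    diag = np.diag(s_pooled)
    for dim, var in zip(("r1", "r2"), diag):
        if var <= 0:
            raise ValidationError(f"pooled covariance singular: dimension {dim} is constant")
    if np.linalg.det(s_pooled) <= np.finfo(float).tiny * diag.prod():
        raise ValidationError("pooled covariance singular: r1 and r2 are collinear")
    t2 = float(k * (n - k) / n * dbar @ np.linalg.solve(s_pooled, dbar))
    f_stat = t2 * (n - 3) / (2.0 * (n - 2))
    dfs = (2, n - 3)
    p = float(f_dist.sf(f_stat, *dfs))
    pillai = t2 / (t2 + (n - 2))
    return pillai, f_stat, dfs, max(p, np.nextafter(0.0, 1.0))


def enrich2d_all(
    joint: pd.DataFrame, sets: GeneSetCollection, min_size: int = 10
) -> pd.DataFrame:
    """Test every sufficiently large gene set for 2D rank displacement.

    Sets with fewer than ``min_size`` members in the joined universe are
    skipped (logged). FDR is Benjamini-Hochberg across exactly the tested
    sets; rows are sorted by p ascending, ties by set name.
    """
    min_size = max(min_size, 2)
    universe = set(joint["gene_id"])
    rows = []
    for name, members in sets.items():
        present = [g for g in members if g in universe]
        k = len(present)
        if k < min_size or k >= len(universe):
            logger.info("enrich2d: set %s skipped (k=%d)", name, k)
            continue
        s1, s2, s_dist = set_scores_2d(joint, present)
        pillai, f_stat, (df1, df2), p = manova_rank_test(joint, present)
        rows.append(
            {
                "set_name": name,
                "size": k,
                "s1": s1,
                "s2": s2,
                "s_dist": s_dist,
                "pillai": pillai,
                "F": f_stat,
                "df_num": df1,
                "df_den": df2,
                "p": p,
            }
        )
    if not rows:
        raise ValidationError("no gene set passes min_size against the joined universe")
    result = pd.DataFrame(rows)
    result["fdr"] = bh_adjust(result["p"].to_numpy())
    return result.sort_values(["p", "set_name"], kind="mergesort").reset_index(drop=True)


def density_grid(joint: pd.DataFrame, bins: int = 50) -> pd.DataFrame:
    """Gene counts over an equal-width (r1, r2) grid spanning [-0.5, 0.5].

    Rows are r1 (x) bins ascending, columns r2 (y) bins ascending; bins
    are half-open ``[lo, hi)`` except the last, which is closed, so the
    grid total equals the number of genes. Index and columns carry bin
    midpoints.
    """
    if bins < 1:
        raise ValidationError("bins must be >= 1")
    edges = np.linspace(-0.5, 0.5, bins + 1)
    grid, _, _ = np.histogram2d(
        joint["r1"].to_numpy(), joint["r2"].to_numpy(), bins=[edges, edges]
    )
    mids = (edges[:-1] + edges[1:]) / 2.0
    return pd.DataFrame(
        grid.astype(np.int64),
        index=pd.Index(mids, name="r1_mid"),
        columns=pd.Index(mids, name="r2_mid"),
    )
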