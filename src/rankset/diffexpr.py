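"""Low-count filtering, log-CPM normalization and a moderated two-group test.

The testing stage is a documented stand-in for a full count-model
workflow: a moderated t-statistic on log2 counts-per-million, with the
variance prior ``(d0, s0^2)`` estimated from the empirical distribution
of per-gene sample variances by moment matching on the log scale. It is
closed-form, calibration-testable, and can be bypassed entirely by
supplying externally computed DE tables to the enrichment stages.

Normalization is total-count CPM only; compositional (TMM-style)
factors are deliberately omitted — a documented limitation acceptable
for composition-balanced libraries such as the simulator's.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import norm, t as t_dist

from .datatypes import CountMatrix, ValidationError

__all__ = [
    "LogExpressionMatrix",
    "ModeratedTestParams",
    "filter_low_expression",
    "log_cpm",
    "moderated_two_group_test",
    "bh_adjust",
    "estimate_variance_prior",
]


@dataclass
class LogExpressionMatrix:
    """log2 counts-per-million with a pseudo-count.

    ``values[g, s] = log2((count + c) / (libsize + 2c) * 1e6)``.
    """

    values: pd.DataFrame
    library_sizes: pd.Series
    pseudo_count: float

    def __post_init__(self) -> None:
        if (self.library_sizes <= 0).any():
            raise ValidationError("library sizes must be positive")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("log-expression values must be finite")


@dataclass(frozen=True)
class ModeratedTestParams:
    """Variance-moderation prior; ``None`` fields are estimated from data."""

    prior_df: float | None = None  # d0 >= 0, possibly inf
    prior_var: float | None = None  # s0^2 > 0
    pseudo_count: float = 0.5

    def __post_init__(self) -> None:
        if self.prior_df is not None and self.prior_df < 0:
            raise ValidationError("prior_df must be >= 0")
        if self.prior_var is not None and self.prior_var <= 0:
            raise ValidationError("prior_var must be > 0")
        if self.pseudo_count <= 0:
            raise ValidationError("pseudo_count must be > 0")


def filter_low_expression(counts: CountMatrix, threshold: float = 10.0) -> CountMatrix:
    """Drop genes averaging fewer than ``threshold`` reads per sample.

    Retains exactly the genes whose row mean is >= ``threshold``
    (a mean of exactly 10 is not "fewer than 10"); gene order preserved.
    Idempotent.
    """
    if threshold < 0:
        raise ValidationError("threshold must be >= 0")
    means = counts.counts.mean(axis=1)
    keep = counts.gene_ids[means >= threshold]
    return counts.subset_genes(keep)


def log_cpm(counts: CountMatrix, pseudo_count: float = 0.5) -> LogExpressionMatrix:
    """Compute log2 counts-per-million with a pseudo-count.

    The pseudo-count enters both numerator and denominator
    (``log2((x + c) / (L + 2c) * 1e6)``), keeping the transform monotone
    in the count and avoiding log of zero.
    """
    if pseudo_count <= 0:
        raise ValidationError("pseudo_count must be > 0")
    libsizes = counts.counts.sum(axis=0).astype(float)
    if (libsizes <= 0).any():
        bad = list(libsizes.index[libsizes <= 0])
        raise ValidationError(f"samples with zero library size: {bad}")
    x = counts.counts.to_numpy(dtype=float)
    values = np.log2((x + pseudo_count) / (libsizes.to_numpy() + 2 * pseudo_count) * 1e6)
    return LogExpressionMatrix(
        values=pd.DataFrame(values, index=counts.gene_ids, columns=counts.sample_ids),
        library_sizes=libsizes,
        pseudo_count=pseudo_count,
    )


def _trigamma_inverse(x: float) -> float:
    # Newton iteration for trigamma(y) = x; monotone decreasing target.
    if x <= 0:
        raise ValueError("trigamma inverse requires x > 0")
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = float(polygamma(1, y))
        step = tri * (1.0 - tri / x) / float(polygamma(2, y))
        y += step
        if abs(step) < 1e-10 * y:
            break
    return y


def estimate_variance_prior(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Moment-match a scaled inverse-chi-square prior to sample variances.

    Works on ``log(s2)``: under the prior, ``log(s2) - digamma(df/2) +
    log(df/2)`` has mean ``log(s0^2) - log(d0/2) + digamma(d0/2)`` and
    excess variance ``trigamma(d0/2)`` beyond ``trigamma(df/2)``. Returns
    ``(d0, s0^2)``; an excess variance of zero or less yields
    ``d0 = inf`` (all genes share one variance).

    Zero sample variances are excluded from estimation.
    """
    s2 = np.asarray(s2, dtype=float)
    positive = s2[s2 > 0]
    if positive.size < 2:
        raise ValidationError("need >= 2 positive sample variances to estimate the prior")
    e = np.log(positive) - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    excess = evar - float(polygamma(1, df / 2.0))
    if excess > 0:
        d0 = 2.0 * _trigamma_inverse(excess)
        s02 = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s02 = float(np.exp(emean))
    return d0, s02


def moderated_two_group_test(
    logexpr: LogExpressionMatrix,
    design: pd.Series,
    group_a: str,
    group_b: str,
    params: ModeratedTestParams | None = None,
) -> pd.DataFrame:
    """Moderated t-test of ``group_b`` minus ``group_a`` on log-CPM.

    Per gene: ``log2fc = mean_b - mean_a``; pooled residual variance
    ``s2`` on ``d_g = n_a + n_b - 2`` df; moderated variance
    ``(d0 s0^2 + d_g s2) / (d0 + d_g)``; t referred to a t-distribution
    with ``d0 + d_g`` df (Gaussian in the ``d0 = inf`` limit).
    Returns a DE table with BH-adjusted p-values.
    """
    params = params or ModeratedTestParams()
    samples_a = list(design.index[design == group_a])
    samples_b = list(design.index[design == group_b])
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError(
            f"both groups need >= 2 samples (got {group_a}: {len(samples_a)}, "
            f"{group_b}: {len(samples_b)})"
        )
    xa = logexpr.values[samples_a].to_numpy()
    xb = logexpr.values[samples_b].to_numpy()
    na, nb = xa.shape[1], xb.shape[1]
    mean_a, mean_b = xa.mean(axis=1), xb.mean(axis=1)
    lfc = mean_b - mean_a
    rss = ((xa - mean_a[:, None]) ** 2).sum(axis=1) + ((xb - mean_b[:, None]) ** 2).sum(axis=1)
    dg = na + nb - 2
    s2 = rss / dg

    d0, s02 = params.prior_df, params.prior_var
    if d0 is None or s02 is None:
        d0_hat, s02_hat = estimate_variance_prior(s2, dg)
        d0 = d0_hat if d0 is None else d0
        s02 = s02_hat if s02 is None else s02

    if np.isinf(d0):
        s2_mod = np.full_like(s2, s02)
    else:
        s2_mod = (d0 * s02 + dg * s2) / (d0 + dg)

    se = np.sqrt(s2_mod * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        tstat = np.where(se > 0, lfc / np.where(se > 0, se, 1.0), np.inf * np.sign(lfc))
    tstat = np.where((se == 0) & (lfc == 0), 0.0, tstat)
    if np.isinf(d0):
        p = 2.0 * norm.sf(np.abs(tstat))
    else:
        p = 2.0 * t_dist.sf(np.abs(tstat), d0 + dg)
    # zero moderated variance (only possible with d0 = 0 and s2 = 0):
    # flag with the smallest representable p rather than dividing by zero
    tiny = np.nextafter(0.0, 1.0)
    p = np.clip(p, tiny, 1.0)

    de = pd.DataFrame(
        {
            "gene_id": logexpr.values.index,
            "log2fc": lfc,
            "p": p,
            "fdr": bh_adjust(p),
            "ave_expr": logexpr.values[samples_a + samples_b].to_numpy().mean(axis=1),
            "t": tstat,
        }
    ).reset_index(drop=True)
    de.attrs["prior_df"] = d0
    de.attrs["prior_var"] = s02
    de.attrs["contrast"] = f"{group_b}-vs-{group_a}"
    return de


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} m p_(j) / j`` capped at 1, returned in the
    input order. Raises on p-values outside (0, 1].
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValidationError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    scaled = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(scaled[::-1])[::-1]
    q = np.empty(m, dtype=float)
    q[order] = np.minimum(q_sorted, 1.0)
    return q
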