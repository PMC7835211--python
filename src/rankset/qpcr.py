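"""qPCR quantification arithmetic.

Two standard closed forms: comparative 2^-ddCt relative expression
against a reference gene and a calibrator group, and ChIP-qPCR recovery
expressed as percent of (dilution-adjusted) input. Amplification
efficiency is fixed at 2.0 per cycle, the comparative-Ct assumption;
efficiency-corrected variants are out of scope.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import f_oneway

from .datatypes import ValidationError

__all__ = ["validate_ct_table", "relative_quantification", "percent_input", "group_anova"]

CT_COLUMNS = ("sample_id", "group", "target", "ct")


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Check a Ct table: required columns, positive finite Ct values."""
    for col in CT_COLUMNS:
        if col not in ct.columns:
            raise ValidationError(f"Ct table missing required column {col!r}")
    values = ct["ct"].to_numpy(dtype=float)
    if not np.isfinite(values).all() or (values <= 0).any():
        raise ValidationError("Ct values must be positive and finite")
    if ct.duplicated(["sample_id", "target"]).any():
        raise ValidationError("duplicate (sample, target) measurements; average replicates first")
    return ct


def relative_quantification(
    ct: pd.DataFrame, reference_target: str, calibrator_group: str
) -> pd.DataFrame:
    """Comparative 2^-ddCt relative quantification.

    Per sample and target: ``dCt = Ct_target - Ct_reference``;
    ``ddCt = dCt - mean(dCt over the calibrator group)``;
    ``rq = 2 ** -ddCt``. The calibrator group is therefore centered at a
    geometric-mean RQ of exactly 1. RQ is unchanged by adding any
    constant to all Ct values of a sample (both target and reference).

    Raises when the reference target is missing for any sample that has a
    target measurement, or when the calibrator group is empty.
    """
    validate_ct_table(ct)
    ref = ct[ct["target"] == reference_target].set_index("sample_id")["ct"]
    targets = ct[ct["target"] != reference_target]
    if targets.empty:
        raise ValidationError("no non-reference target measurements")
    missing = sorted(set(targets["sample_id"]) - set(ref.index))
    if missing:
        raise ValidationError(
            f"reference target {reference_target!r} not measured for samples {missing}"
        )
    out = targets.copy()
    out["delta_ct"] = out["ct"].to_numpy() - ref.loc[out["sample_id"]].to_numpy()
    calibrator = out["group"] == calibrator_group
    if not calibrator.any():
        raise ValidationError(f"calibrator group {calibrator_group!r} has no samples")
    cal_mean = out.loc[calibrator].groupby("target")["delta_ct"].mean()
    missing_cal = sorted(set(out["target"]) - set(cal_mean.index))
    if missing_cal:
        raise ValidationError(
            f"calibrator group {calibrator_group!r} lacks targets {missing_cal}"
        )
    out["delta_delta_ct"] = out["delta_ct"] - cal_mean.loc[out["target"]].to_numpy()
    out["rq"] = np.exp2(-out["delta_delta_ct"])
    return out[["sample_id", "group", "target", "ct", "delta_ct", "delta_delta_ct", "rq"]]


def percent_input(ct_ip, ct_input, input_fraction: float):
    """ChIP-qPCR recovery as percent of input.

    The input Ct is first adjusted for the dilution:
    ``ct_adj = ct_input - log2(1 / input_fraction)``; then
    ``%input = 100 * 2 ** (ct_adj - ct_ip)``. Monotone decreasing in
    ``ct_ip`` (one cycle less IP Ct doubles the recovery).
    ``input_fraction`` is a required explicit parameter in (0, 1].
    """
    if not 0.0 < input_fraction <= 1.0:
        raise ValidationError("input_fraction must lie in (0, 1]")
    ct_ip = np.asarray(ct_ip, dtype=float)
    ct_input = np.asarray(ct_input, dtype=float)
    if not (np.isfinite(ct_ip).all() and np.isfinite(ct_input).all()):
        raise ValidationError("Ct values must be finite")
    ct_adj = ct_input - np.log2(1.0 / input_fraction)
    result = 100.0 * np.exp2(ct_adj - ct_ip)
    return result.item() if result.ndim == 0 else result


def group_anova(values: pd.DataFrame, value_col: str = "rq") -> tuple[float, float]:
    """One-way ANOVA across groups (convenience wrapper, not core output)."""
    groups = [g[value_col].to_numpy(dtype=float) for _, g in values.groupby("group")]
    if len(groups) < 2:
        raise ValidationError("need >= 2 groups for ANOVA")
    stat, p = f_oneway(*groups)
    return float(stat), float(p)
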