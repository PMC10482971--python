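"""Small statistics for qRT-PCR validation experiments.

Relative expression is quantified with the comparative-Ct method: for each
sample dCt = Ct_target - Ct_reference, ddCt = dCt - dCt_calibrator, and
relative expression = 2**(-ddCt).  The reference may be a housekeeping
gene or an exogenous spike-in probe; samples where the reference failed to
amplify are dropped, never imputed.  Dispersion of expression between two
recovery strategies is compared with the variance-ratio F-test.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, SchemaError

__all__ = ["ddct_relative_expression", "variance_f_test"]

logger = logging.getLogger(__name__)


def ddct_relative_expression(
    ct_table: pd.DataFrame,
    calibrator_sample: str | None = None,
    calibrator_group: str | None = None,
) -> pd.DataFrame:
    """Per-sample relative expression by the comparative-Ct (ddCt) method.

    Parameters
    ----------
    ct_table : DataFrame
        Columns ``sample``, ``ct_target``, ``ct_ref`` and, when calibrating
        against a group, ``group``.  Rows with a missing/undetected
        reference Ct (NaN) are omitted and counted in the log.
    calibrator_sample : str, optional
        Sample whose dCt serves as the ddCt baseline.
    calibrator_group : str, optional
        Alternatively, calibrate against the mean dCt of this group.

    Returns
    -------
    DataFrame
        Columns ``sample``, ``dct``, ``ddct``, ``rel_expr`` over retained
        samples.
    """
    required = {"sample", "ct_target", "ct_ref"}
    missing = required - set(ct_table.columns)
    if missing:
        raise SchemaError(f"ct table missing columns {sorted(missing)}")
    if (calibrator_sample is None) == (calibrator_group is None):
        raise ConfigError("give exactly one of calibrator_sample / calibrator_group")

    df = ct_table.copy()
    bad_ref = df["ct_ref"].isna() | ~np.isfinite(df["ct_ref"])
    n_dropped = int(bad_ref.sum())
    if n_dropped:
        logger.info("omitting %d samples with undetected reference", n_dropped)
    df = df.loc[~bad_ref].copy()
    if df.empty:
        raise SchemaError("no samples with a detected reference")
    if (df["ct_target"] <= 0).any() or (df["ct_ref"] <= 0).any():
        raise SchemaError("Ct values must be positive")

    df["dct"] = df["ct_target"] - df["ct_ref"]
    if calibrator_sample is not None:
        cal = df.loc[df["sample"] == calibrator_sample, "dct"]
        if cal.empty:
            raise ConfigError(f"calibrator sample {calibrator_sample!r} not found")
        baseline = float(cal.iloc[0])
    else:
        if "group" not in df.columns:
            raise ConfigError("calibrator_group given but no 'group' column")
        cal = df.loc[df["group"] == calibrator_group, "dct"]
        if cal.empty:
            raise ConfigError(f"calibrator group {calibrator_group!r} not found")
        baseline = float(cal.mean())

    df["ddct"] = df["dct"] - baseline
    df["rel_expr"] = 2.0 ** (-df["ddct"])
    out_cols = ["sample", "dct", "ddct", "rel_expr"]
    df.attrs["n_omitted"] = n_dropped
    return df[out_cols].reset_index(drop=True)


def variance_f_test(values_a, values_b) -> tuple[float, float]:
    """Variance-ratio F-test between two samples.

    F = s_a^2 / s_b^2 with (n_a - 1, n_b - 1) degrees of freedom; the
    two-sided p doubles the smaller tail (capped at 1), so it is invariant
    under exchanging the groups.  A zero denominator variance with a
    non-zero numerator is reported as (inf, 0.0).
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise SchemaError("each group needs >= 2 values")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise SchemaError("non-finite values")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if vb == 0:
        if va == 0:
            return 1.0, 1.0
        return float("inf"), 0.0
    F = va / vb
    dist = stats.f(a.size - 1, b.size - 1)
    p = 2.0 * min(dist.cdf(F), dist.sf(F))
    return float(F), float(min(p, 1.0))
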