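"""Relative qPCR quantification by the 2^-ddCt method.

For each sample, technical replicates are averaged on the Ct (cycle)
scale, dCt = mean Ct(target) - mean Ct(reference gene, e.g. GAPDH) removes
input-amount variation, ddCt = dCt - mean dCt of the calibrator group
(e.g. the STH control) re-expresses everything relative to the control,
and fold = 2^-ddCt. Because ddCt is centered on the calibrator's
arithmetic mean dCt, the calibrator group's geometric-mean fold change is
exactly 1. Group means are compared with a two-sided Welch t-test with the
conventional significance bands (* p < 0.05, ** p < 0.01).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["validate_ct_table", "ddct", "group_compare"]

REQUIRED_COLUMNS = ("sample", "group", "gene", "ct")


def validate_ct_table(ct: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format Ct table: required columns, positive Ct."""
    missing = [c for c in REQUIRED_COLUMNS if c not in ct.columns]
    if missing:
        raise ValueError(f"Ct table missing columns: {missing}")
    if (ct["ct"] <= 0).any():
        raise ValueError("Ct values must be positive")
    return ct


def ddct(
    ct: pd.DataFrame,
    target: str,
    reference: str,
    calibrator_group: str,
) -> pd.DataFrame:
    """Per-sample 2^-ddCt fold changes for one target gene.

    A sample lacking a reference-gene Ct cannot be normalized and is
    excluded with a warning. Returns columns sample, group, dct, ddct, fold.
    """
    validate_ct_table(ct)
    if target == reference:
        raise ValueError("target and reference gene must differ")
    mean_ct = (
        ct[ct["gene"].isin([target, reference])]
        .groupby(["sample", "group", "gene"], sort=False)["ct"]
        .mean()
        .unstack("gene")
        .reset_index()
    )
    if target not in mean_ct.columns:
        raise ValueError(f"no Ct measurements for target {target!r}")
    no_ref = mean_ct[reference].isna() if reference in mean_ct.columns else pd.Series(True, index=mean_ct.index)
    if no_ref.any():
        dropped = mean_ct.loc[no_ref, "sample"].tolist()
        warnings.warn(f"excluding samples without reference Ct: {dropped}", stacklevel=2)
        mean_ct = mean_ct.loc[~no_ref]
    mean_ct = mean_ct.dropna(subset=[target])
    mean_ct["dct"] = mean_ct[target] - mean_ct[reference]

    cal = mean_ct.loc[mean_ct["group"] == calibrator_group, "dct"]
    if cal.empty:
        raise ValueError(f"calibrator group {calibrator_group!r} has no usable samples")
    mean_ct["ddct"] = mean_ct["dct"] - cal.mean()
    mean_ct["fold"] = 2.0 ** (-mean_ct["ddct"])
    return mean_ct[["sample", "group", "dct", "ddct", "fold"]].reset_index(drop=True)


def group_compare(
    folds: pd.DataFrame,
    value: str = "fold",
    group: str = "group",
) -> pd.DataFrame:
    """Mean +/- SD per group and a two-sided Welch t-test between the two
    groups. The significance flag follows the usual bands: '**' for
    p < 0.01, '*' for p < 0.05, 'ns' otherwise."""
    labels = sorted(folds[group].unique())
    if len(labels) != 2:
        raise ValueError(f"exactly two groups required, found {labels}")
    a = folds.loc[folds[group] == labels[0], value].to_numpy(float)
    b = folds.loc[folds[group] == labels[1], value].to_numpy(float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least two values")
    p = float(stats.ttest_ind(a, b, equal_var=False).pvalue)
    flag = "**" if p < 0.01 else "*" if p < 0.05 else "ns"
    return pd.DataFrame(
        {
            "group": labels,
            "n": [len(a), len(b)],
            "mean": [a.mean(), b.mean()],
            "sd": [a.std(ddof=1), b.std(ddof=1)],
            "p": [p, p],
            "significance": [flag, flag],
        }
    )
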