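"""FPKM normalization, expressed-gene filtering and two-group DEG screening.

FPKM_gs = counts_gs * 1e9 / (total_s * length_g) normalizes for sequencing
depth and transcript length. A gene counts as expressed when its mean FPKM
across all samples is at least 0.1 (inclusive). Differential expression
between the two populations is screened with a Welch t-test on
log2(FPKM + 1) — the test is pluggable; the module's contract is the
screening thresholds — and Benjamini-Hochberg FDR control: a gene is a DEG
iff fdr < 0.01 and |log2FC| > 1 (both strict), with log2FC computed from
group mean FPKM with a pseudocount of 1 and signed relative to the control
group (the purebred STH population in the motivating study).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Literal

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "fpkm",
    "expressed_filter",
    "bh_adjust",
    "de_screen",
]


@dataclass
class ExpressionMatrix:
    """Genes x samples abundance table with group labels and a unit tag.

    ``values``: DataFrame indexed by unique gene ids, one column per sample.
    ``groups``: sample -> group label (two groups for testing).
    ``lengths``: gene -> transcript length in bp (required for FPKM).
    ``units``: 'counts' or 'fpkm'.
    """

    values: pd.DataFrame
    groups: pd.Series
    lengths: pd.Series | None = None
    units: Literal["counts", "fpkm"] = "counts"

    def __post_init__(self) -> None:
        if not self.values.index.is_unique:
            raise ValueError("gene ids must be unique")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("abundance values must be non-negative")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    def group_samples(self, label: str) -> list[str]:
        return [s for s in self.samples if self.groups[s] == label]

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        path: str | Path,
        groups: pd.Series | dict,
        lengths: pd.Series | None = None,
        units: Literal["counts", "fpkm"] = "counts",
    ) -> "ExpressionMatrix":
        values = pd.read_csv(path, sep="\t", index_col=0)
        return cls(values=values, groups=pd.Series(groups), lengths=lengths, units=units)


def fpkm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Convert a count matrix to FPKM.

    Requires gene lengths and positive per-sample totals; a zero-length
    gene is rejected by id.
    """
    if m.units != "counts":
        raise ValueError("fpkm() expects a count matrix")
    if m.lengths is None:
        raise ValueError("gene lengths required for FPKM conversion")
    lengths = m.lengths.reindex(m.genes)
    if lengths.isna().any():
        raise ValueError(f"genes without lengths: {list(lengths.index[lengths.isna()])[:5]}")
    zero_len = lengths.index[lengths <= 0]
    if len(zero_len):
        raise ValueError(f"non-positive gene length for: {list(zero_len)[:5]}")
    totals = m.values.sum(axis=0)
    if (totals <= 0).any():
        raise ValueError(f"samples with zero total counts: {list(totals.index[totals <= 0])}")
    vals = m.values * 1e9
    vals = vals.div(totals, axis=1).div(lengths, axis=0)
    return replace(m, values=vals, units="fpkm")


def expressed_filter(m: ExpressionMatrix, min_fpkm: float = 0.1) -> ExpressionMatrix:
    """Keep genes whose mean FPKM across all samples is >= min_fpkm (inclusive)."""
    if m.units != "fpkm":
        raise ValueError("expressed_filter expects FPKM units")
    keep = m.values.mean(axis=1) >= min_fpkm
    return replace(m, values=m.values.loc[keep])


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order-preserving.

    NaN entries propagate as NaN and are excluded from the number of tests.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        if ((p[ok] < 0) | (p[ok] > 1)).any():
            raise ValueError("p-values must lie in [0, 1]")
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def _welch_t(case: np.ndarray, ctrl: np.ndarray) -> float:
    return stats.ttest_ind(case, ctrl, equal_var=False).pvalue


def de_screen(
    m: ExpressionMatrix,
    control_group: str,
    fdr_cut: float = 0.01,
    lfc_cut: float = 1.0,
    pseudocount: float = 1.0,
    test: Callable[[np.ndarray, np.ndarray], float] = _welch_t,
) -> pd.DataFrame:
    """Two-group DEG screen on an FPKM matrix.

    Returns a table with columns gene, log2fc, p, fdr, direction, is_deg.
    log2FC is the group-of-interest over control ratio of mean FPKM (with
    pseudocount); direction is 'up'/'down' relative to the control. A group
    with fewer than two samples cannot be tested and raises.
    """
    if m.units != "fpkm":
        raise ValueError("de_screen expects FPKM units")
    group_labels = sorted(set(m.groups[s] for s in m.samples))
    if len(group_labels) != 2:
        raise ValueError(f"exactly two groups required, found {group_labels}")
    if control_group not in group_labels:
        raise ValueError(f"control group {control_group!r} not among {group_labels}")
    case_group = next(g for g in group_labels if g != control_group)
    case_cols = m.group_samples(case_group)
    ctrl_cols = m.group_samples(control_group)
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("each group needs at least two samples for testing")

    case = m.values[case_cols].to_numpy(float)
    ctrl = m.values[ctrl_cols].to_numpy(float)
    log2fc = np.log2(case.mean(axis=1) + pseudocount) - np.log2(ctrl.mean(axis=1) + pseudocount)

    log_case = np.log2(case + 1.0)
    log_ctrl = np.log2(ctrl + 1.0)
    pvals = np.array([test(log_case[i], log_ctrl[i]) for i in range(len(m.genes))])
    # a gene flat at zero in both groups has no variance and an undefined test
    pvals = np.where(np.isnan(pvals), 1.0, pvals)
    fdr = bh_adjust(pvals)

    table = pd.DataFrame(
        {
            "gene": m.genes,
            "log2fc": log2fc,
            "p": pvals,
            "fdr": fdr,
            "direction": np.where(log2fc >= 0, "up", "down"),
            "is_deg": (fdr < fdr_cut) & (np.abs(log2fc) > lfc_cut),
        }
    ).set_index("gene", drop=False)
    table.index.name = None
    return table
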