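"""Differential-expression calling and qPCR relative quantification.

DE transcripts are called with the thresholds |log2FC| > 1 and BH-FDR <
0.05 (both strict). The per-transcript test is a two-sided Welch t-test on
log2(x + 1): a deliberately simple, documented substitute for
negative-binomial machinery (DESeq2/edgeR) — it changes the p-values but
preserves the thresholding logic everything downstream depends on. The
multiple-testing family is one expression matrix (one RNA class, one
tissue).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .simulate import SampleDesign

__all__ = [
    "log2_fold_change",
    "de_pvalues",
    "bh_adjust",
    "call_de",
    "de_table",
    "summarize_de",
    "DECounts",
    "QpcrRecord",
    "ddct_relative_expression",
]


def _group_columns(
    matrix: pd.DataFrame, design: Sequence[SampleDesign]
) -> tuple[list[str], list[str]]:
    cols = set(matrix.columns)
    nhs = [s.sample_id for s in design if s.group == "NHS" and s.sample_id in cols]
    hs = [s.sample_id for s in design if s.group == "HS" and s.sample_id in cols]
    if not nhs or not hs:
        raise ValueError("both groups (NHS, HS) must have samples in the matrix")
    return nhs, hs


def log2_fold_change(
    matrix: pd.DataFrame,
    design: Sequence[SampleDesign],
    pseudocount: float = 1.0,
) -> pd.Series:
    """Per-transcript log2((mean_HS + c) / (mean_NHS + c)), HS as numerator.

    "Up-regulated" therefore means higher under heat stress. With c = 0 and
    a zero control-group mean the ratio is undefined; such transcripts get
    NaN rather than a silent +/-inf.
    """
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    nhs, hs = _group_columns(matrix, design)
    mean_nhs = matrix[nhs].mean(axis=1) + pseudocount
    mean_hs = matrix[hs].mean(axis=1) + pseudocount
    with np.errstate(divide="ignore", invalid="ignore"):
        lfc = np.log2(mean_hs / mean_nhs)
    lfc = lfc.where(mean_nhs > 0, np.nan)
    lfc.name = "log2fc"
    return lfc


def de_pvalues(matrix: pd.DataFrame, design: Sequence[SampleDesign]) -> pd.Series:
    """Two-sided Welch t-test per transcript on log2(x + 1) values.

    Degenerate transcripts (zero variance in both groups) get p = 1 when
    the group means are equal and p = 0 otherwise — the limiting answers of
    the t-test as variance vanishes.
    """
    nhs, hs = _group_columns(matrix, design)
    if len(nhs) < 2 or len(hs) < 2:
        raise ValueError("each group needs >= 2 samples for a t-test")
    a = np.log2(matrix[hs].to_numpy(dtype=float) + 1.0)
    b = np.log2(matrix[nhs].to_numpy(dtype=float) + 1.0)
    with np.errstate(divide="ignore", invalid="ignore"), warnings.catch_warnings():
        # constant transcripts trip scipy's precision-loss warning; their
        # p-values are overwritten by the degenerate-case rules below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=False)
    p = np.asarray(res.pvalue, dtype=float)
    degenerate = (a.var(axis=1) == 0.0) & (b.var(axis=1) == 0.0)
    equal_means = np.isclose(a.mean(axis=1), b.mean(axis=1))
    p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    # One-group-constant cases where scipy still yields NaN (e.g. n too
    # small after filtering) are conservatively given p = 1.
    p = np.where(np.isnan(p), 1.0, p)
    return pd.Series(p, index=matrix.index, name="pvalue")


def bh_adjust(pvalues: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(list(pvalues), dtype=float)
    if p.size == 0:
        return p
    if np.any(p < 0) or np.any(p > 1) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(
    log2fc: Mapping[str, float] | pd.Series,
    fdr: Mapping[str, float] | pd.Series,
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
    pvalue: Mapping[str, float] | pd.Series | None = None,
) -> pd.DataFrame:
    """Apply the strict DE thresholds |log2FC| > lfc AND FDR < fdr.

    Both inequalities are strict: log2FC = 1.0 exactly or FDR = 0.05
    exactly is *not* DE. Returns a frame with columns (log2fc, pvalue, fdr,
    is_de, direction), indexed by transcript id. An undefined (NaN) log2FC
    is never DE.
    """
    lfc = pd.Series(log2fc, dtype=float)
    q = pd.Series(fdr, dtype=float)
    if set(lfc.index) != set(q.index):
        diff = set(lfc.index) ^ set(q.index)
        raise ValueError(f"transcript universes differ; symmetric difference: {sorted(diff)[:10]}")
    q = q.reindex(lfc.index)
    is_de = (lfc.abs() > lfc_thresh) & (q < fdr_thresh)
    is_de = is_de.fillna(False)
    direction = np.where(~is_de, "none", np.where(lfc > 0, "up", "down"))
    out = pd.DataFrame(
        {
            "log2fc": lfc,
            "pvalue": pd.Series(pvalue, dtype=float).reindex(lfc.index)
            if pvalue is not None
            else np.nan,
            "fdr": q,
            "is_de": is_de.astype(bool),
            "direction": direction,
        }
    )
    out.index.name = "transcript_id"
    return out


def de_table(
    matrix: pd.DataFrame,
    design: Sequence[SampleDesign],
    lfc_thresh: float = 1.0,
    fdr_thresh: float = 0.05,
    pseudocount: float = 1.0,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Full DE pipeline for one matrix: log2FC, Welch p, BH FDR, calls.

    ``use_raw_p`` substitutes the unadjusted p-value for the FDR in the
    threshold (the volcano-plot convention p < 0.05); the default is the
    FDR rule.
    """
    lfc = log2_fold_change(matrix, design, pseudocount=pseudocount)
    p = de_pvalues(matrix, design)
    q = pd.Series(bh_adjust(p.to_numpy()), index=p.index, name="fdr")
    crit = p if use_raw_p else q
    out = call_de(lfc, crit, lfc_thresh=lfc_thresh, fdr_thresh=fdr_thresh, pvalue=p)
    out["fdr"] = q  # keep the true FDR column even under the raw-p rule
    return out


class DECounts(NamedTuple):
    total_de: int
    n_up: int
    n_down: int


def summarize_de(results: pd.DataFrame) -> DECounts:
    """Counts of DE transcripts by direction (total = up + down)."""
    if len(results) == 0:
        return DECounts(0, 0, 0)
    de = results[results["is_de"]]
    n_up = int((de["direction"] == "up").sum())
    n_down = int((de["direction"] == "down").sum())
    return DECounts(n_up + n_down, n_up, n_down)


@dataclass(frozen=True)
class QpcrRecord:
    """One qPCR well pair: target and reference-gene Ct for one sample."""

    sample_id: str
    ct_target: float
    ct_reference: float
    group: str

    def __post_init__(self):
        for name in ("ct_target", "ct_reference"):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise ValueError(f"{name} must be finite and positive for {self.sample_id!r}")


def ddct_relative_expression(
    records: Sequence[QpcrRecord], calibrator_group: str = "NHS"
) -> pd.Series:
    """Relative expression by the 2^-ddCt method.

    dCt = Ct(target) - Ct(reference); ddCt = dCt - mean dCt over the
    calibrator group; returns 2**(-ddCt) per sample. The calibrator group's
    geometric mean is exactly 1 by construction.
    """
    records = list(records)
    dct = {r.sample_id: r.ct_target - r.ct_reference for r in records}
    cal = [dct[r.sample_id] for r in records if r.group == calibrator_group]
    if not cal:
        raise ValueError(f"calibrator group {calibrator_group!r} has no records")
    baseline = float(np.mean(cal))
    rel = {sid: 2.0 ** -(d - baseline) for sid, d in dct.items()}
    return pd.Series(rel, name="relative_expression")
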