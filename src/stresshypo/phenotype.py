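"""Phenotype statistics: Welch t-tests with Cohen's d, and Spearman
correlations between top-DEG expression and behaviors with Holm correction.

Conventions match the emulated study's reporting: statistics are signed as
Stressed − Control, degrees of freedom follow Welch–Satterthwaite, and
Cohen's d uses the average-variance pooled denominator
``sqrt((s1^2 + s2^2) / 2)`` (equivalent to the classical pooled SD at equal
group sizes).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GroupSummary",
    "WelchResult",
    "welch_test",
    "welch_test_raw",
    "holm_adjust",
    "spearman_holm",
    "top_degs",
]


@dataclass
class GroupSummary:
    """Summary statistics of one group for one measure."""

    label: str
    mean: float
    sd: float
    n: int

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError(f"sd must be >= 0, got {self.sd}")
        if self.n < 2:
            raise ValueError(f"n must be >= 2, got {self.n}")


@dataclass
class WelchResult:
    """Welch two-sample test with effect size."""

    t: float
    df: float
    p: float
    d: float  # Cohen's d, average-variance pooled denominator

    def summary(self) -> str:
        return (
            f"t({self.df:.2f}) = {self.t:.2f}, p = {self.p:.3g}, d = {self.d:.2f}"
        )


def welch_test(g1: GroupSummary, g2: GroupSummary) -> WelchResult:
    """Welch's t-test of group 2 minus group 1 from summary statistics.

    t = (m2 − m1) / sqrt(s1²/n1 + s2²/n2); df by Welch–Satterthwaite;
    d = (m2 − m1) / sqrt((s1² + s2²)/2).
    """
    v1, v2 = g1.sd**2 / g1.n, g2.sd**2 / g2.n
    diff = g2.mean - g1.mean
    denom_d = np.sqrt((g1.sd**2 + g2.sd**2) / 2.0)
    if v1 + v2 == 0:
        t = 0.0 if diff == 0 else np.inf * np.sign(diff)
        df = float(g1.n + g2.n - 2)
        p = 1.0 if diff == 0 else 0.0
        d = 0.0 if diff == 0 else np.inf * np.sign(diff)
        return WelchResult(t, df, p, d)
    t = diff / np.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    d = diff / denom_d if denom_d > 0 else np.inf * np.sign(diff)
    return WelchResult(float(t), float(df), float(p), float(d))


def welch_test_raw(x: Sequence[float], y: Sequence[float]) -> WelchResult:
    """Welch's t-test of y minus x from raw vectors (reduces to summaries)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs at least 2 observations")
    return welch_test(
        GroupSummary("x", float(x.mean()), float(x.std(ddof=1)), len(x)),
        GroupSummary("y", float(y.mean()), float(y.std(ddof=1)), len(y)),
    )


def holm_adjust(p_raw: Sequence[float], m: int | None = None) -> np.ndarray:
    """Holm step-down adjustment with explicit family size.

    p_holm(i) = max over j <= i (in ascending raw-p order) of
    min(1, (m − j + 1) · p_(j)). ``m`` defaults to the number of supplied
    p-values but may be larger when the computed tests are part of a wider
    family.
    """
    p = np.asarray(p_raw, dtype=float)
    if m is None:
        m = len(p)
    if m < len(p):
        raise ValueError("family size m cannot be smaller than the number of tests")
    order = np.argsort(p, kind="stable")
    adj_sorted = np.minimum((m - np.arange(len(p))) * p[order], 1.0)
    adj_sorted = np.maximum.accumulate(adj_sorted)
    out = np.empty_like(p)
    out[order] = adj_sorted
    return out


def spearman_holm(
    expr: pd.DataFrame,
    behaviors: pd.DataFrame,
    family_size: int | None = None,
) -> pd.DataFrame:
    """Spearman correlation of each gene (rows of ``expr``) with each
    behavior (columns of ``behaviors``), Holm-corrected.

    Samples are matched on ``behaviors.index`` ∩ ``expr.columns``; pairs with
    a constant vector get missing r/p and do not consume a Holm slot.
    ``family_size`` overrides the Holm family m (default: number of valid
    tests), e.g. when the screened gene list spans several regions.
    """
    common = [s for s in behaviors.index if s in expr.columns]
    if len(common) < 3:
        raise ValueError("need at least 3 paired observations")
    rows = []
    for gene in expr.index:
        gvals = expr.loc[gene, common].to_numpy(float)
        for beh in behaviors.columns:
            bvals = behaviors.loc[common, beh].to_numpy(float)
            mask = np.isfinite(gvals) & np.isfinite(bvals)
            if mask.sum() < 3 or np.ptp(gvals[mask]) == 0 or np.ptp(bvals[mask]) == 0:
                rows.append({"gene": gene, "behavior": beh, "r": np.nan, "p_raw": np.nan,
                             "n": int(mask.sum())})
                continue
            r, p = stats.spearmanr(gvals[mask], bvals[mask])
            rows.append({"gene": gene, "behavior": beh, "r": float(r),
                         "p_raw": float(p), "n": int(mask.sum())})
    table = pd.DataFrame(rows)
    valid = table["p_raw"].notna()
    table["p_holm"] = np.nan
    if valid.any():
        table.loc[valid, "p_holm"] = holm_adjust(
            table.loc[valid, "p_raw"].to_numpy(), m=family_size
        )
    return table


def top_degs(de_table: pd.DataFrame, k_each: int = 5,
             efdr_threshold: float = 0.05) -> tuple[list[str], bool]:
    """The k largest-positive and k most-negative log2FC genes among
    significant calls (eFDR < threshold).

    Ties break by smaller eFDR then gene id. Returns (genes, short) where
    ``short`` flags that a side had fewer than ``k_each`` significant genes.
    """
    sig = de_table[de_table["eFDR"] < efdr_threshold].copy()
    sig["_gene"] = sig.index.astype(str)
    up = sig[sig["log2FC"] > 0].sort_values(
        ["log2FC", "eFDR", "_gene"], ascending=[False, True, True], kind="stable"
    )
    down = sig[sig["log2FC"] < 0].sort_values(
        ["log2FC", "eFDR", "_gene"], ascending=[True, True, True], kind="stable"
    )
    chosen = list(up.index[:k_each]) + list(down.index[:k_each])
    short = len(up) < k_each or len(down) < k_each
    return [str(g) for g in chosen], short
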