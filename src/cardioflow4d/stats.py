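"""Paired method-agreement statistics.

Implements the comparison layer used to contrast two acquisition
conditions measuring the same quantity on the same subjects: the Wilcoxon
signed-rank test (exact small-sample p by convolution over the rank-sum
distribution, normal approximation with tie correction for larger n),
Pearson correlation with ordinary least squares regression, and
Bland-Altman agreement (bias, SD of differences, 1.96*SD limits of
agreement) with a percentage-difference companion.

Difference direction is first-named condition minus second throughout.
The percentage difference uses the pairwise mean (x+y)/2 as denominator by
default; the second condition alone can be selected instead.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PairedMeasurements",
    "WilcoxonResult",
    "BlandAltman",
    "Correlation",
    "AgreementReport",
    "wilcoxon_paired",
    "bland_altman",
    "correlate",
    "agreement_report",
    "comparison_table",
]


@dataclass
class PairedMeasurements:
    """The same metric measured under two conditions on the same subjects."""

    labels: Sequence[str]
    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        if not (len(self.labels) == len(self.x) == len(self.y)):
            raise ValueError("labels, x and y must have equal lengths")
        if len(self.x) < 3:
            raise ValueError("need at least 3 pairs")
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("missing values must be excluded explicitly")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class WilcoxonResult:
    statistic: float  # W+ (sum of ranks of positive differences)
    p_value: float  # two-tailed
    n_used: int  # pairs after dropping zero differences
    exact: bool
    note: str = ""


def _signed_rank_distribution(ranks: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Exact distribution of W+ over all 2^n equiprobable sign assignments.

    Average ranks for tied |d| may be half-integers, so the convolution
    runs on doubled ranks.  Returns (support of 2*W+, probabilities).
    """
    doubled = np.round(2.0 * ranks).astype(np.int64)
    total = int(doubled.sum())
    probs = np.zeros(total + 1)
    probs[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(probs)
        shifted[r:] = probs[: len(probs) - r]
        probs = 0.5 * (probs + shifted)
    return np.arange(total + 1), probs


def wilcoxon_paired(pm: PairedMeasurements, exact_max_n: int = 25) -> WilcoxonResult:
    """Two-tailed Wilcoxon signed-rank test of x vs y.

    Zero differences are dropped (Wilcoxon's original rule); if every
    difference is zero the test is degenerate and p = 1 is returned with a
    note.  The exact two-tailed p for n <= ``exact_max_n`` is
    ``2 * min(P(W+ <= w), P(W+ >= w))`` capped at 1, matching direct
    enumeration of sign assignments; larger samples use the normal
    approximation with tie-corrected variance.
    """
    d = pm.x - pm.y
    nonzero = d != 0.0
    if not nonzero.any():
        return WilcoxonResult(0.0, 1.0, 0, True, "all differences zero")
    d = d[nonzero]
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())

    if n <= exact_max_n:
        support2, probs = _signed_rank_distribution(ranks)
        w2 = int(round(2.0 * w_pos))
        p_le = probs[support2 <= w2].sum()
        p_ge = probs[support2 >= w2].sum()
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return WilcoxonResult(w_pos, float(p), n, True)

    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = (counts**3 - counts).sum() / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    z = (w_pos - mean) / np.sqrt(var)
    p = 2.0 * sps.norm.sf(abs(z))
    return WilcoxonResult(w_pos, float(min(1.0, p)), n, False)


@dataclass
class BlandAltman:
    bias: float  # mean of x - y
    sd: float  # sample SD (n-1) of the differences
    loa: tuple[float, float]  # bias -/+ 1.96 SD
    pct_bias: float  # mean percentage difference
    pct_sd: float
    n_pct: int  # pairs used for the percentage (x + y = 0 excluded)


def bland_altman(
    pm: PairedMeasurements,
    pct_denominator: Literal["mean", "second"] = "mean",
) -> BlandAltman:
    """Bland-Altman agreement of x vs y (differences d = x - y)."""
    d = pm.x - pm.y
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    if pct_denominator == "mean":
        denom = (pm.x + pm.y) / 2.0
    elif pct_denominator == "second":
        denom = pm.y.copy()
    else:
        raise ValueError(f"unknown pct_denominator {pct_denominator!r}")
    ok = denom != 0.0
    if not ok.all():
        warnings.warn(
            f"{(~ok).sum()} pair(s) with zero denominator excluded from the "
            "percentage difference", stacklevel=2,
        )
    pct = 100.0 * d[ok] / denom[ok]
    return BlandAltman(
        bias=bias,
        sd=sd,
        loa=(bias - 1.96 * sd, bias + 1.96 * sd),
        pct_bias=float(pct.mean()) if ok.any() else float("nan"),
        pct_sd=float(pct.std(ddof=1)) if ok.sum() > 1 else float("nan"),
        n_pct=int(ok.sum()),
    )


@dataclass
class Correlation:
    r: float
    r2: float
    slope: float
    intercept: float
    p_value: float  # two-tailed, t distribution with n-2 df


def correlate(pm: PairedMeasurements) -> Correlation:
    """Pearson correlation and OLS regression of y on x."""
    if np.var(pm.x) == 0.0:
        raise ValueError("x has zero variance; correlation undefined")
    res = sps.linregress(pm.x, pm.y)
    return Correlation(
        r=float(res.rvalue),
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        p_value=float(res.pvalue),
    )


@dataclass
class AgreementReport:
    """Full paired comparison of one metric under two conditions."""

    bias: float
    sd: float
    loa: tuple[float, float]
    pct_bias: float
    pct_sd: float
    r: float
    r2: float
    slope: float
    intercept: float
    wilcoxon_p: float


def agreement_report(
    pm: PairedMeasurements,
    pct_denominator: Literal["mean", "second"] = "mean",
) -> AgreementReport:
    ba = bland_altman(pm, pct_denominator)
    corr = correlate(pm)
    wil = wilcoxon_paired(pm)
    return AgreementReport(
        bias=ba.bias, sd=ba.sd, loa=ba.loa,
        pct_bias=ba.pct_bias, pct_sd=ba.pct_sd,
        r=corr.r, r2=corr.r2, slope=corr.slope, intercept=corr.intercept,
        wilcoxon_p=wil.p_value,
    )


def comparison_table(
    comparisons: Sequence[tuple[str, PairedMeasurements]],
    pct_denominator: Literal["mean", "second"] = "mean",
) -> pd.DataFrame:
    """Bias table with absolute and percentage columns, one row per comparison."""
    rows = []
    for name, pm in comparisons:
        ba = bland_altman(pm, pct_denominator)
        rows.append(
            {
                "comparison": name,
                "absolute": f"{ba.bias:.1f} ± {ba.sd:.1f}",
                "percentage": f"{ba.pct_bias:.0f} ± {ba.pct_sd:.0f} %",
                "bias": ba.bias,
                "sd": ba.sd,
                "pct_bias": ba.pct_bias,
                "pct_sd": ba.pct_sd,
            }
        )
    return pd.DataFrame(rows)
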