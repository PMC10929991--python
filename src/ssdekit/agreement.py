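"""Method-agreement statistics: regression, Pearson r, %difference, Bland-Altman.

Used to compare per-slice SSDE series produced by different measurement
routes (e.g. corrected-effective-diameter vs water-equivalent-diameter, or
automated vs reference segmentation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["AgreementReport", "percent_difference", "agreement_analysis"]


@dataclass(frozen=True)
class AgreementReport:
    """Linear-regression, correlation and Bland-Altman summary of two series."""

    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    mean_pct_diff: float  # %
    largest_pct_diff: float  # %, largest magnitude, sign preserved
    bias: float  # mean(a - b)
    loa_low: float  # bias - 1.96 * SD(a - b)
    loa_high: float  # bias + 1.96 * SD(a - b)

    def to_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in (
            "slope", "intercept", "r_squared", "pearson_r", "mean_pct_diff",
            "largest_pct_diff", "bias", "loa_low", "loa_high")}


def percent_difference(a, b) -> tuple[np.ndarray, float, float]:
    """Per-pair percentage difference of ``a`` relative to reference ``b``.

    Returns (per-pair %, signed mean %, largest-magnitude % with its sign),
    where each per-pair value is (a_i - b_i) / b_i x 100.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 1:
        raise ValueError("series must have equal, nonzero length")
    if np.any(b == 0):
        raise ValueError("reference series contains zero")
    pct = (a - b) / b * 100.0
    largest = pct[np.argmax(np.abs(pct))]
    return pct, float(pct.mean()), float(largest)


def agreement_analysis(a, b) -> AgreementReport:
    """Full agreement summary of series ``a`` against reference ``b``.

    Ordinary least squares of a on b (slope, intercept, R^2), Pearson r,
    signed percentage differences, and Bland-Altman bias with 1.96-SD
    limits of agreement (sample SD, n-1 denominator).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need at least 3 paired values")
    if np.ptp(b) == 0:
        raise ValueError("reference series has zero variance")
    reg = stats.linregress(b, a)
    r = float(stats.pearsonr(a, b).statistic)
    _, mean_pct, largest_pct = percent_difference(a, b)
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return AgreementReport(
        slope=float(reg.slope),
        intercept=float(reg.intercept),
        r_squared=float(reg.rvalue**2),
        pearson_r=r,
        mean_pct_diff=mean_pct,
        largest_pct_diff=largest_pct,
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )
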