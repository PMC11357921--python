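"""Per-lesion ROI statistics and two-reader agreement.

Mean parameter values are extracted from ROI masks drawn on the
parameter maps (NaN/failed voxels excluded, emulating the exclusion of
necrotic or cystic areas from manually drawn ROIs), the two readers'
values are averaged, and interobserver agreement is quantified with the
two-way random-effects, absolute-agreement, single-measure intraclass
correlation coefficient, ICC(2,1) - the standard form for two readers
each measuring every lesion once.  Agreement is banded on the
conventional 0.20-wide scale: <0.20 poor, 0.21-0.40 fair, 0.41-0.60
moderate, 0.61-0.80 good, 0.81-1.00 perfect.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ROIMean",
    "AgreementResult",
    "roi_mean",
    "average_readers",
    "interobserver_icc",
    "icc_band",
]


@dataclass(frozen=True)
class ROIMean:
    """Mean over usable ROI voxels and the count that contributed."""

    value: float
    n_used: int

    @property
    def empty(self) -> bool:
        return self.n_used == 0


@dataclass(frozen=True)
class AgreementResult:
    """ICC point estimate with 95% CI and the categorical band."""

    icc: float
    ci_low: float
    ci_high: float
    band: str
    degenerate: bool = False


def roi_mean(parameter_map, mask) -> ROIMean:
    """Arithmetic mean of a parameter map over a voxel mask.

    NaN voxels (failed fits, unusable ADC voxels) and negative ADC
    artifacts are excluded; the number of voxels actually used is
    reported.  An all-unusable ROI yields a flagged empty result instead
    of raising, mirroring how an unusable lesion is dropped from the
    cohort table rather than aborting the study.
    """
    parameter_map = np.asarray(parameter_map, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != parameter_map.shape:
        raise ValueError("mask shape must match the map shape")
    if not mask.any():
        raise ValueError("ROI mask contains no voxels")
    values = parameter_map[mask]
    usable = np.isfinite(values)
    if not usable.any():
        return ROIMean(value=np.nan, n_used=0)
    return ROIMean(value=float(values[usable].mean()), n_used=int(usable.sum()))


def average_readers(r1: float, r2: float) -> float:
    """Two-reader average (r1 + r2) / 2; non-finite input propagates NaN."""
    if not (np.isfinite(r1) and np.isfinite(r2)):
        return np.nan
    return 0.5 * (float(r1) + float(r2))


def icc_band(icc: float) -> str:
    """Categorical agreement band on the 0.20-wide scale."""
    if not np.isfinite(icc):
        return "undefined"
    if icc < 0.20:
        return "poor"
    if icc <= 0.40:
        return "fair"
    if icc <= 0.60:
        return "moderate"
    if icc <= 0.80:
        return "good"
    return "perfect"


def interobserver_icc(reader1, reader2) -> AgreementResult:
    """ICC(2,1) between two readers' per-lesion values, with 95% CI.

    Two-way random effects, absolute agreement, single measure, computed
    via pingouin; lesions with a non-finite value from either reader are
    dropped pairwise.  A degenerate input (no between-lesion variance)
    returns a flagged result rather than raising.
    """
    r1 = np.asarray(reader1, dtype=float)
    r2 = np.asarray(reader2, dtype=float)
    if r1.shape != r2.shape or r1.ndim != 1:
        raise ValueError("reader vectors must be 1-D and equal length")
    keep = np.isfinite(r1) & np.isfinite(r2)
    r1, r2 = r1[keep], r2[keep]
    n = len(r1)
    if n < 5:
        raise ValueError(f"need >= 5 paired lesions, got {n}")
    if np.ptp(np.concatenate([r1, r2])) == 0:
        return AgreementResult(np.nan, np.nan, np.nan, "undefined", degenerate=True)

    # two-way ANOVA mean squares without replication (k = 2 raters)
    k = 2
    x = np.column_stack([r1, r2])
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    if denom <= 0:
        return AgreementResult(np.nan, np.nan, np.nan, "undefined", degenerate=True)
    icc = (msr - mse) / denom

    # McGraw & Wong F-based 95% interval for ICC(A,1)
    from scipy.stats import f as f_dist

    if np.isclose(icc, 1.0):
        ci_low, ci_high = icc, 1.0
    else:
        a = (k * icc) / (n * (1.0 - icc))
        b = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc))
        v = (a * msc + b * mse) ** 2 / (
            (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_low = f_dist.ppf(0.975, n - 1, v)
        f_up = f_dist.ppf(0.975, v, n - 1)
        ci_low = (
            n * (msr - f_low * mse)
            / (f_low * (k * msc + (k * n - k - n) * mse) + n * msr)
        )
        ci_high = (
            n * (f_up * msr - mse)
            / (k * msc + (k * n - k - n) * mse + n * f_up * msr)
        )
    if not np.isfinite(icc):
        return AgreementResult(np.nan, np.nan, np.nan, "undefined", degenerate=True)
    return AgreementResult(
        icc=float(icc),
        ci_low=float(min(ci_low, icc)),
        ci_high=float(min(max(ci_high, icc), 1.0)),
        band=icc_band(float(icc)),
    )
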