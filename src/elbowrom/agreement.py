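"""Method-comparison and reliability statistics.

Implements the validation toolkit for comparing a new angle-measurement
method against a reference: Pearson correlation with the exact t-based
two-sided p-value, Bland–Altman 95% limits of agreement (mean difference
± 1.96 SD, sample SD), and intraclass correlation coefficients from the
one-way and two-way random-effects ANOVA decompositions (Shrout–Fleiss
conventions, McGraw–Wong F-based confidence intervals).

Differences are always taken as *method minus reference*, so a positive
mean difference means the new method reads high.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .rigid import ValidationError

__all__ = [
    "CorrelationResult",
    "BlandAltmanResult",
    "ICCResult",
    "pearson",
    "bland_altman",
    "limits_from_summary",
    "icc",
    "strength_category",
    "LOA_MULTIPLIER",
]

#: limits of agreement use the conventional normal-quantile multiplier
LOA_MULTIPLIER = 1.96

_STRENGTH_LABELS = ("slight", "fair", "moderate", "substantial", "almost perfect")
_STRENGTH_EDGES = (0.20, 0.40, 0.60, 0.80)


def strength_category(r: float) -> str:
    """Correlation-strength label for |r|.

    Bands: 0.00–0.20 slight, 0.21–0.40 fair, 0.41–0.60 moderate,
    0.61–0.80 substantial, 0.81–1.00 almost perfect; band edges belong to
    the lower band.
    """
    a = abs(float(r))
    if a > 1.0 + 1e-12:
        raise ValidationError(f"|r| = {a:.6g} exceeds 1")
    a = min(a, 1.0)
    return _STRENGTH_LABELS[sum(a > e for e in _STRENGTH_EDGES)]


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_two_sided: float
    n: int
    category: str

    def to_dict(self) -> dict:
        return {
            "r": self.r,
            "p_two_sided": self.p_two_sided,
            "n": self.n,
            "category": self.category,
        }


def pearson(x, y) -> CorrelationResult:
    """Pearson product-moment correlation with exact two-sided p.

    The p-value follows from t = r·sqrt((n−2)/(1−r²)) on n−2 degrees of
    freedom (the default in :func:`scipy.stats.pearsonr`).
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise ValidationError("x and y must have equal length")
    if x.size < 3:
        raise ValidationError(f"need at least 3 pairs, got {x.size}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValidationError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    r = float(np.clip(res.statistic, -1.0, 1.0))
    return CorrelationResult(
        r=r, p_two_sided=float(res.pvalue), n=int(x.size), category=strength_category(r)
    )


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bland–Altman summary of paired differences (method − reference)."""

    mean_diff_deg: float
    sd_diff_deg: float
    upper_loa_deg: float
    lower_loa_deg: float
    half_width_deg: float
    n: int | None = None

    def to_dict(self) -> dict:
        return {
            "mean_diff_deg": self.mean_diff_deg,
            "sd_diff_deg": self.sd_diff_deg,
            "upper_loa_deg": self.upper_loa_deg,
            "lower_loa_deg": self.lower_loa_deg,
            "half_width_deg": self.half_width_deg,
            "n": self.n,
        }


def limits_from_summary(mean_diff: float, sd_diff: float) -> BlandAltmanResult:
    """Limits of agreement from a reported mean ± SD of differences."""
    mean_diff = float(mean_diff)
    sd_diff = float(sd_diff)
    if sd_diff < 0:
        raise ValidationError("SD of differences cannot be negative")
    half = LOA_MULTIPLIER * sd_diff
    return BlandAltmanResult(
        mean_diff_deg=mean_diff,
        sd_diff_deg=sd_diff,
        upper_loa_deg=mean_diff + half,
        lower_loa_deg=mean_diff - half,
        half_width_deg=half,
        n=None,
    )


def bland_altman(x, y) -> BlandAltmanResult:
    """Limits of agreement for paired measurements (x = method, y = reference).

    Differences are x − y; the SD uses the n−1 denominator.
    """
    x = np.asarray(x, dtype=float).reshape(-1)
    y = np.asarray(y, dtype=float).reshape(-1)
    if x.size != y.size:
        raise ValidationError("paired arrays must have equal length")
    if x.size < 2:
        raise ValidationError(f"need at least 2 pairs, got {x.size}")
    d = x - y
    res = limits_from_summary(float(d.mean()), float(d.std(ddof=1)))
    return BlandAltmanResult(**{**res.to_dict(), "n": int(x.size)})


@dataclass(frozen=True)
class ICCResult:
    """One intraclass correlation estimate with its 95% CI."""

    model: str  # "oneway" | "twoway_random"
    unit: str  # "single" | "average"
    k: int
    n: int
    estimate: float
    ci95: tuple[float, float]
    label: str = ""

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "unit": self.unit,
            "k": self.k,
            "n": self.n,
            "estimate": self.estimate,
            "ci95": list(self.ci95),
            "label": self.label,
        }


def _anova_mean_squares(data: np.ndarray):
    """Mean squares of the targets × measurements two-way layout.

    Returns (bms, wms, jms, ems) — between-target, within-target,
    between-measurement (column), and residual mean squares.
    """
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_total = float(((data - grand) ** 2).sum())
    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    bms = ss_rows / (n - 1)
    wms = (ss_total - ss_rows) / (n * (k - 1))
    jms = ss_cols / (k - 1)
    ems = ss_err / ((n - 1) * (k - 1))
    return bms, wms, jms, ems


def _spearman_brown(r: float, k: int) -> float:
    return k * r / (1.0 + (k - 1) * r)


def icc(data, model: str = "oneway", unit: str = "single", confidence: float = 0.95) -> ICCResult:
    """Intraclass correlation of an ``n_targets × k_measurements`` matrix.

    ``model="oneway"`` treats measurements as nested within targets
    (intra-rater reliability); ``model="twoway_random"`` treats columns as
    a random sample of raters crossed with targets (inter-rater,
    absolute agreement). ``unit`` selects the single-measurement or the
    average-of-k form. Confidence intervals use the F-distribution
    constructions (Satterthwaite degrees of freedom for the two-way
    model), clamped to [−1, 1].
    """
    data = np.asarray(data, dtype=float)
    if data.ndim != 2:
        raise ValidationError("data must be a 2-D targets × measurements matrix")
    if np.any(~np.isfinite(data)):
        raise ValidationError("missing or non-finite cells are not supported")
    n, k = data.shape
    if n < 2 or k < 2:
        raise ValidationError(f"need at least 2 targets and 2 measurements, got {n}×{k}")
    if np.ptp(data) == 0:
        raise ValidationError("ICC undefined for a constant matrix")
    if model not in ("oneway", "twoway_random"):
        raise ValidationError(f"unknown model {model!r}")
    if unit not in ("single", "average"):
        raise ValidationError(f"unknown unit {unit!r}")

    bms, wms, jms, ems = _anova_mean_squares(data)
    alpha = 1.0 - confidence

    if model == "oneway":
        if wms == 0.0:  # perfect repeatability: degenerate but well-defined
            est = lo = hi = 1.0
        else:
            fvalue = bms / wms
            df1, df2 = n - 1, n * (k - 1)
            fl = fvalue / stats.f.ppf(1 - alpha / 2, df1, df2)
            fu = fvalue * stats.f.ppf(1 - alpha / 2, df2, df1)
            if unit == "single":
                est = (bms - wms) / (bms + (k - 1) * wms)
                lo = (fl - 1) / (fl + k - 1)
                hi = (fu - 1) / (fu + k - 1)
            else:
                est = (bms - wms) / bms
                lo = 1 - 1 / fl
                hi = 1 - 1 / fu
    else:
        if ems == 0.0 and jms == 0.0:  # columns identical: perfect agreement
            est = lo = hi = 1.0
        else:
            single = (bms - ems) / (bms + (k - 1) * ems + k * (jms - ems) / n)
            a = k * single / (n * (1.0 - single))
            b = 1.0 + k * single * (n - 1) / (n * (1.0 - single))
            v = (a * jms + b * ems) ** 2 / (
                (a * jms) ** 2 / (k - 1) + (b * ems) ** 2 / ((n - 1) * (k - 1))
            )
            f1 = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f2 = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo_s = n * (bms - f1 * ems) / (f1 * (k * jms + (k * n - k - n) * ems) + n * bms)
            hi_s = n * (f2 * bms - ems) / (k * jms + (k * n - k - n) * ems + n * f2 * bms)
            if unit == "single":
                est, lo, hi = single, lo_s, hi_s
            else:
                est = (bms - ems) / (bms + (jms - ems) / n)
                lo = _spearman_brown(lo_s, k)
                hi = _spearman_brown(hi_s, k)

    # the estimate is reported exactly as the ANOVA formulas give it
    # (average-of-k forms can drop below -1 on noise-only data); only the
    # interval is clamped to the nominal [-1, 1] range
    est = float(est)
    lo = float(np.clip(lo, -1.0, 1.0))
    hi = float(np.clip(hi, -1.0, 1.0))
    lo, hi = min(lo, est), max(hi, est)
    return ICCResult(model=model, unit=unit, k=int(k), n=int(n), estimate=est, ci95=(lo, hi))
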