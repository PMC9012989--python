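"""Face-chest temperature-difference features and verification statistics.

The mined rule — that the two cohorts differ in the relation between facial
and chest skin temperature — is verified on three per-subject features:

    ΔTavg = mean(face) − mean(chest)
    ΔTmax = max(face)  − max(chest)
    ΔTmin = min(face)  − min(chest)

where "face" pools the nonzero pixels of the two face ROIs (ROI9, ROI10) and
"chest" the two chest ROIs (ROI13, ROI14). Group contrasts are two-sample
t tests in both the pooled-variance and Welch (unequal-variance,
Satterthwaite df) flavors, with 95% confidence intervals, and study power
comes from the noncentral-t distribution of the two-sided two-sample test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .errors import DegenerateInputError, FeatureError, ParameterError
from .roi_segmentation import ROISet

__all__ = [
    "DeltaFeatures",
    "TTestResult",
    "PowerResult",
    "face_chest_delta",
    "two_sample_t",
    "select_variant",
    "ci_from_summary",
    "power_two_sample",
]

FACE_ROIS = ("ROI9", "ROI10")
CHEST_ROIS = ("ROI13", "ROI14")


@dataclass(frozen=True)
class DeltaFeatures:
    """Face-minus-chest differences, °C."""

    d_avg: float
    d_max: float
    d_min: float

    def as_dict(self) -> dict[str, float]:
        return {"d_avg": self.d_avg, "d_max": self.d_max, "d_min": self.d_min}


@dataclass(frozen=True)
class TTestResult:
    """Two-sample t test in SPSS table layout."""

    t: float
    df: float
    p: float                    # two-sided
    mean_difference: float      # mean(A) - mean(B), °C
    se_difference: float        # °C
    ci_low: float
    ci_high: float
    variant: str                # "welch" | "pooled"


@dataclass(frozen=True)
class PowerResult:
    effect_size: float          # Cohen's d
    n_per_group: int
    alpha: float
    power: float


def face_chest_delta(roiset: ROISet, pool_pixels: bool = True) -> DeltaFeatures:
    """Per-subject face-minus-chest features.

    ``pool_pixels=True`` (default) pools the nonzero pixels of both side ROIs
    before taking mean/max/min; the alternative averages each statistic over
    the left and right ROI separately and differences those.
    """

    def _nonzero(label: str) -> np.ndarray:
        vals = np.asarray(roiset[label], dtype=np.float64)
        return vals[vals != 0.0]

    face_parts = [_nonzero(l) for l in FACE_ROIS]
    chest_parts = [_nonzero(l) for l in CHEST_ROIS]
    if any(p.size == 0 for p in face_parts + chest_parts):
        empty = [
            l for l, p in zip(FACE_ROIS + CHEST_ROIS, face_parts + chest_parts) if p.size == 0
        ]
        raise FeatureError(f"face/chest ROIs entirely background: {empty}")
    if pool_pixels:
        face = np.concatenate(face_parts)
        chest = np.concatenate(chest_parts)
        return DeltaFeatures(
            d_avg=float(face.mean() - chest.mean()),
            d_max=float(face.max() - chest.max()),
            d_min=float(face.min() - chest.min()),
        )
    stat = lambda fn, parts: float(np.mean([fn(p) for p in parts]))
    return DeltaFeatures(
        d_avg=stat(np.mean, face_parts) - stat(np.mean, chest_parts),
        d_max=stat(np.max, face_parts) - stat(np.max, chest_parts),
        d_min=stat(np.min, face_parts) - stat(np.min, chest_parts),
    )


def two_sample_t(group_a, group_b, variant: str = "welch", level: float = 0.95) -> TTestResult:
    """Independent-samples t test with confidence interval.

    ``welch`` uses the unequal-variance statistic with Welch-Satterthwaite
    fractional df; ``pooled`` assumes equal variances with df = nA + nB - 2.
    Zero pooled spread (SE = 0) is degenerate and raises.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise DegenerateInputError("each group needs at least 2 observations")
    if variant not in ("welch", "pooled"):
        raise ParameterError(f"variant must be 'welch' or 'pooled', got {variant!r}")
    na, nb = a.size, b.size
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if variant == "welch":
        se = float(np.sqrt(va / na + vb / nb))
        if se == 0.0:
            raise DegenerateInputError("zero variance in both groups: SE of difference is 0")
        df = (va / na + vb / nb) ** 2 / (
            (va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1)
        )
    else:
        sp2 = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
        se = float(np.sqrt(sp2 * (1 / na + 1 / nb)))
        if se == 0.0:
            raise DegenerateInputError("zero variance in both groups: SE of difference is 0")
        df = na + nb - 2
    res = sps.ttest_ind(a, b, equal_var=(variant == "pooled"))
    md = float(a.mean() - b.mean())
    lo, hi = ci_from_summary(md, se, float(df), level)
    return TTestResult(
        t=float(res.statistic),
        df=float(df),
        p=float(res.pvalue),
        mean_difference=md,
        se_difference=se,
        ci_low=lo,
        ci_high=hi,
        variant=variant,
    )


def select_variant(group_a, group_b, alpha: float = 0.05) -> str:
    """Levene-style helper: 'welch' when Levene's test rejects equal
    variances at ``alpha``, else 'pooled' (the SPSS two-row convention)."""
    _, p = sps.levene(np.asarray(group_a, float), np.asarray(group_b, float))
    return "welch" if p < alpha else "pooled"


def ci_from_summary(
    mean_diff: float, se: float, df: float, level: float = 0.95
) -> tuple[float, float]:
    """Confidence interval ``mean_diff ± t_{df,(1+level)/2} * se`` from
    summary numbers alone (as printed in a t-test table)."""
    if se < 0:
        raise ParameterError("standard error cannot be negative")
    if df <= 0:
        raise ParameterError("degrees of freedom must be positive")
    half = float(sps.t.ppf((1 + level) / 2.0, df)) * se
    return (mean_diff - half, mean_diff + half)


def power_two_sample(
    mean_diff: float, se_diff: float, n_per_group: int, alpha: float = 0.05
) -> PowerResult:
    """Post-hoc power of the two-sided two-sample t test from summary numbers.

    The between-subject SD is recovered from the standard error of the
    difference as ``SD = SE * sqrt(n/2)``, giving Cohen's d = mean_diff/SD
    and noncentrality ``d * sqrt(n/2) = mean_diff / SE``. Power is the
    probability mass of the noncentral-t beyond the two-sided critical
    values at ``alpha`` with df = 2n - 2. A zero effect returns exactly
    ``alpha``.
    """
    if n_per_group < 2:
        raise DegenerateInputError("need at least 2 subjects per group")
    if se_diff <= 0:
        raise ParameterError("se_diff must be positive")
    sd = se_diff * np.sqrt(n_per_group / 2.0)
    d = mean_diff / sd
    df = 2 * n_per_group - 2
    ncp = mean_diff / se_diff
    tcrit = sps.t.ppf(1 - alpha / 2.0, df)
    power = float(1 - sps.nct.cdf(tcrit, df, ncp) + sps.nct.cdf(-tcrit, df, ncp))
    return PowerResult(effect_size=float(d), n_per_group=n_per_group, alpha=alpha, power=power)
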