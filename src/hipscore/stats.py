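"""Rater-agreement and association statistics.

The statistical battery used around the quality score: intraclass
correlation for two-rater (and manual-vs-AI) agreement, Pearson correlation
of anthropometric covariates with the composite score, an independent-sample
t-test for the sex difference, and one-way ANOVA over age-month groups.

The ICC is computed from two-way ANOVA mean squares.  With ``n`` subjects
and ``k`` raters, grand mean ``x..``, row means ``xi.`` and column means
``x.j``:

    MSR = k * sum_i (xi. - x..)^2 / (n - 1)        (between subjects)
    MSC = n * sum_j (x.j - x..)^2 / (k - 1)        (between raters)
    MSE = residual SS / ((n - 1)(k - 1))

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)
    ICC(C,1) = (MSR - MSE) / (MSR + (k-1) MSE)

ICC(A,1) (two-way, absolute agreement, single measurement) is the default:
for rater reliability a systematic offset between raters should count
against agreement.  ICC(C,1) (consistency) is available via ``variant``.

Pearson r, the t-test (pooled by default, Welch via a flag) and one-way
ANOVA delegate to scipy.stats; all p-values are two-sided and no
multiplicity correction is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .exceptions import UndefinedStatisticError, ValidationError

ICC_VARIANTS = ("absolute", "consistency")


@dataclass(frozen=True)
class AgreementResult:
    """An ICC estimate and the variant that produced it.

    ``icc`` can be slightly negative in small samples; it never exceeds 1.
    ``label`` follows the McGraw & Wong naming: ICC(A,1) or ICC(C,1).
    """

    icc: float
    variant: str

    @property
    def label(self) -> str:
        return {"absolute": "ICC(A,1)", "consistency": "ICC(C,1)"}[self.variant]


def _two_way_mean_squares(x: np.ndarray) -> tuple[float, float, float, int, int]:
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid**2) / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse), n, k


def icc(matrix, variant: str = "absolute") -> AgreementResult:
    """Intraclass correlation of an ``n_subjects x k_raters`` matrix.

    Parameters
    ----------
    matrix
        Complete real-valued ratings, one row per subject, one column per
        rater (or measurement method).
    variant
        ``"absolute"`` for ICC(A,1) — two-way, absolute agreement, single
        measurement (default) — or ``"consistency"`` for ICC(C,1).

    Raises
    ------
    UndefinedStatisticError
        If the total variance of the ratings is zero.
    """
    if variant not in ICC_VARIANTS:
        raise ValidationError(f"unknown ICC variant {variant!r}; use one of {ICC_VARIANTS}")
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValidationError(
            f"ratings matrix must be at least 2 subjects x 2 raters, got shape {x.shape}"
        )
    if not np.isfinite(x).all():
        raise ValidationError("ratings matrix contains missing or non-finite cells")

    msr, msc, mse, n, k = _two_way_mean_squares(x)
    if x.var() == 0:
        raise UndefinedStatisticError("all ratings identical: ICC undefined (0/0)")
    if variant == "absolute":
        denom = msr + (k - 1) * mse + k * (msc - mse) / n
    else:
        denom = msr + (k - 1) * mse
    if denom == 0:
        raise UndefinedStatisticError("zero denominator: ICC undefined")
    return AgreementResult(icc=float((msr - mse) / denom), variant=variant)


@dataclass(frozen=True)
class AnglePair:
    """Graf acetabular angles in degrees for one hip."""

    alpha_deg: float
    beta_deg: float

    def __post_init__(self) -> None:
        for name in ("alpha_deg", "beta_deg"):
            v = getattr(self, name)
            if not 0.0 < v < 180.0:
                raise ValidationError(f"{name}={v} must lie strictly between 0 and 180")


def angle_agreement(angles, variant: str = "absolute") -> dict[str, AgreementResult]:
    """Method-agreement ICC for alpha and beta angles.

    ``angles`` is a long table with columns ``case_id, method, alpha_deg,
    beta_deg`` (e.g. manual vs AI measurement of the same hips).  Returns
    one :class:`AgreementResult` per angle.
    """
    out = {}
    for col in ("alpha_deg", "beta_deg"):
        for v in angles[col]:
            if not 0.0 < float(v) < 180.0:
                raise ValidationError(f"{col}={v} outside (0, 180)")
        wide = angles.pivot(index="case_id", columns="method", values=col)
        if wide.isna().any().any():
            raise ValidationError(f"{col}: not every case was measured by every method")
        out[col.removesuffix("_deg")] = icc(wide.to_numpy(float), variant=variant)
    return out


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with its two-sided p-value."""
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValidationError("x and y must be 1-d vectors of equal length")
    if xa.size < 3:
        raise ValidationError(f"need at least 3 observations, got {xa.size}")
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise UndefinedStatisticError("correlation undefined for a constant vector")
    r, p = sps.pearsonr(xa, ya)
    return float(r), float(p)


def ttest_independent(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample t statistic and two-sided p-value.

    Pooled-variance by default; pass ``equal_var=False`` for Welch.
    """
    aa = np.asarray(a, dtype=float)
    ba = np.asarray(b, dtype=float)
    if aa.size < 2 or ba.size < 2:
        raise ValidationError("each group needs at least 2 observations")
    t, p = sps.ttest_ind(aa, ba, equal_var=equal_var)
    return float(t), float(p)


def anova_oneway(groups) -> tuple[float, float]:
    """One-way ANOVA F statistic and p-value over two or more groups."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if len(arrays) < 2:
        raise ValidationError(f"ANOVA needs at least 2 groups, got {len(arrays)}")
    for i, g in enumerate(arrays):
        if g.size < 2:
            raise ValidationError(f"group {i} has {g.size} observations; need at least 2")
    f, p = sps.f_oneway(*arrays)
    return float(f), float(p)
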