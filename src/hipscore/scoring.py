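"""Rubric scores, entropy-weight computation, and the composite quality score.

Infant hip ultrasound images (Graf coronal plane) are scored 1-5 by each
rater on the visibility of three anatomical structures:

* ``brp`` — bony rim point
* ``lil`` — lower iliac limb point
* ``gl``  — glenoid labrum

Scores are averaged over raters, the entropy weight method assigns each
structure an objective weight proportional to the diversity of its scores
across images, and the final quality score is the weighted average.  A
composite score strictly greater than 3 marks the image as clear enough for
angle measurement; per-structure measurability uses score >= 3.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import DegenerateDataError, ValidationError

#: Structure column names, in rubric order.
STRUCTURES: tuple[str, str, str] = ("brp", "lil", "gl")

#: Composite-score decision threshold: q > 3 means clear and measurable.
DEFAULT_THRESHOLD: float = 3.0

#: Per-structure measurability threshold: a structure scored >= 3 is measurable.
STRUCTURE_THRESHOLD: float = 3.0

SCORE_MIN, SCORE_MAX = 1, 5


@dataclass(frozen=True)
class StructureScoreTriple:
    """One rater's integer rubric scores for a single image."""

    brp: int
    lil: int
    gl: int

    def __post_init__(self) -> None:
        for name in STRUCTURES:
            v = getattr(self, name)
            if not (isinstance(v, (int, np.integer)) and SCORE_MIN <= v <= SCORE_MAX):
                raise ValidationError(
                    f"rubric score {name}={v!r} is not an integer in "
                    f"[{SCORE_MIN}, {SCORE_MAX}]"
                )


@dataclass(frozen=True)
class AveragedScores:
    """Per-image structure scores averaged over raters (each in [1, 5])."""

    brp: float
    lil: float
    gl: float

    def __post_init__(self) -> None:
        for name in STRUCTURES:
            v = getattr(self, name)
            if not SCORE_MIN <= v <= SCORE_MAX:
                raise ValidationError(f"averaged score {name}={v} outside [1, 5]")

    def as_array(self) -> np.ndarray:
        return np.array([self.brp, self.lil, self.gl], dtype=float)


@dataclass(frozen=True)
class EntropyWeights:
    """Nonnegative structure weights summing to 1."""

    brp: float
    lil: float
    gl: float

    def __post_init__(self) -> None:
        w = self.as_array()
        if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
            raise ValidationError(f"weights {tuple(w)} must be >= 0 and sum to 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.brp, self.lil, self.gl], dtype=float)

    @classmethod
    def from_array(cls, w) -> "EntropyWeights":
        return cls(*(float(v) for v in w))


#: Published structure weights (rounded to two decimals in the reference analysis).
PUBLISHED_WEIGHTS = EntropyWeights(0.29, 0.41, 0.30)


@dataclass(frozen=True)
class WeightedQualityScore:
    """Composite quality score and the measurability decision."""

    q: float
    qualified: bool


def validate_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Validate a long-format rater score table.

    Expects columns ``image_id, rater_id, brp, lil, gl``.  Checks that every
    score is an integer in {1..5}, that no (image, rater) pair is duplicated,
    and that every image was scored by the same set of raters.

    Returns the table unchanged (sorted copy).  Raises
    :class:`ValidationError` naming the offending row otherwise.
    """
    required = ["image_id", "rater_id", *STRUCTURES]
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ValidationError(f"score table is missing columns {missing}")

    for name in STRUCTURES:
        col = table[name]
        numeric = pd.to_numeric(col, errors="coerce")
        bad = numeric.isna() | (numeric != numeric.round()) | (numeric < SCORE_MIN) | (numeric > SCORE_MAX)
        if bad.any():
            i = int(np.flatnonzero(bad.to_numpy())[0])
            row = table.iloc[i]
            raise ValidationError(
                f"row {i} (image {row['image_id']!r}, rater {row['rater_id']!r}): "
                f"{name}={row[name]!r} is not an integer in [{SCORE_MIN}, {SCORE_MAX}]"
            )

    dup = table.duplicated(subset=["image_id", "rater_id"])
    if dup.any():
        i = int(np.flatnonzero(dup.to_numpy())[0])
        row = table.iloc[i]
        raise ValidationError(
            f"row {i}: duplicate rating of image {row['image_id']!r} "
            f"by rater {row['rater_id']!r}"
        )

    rater_sets = table.groupby("image_id")["rater_id"].agg(frozenset)
    if rater_sets.nunique() > 1:
        ref = rater_sets.iloc[0]
        offender = rater_sets[rater_sets != ref].index[0]
        raise ValidationError(
            f"image {offender!r} was rated by {sorted(rater_sets[offender])}, "
            f"expected raters {sorted(ref)}"
        )

    out = table.sort_values(["image_id", "rater_id"], kind="stable").reset_index(drop=True)
    out[list(STRUCTURES)] = out[list(STRUCTURES)].astype(int)
    return out


def average_raters(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of each structure score over raters, per image.

    Returns a frame with columns ``image_id, brp, lil, gl`` in the input's
    image order of first appearance.
    """
    if table.empty:
        raise ValidationError("score table is empty")
    avg = (
        table.groupby("image_id", sort=False)[list(STRUCTURES)]
        .mean()
        .reset_index()
    )
    return avg


def entropy_weights(matrix: np.ndarray, d_tol: float = 1e-12) -> np.ndarray:
    """Entropy-weight-method weights for the columns of a score matrix.

    For an ``n x m`` matrix of positive scores ``x_ij`` (images by
    structures):

    .. math::

        p_{ij} = x_{ij} / \\sum_i x_{ij}, \\qquad
        e_j = -\\frac{1}{\\ln n} \\sum_i p_{ij} \\ln p_{ij}, \\qquad
        d_j = 1 - e_j, \\qquad
        w_j = d_j / \\sum_j d_j

    with the convention ``0 ln 0 = 0``.  A column whose scores are all equal
    has maximal entropy (``e_j = 1``), hence zero diversity and zero weight:
    an indicator that does not discriminate between images carries no
    information.  If *every* column is constant the total diversity is zero
    and :class:`DegenerateDataError` is raised — a caller wanting equal
    weights in that situation must opt in explicitly.

    Rubric scores are strictly positive, so no min-max shift is applied
    before normalisation.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        raise ValidationError("score matrix must be 2-dimensional")
    n, m = x.shape
    if n < 2:
        raise ValidationError(f"entropy weighting needs at least 2 rows, got {n}")
    if np.any(x < 0):
        raise ValidationError("score matrix entries must be nonnegative")
    colsum = x.sum(axis=0)
    if np.any(colsum <= 0):
        j = int(np.flatnonzero(colsum <= 0)[0])
        raise ValidationError(f"column {j} has nonpositive sum; scores must be positive")

    p = x / colsum
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    d = np.clip(1.0 - e, 0.0, None)  # fp noise can push a constant column to -1e-16
    total = d.sum()
    if total <= d_tol:
        raise DegenerateDataError(
            "all columns are constant: zero total diversity, entropy weights undefined"
        )
    return d / total


def structure_weights(averaged: pd.DataFrame) -> EntropyWeights:
    """Entropy weights of the three structures from an averaged-score table."""
    return EntropyWeights.from_array(entropy_weights(averaged[list(STRUCTURES)].to_numpy()))


def qualify(q, threshold: float = DEFAULT_THRESHOLD):
    """Measurability decision: strictly greater than the threshold.

    A composite score of exactly 3 is *not* qualified.  Works on scalars and
    arrays.
    """
    return np.asarray(q) > threshold if np.ndim(q) else q > threshold


def weighted_score(
    scores: AveragedScores | pd.DataFrame,
    weights: EntropyWeights,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Composite quality score ``q = w . (brp, lil, gl)`` and its decision.

    Accepts a single :class:`AveragedScores` (returns a
    :class:`WeightedQualityScore`) or an averaged-score frame (returns the
    frame with ``q`` and ``qualified`` columns appended).  As a convex
    combination, ``q`` always lies between the smallest and largest of the
    three structure scores.
    """
    w = weights.as_array()
    if isinstance(scores, AveragedScores):
        q = float(scores.as_array() @ w)
        return WeightedQualityScore(q=q, qualified=bool(qualify(q, threshold)))
    out = scores.copy()
    q = out[list(STRUCTURES)].to_numpy() @ w
    out["q"] = q
    out["qualified"] = q > threshold
    return out


def below_threshold_by_month(
    age_months,
    q,
    threshold: float = DEFAULT_THRESHOLD,
) -> dict[int, float]:
    """Per-age-month fraction of composite scores strictly below the threshold.

    The study reports this as the month-wise proportion of images whose final
    weighted score falls under 3 — the share of infants for whom the
    ultrasound image was not measurable.  Proportions are rounded to two
    decimals; months with no records are omitted.
    """
    age = np.asarray(age_months)
    qv = np.asarray(q, dtype=float)
    if age.shape[0] != qv.shape[0]:
        raise ValidationError(
            f"{age.shape[0]} age records but {qv.shape[0]} scores; must align one-to-one"
        )
    out: dict[int, float] = {}
    for month in sorted(np.unique(age)):
        mask = age == month
        out[int(month)] = round(float((qv[mask] < threshold).mean()), 2)
    return out
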