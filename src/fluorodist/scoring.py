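"""Distribution scoring for organ-uptake images.

Each compound's biodistribution image yields three mean pixel intensities on
the 8-bit [0, 255] scale: the target organ, a muscle reference, and the
system background (BG).  Because images were acquired over years on
different systems, raw intensities are not comparable across compounds.  The
exposure adjustment function (EAF) re-maps intensities along the line
through (BG, 0) and the fixed midpoint (127.5, 127.5), clamped to [0, 255] —
i.e. the contrast adjustment that pins the system background of every image
to 0 while leaving the mid-intensity untouched:

    c(x) = clamp(127.5 / (127.5 - BG) * (x - 127.5) + 127.5, 0, 255)

The distribution score for compound i and one organ is then

    Score_i = c(ORG_i) - c(MU_i)

so a compound that is no brighter in the organ than in muscle scores ~0
regardless of exposure.  Scores are ranked per organ into quantile labels:
-1 for negative scores, 0-3 for the ascending empirical quartiles of the
non-negative scores.  Labels >= 2 mark "high-scoring" compounds
(approximately the upper half of organ uptake).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .errors import DegenerateBackgroundError, EmptyInputError, LabelError, RangeError

MIDPOINT = 127.5
INTENSITY_MAX = 255.0

VALID_QUANTILES = (-1, 0, 1, 2, 3)
HIGH_THRESHOLD = 2


@dataclass(frozen=True)
class IntensityMeasurement:
    """Raw mean intensities for one compound-organ pair, all on [0, 255]."""

    compound_id: str
    organ: str
    organ_intensity: float
    muscle_intensity: float
    background: float

    def __post_init__(self):
        for name in ("organ_intensity", "muscle_intensity", "background"):
            v = getattr(self, name)
            if not (0.0 <= v <= INTENSITY_MAX):
                raise RangeError(f"{name}={v} outside [0, 255] for {self.compound_id}/{self.organ}")


@dataclass(frozen=True)
class DistributionScore:
    """Score, quantile label and high/low flag for one compound-organ pair."""

    compound_id: str
    organ: str
    score: float
    quantile: int | None = None
    high: bool | None = None


def _check_background(bg: np.ndarray | float) -> None:
    bg = np.asarray(bg, dtype=float)
    if np.any(bg < 0) or np.any(bg > INTENSITY_MAX):
        raise RangeError("background outside [0, 255]")
    if np.any(bg >= MIDPOINT):
        raise DegenerateBackgroundError(
            "background >= 127.5: exposure-adjustment slope undefined or negative"
        )


def exposure_adjust(x, bg):
    """Contrast-adjust intensity ``x`` so the system background maps to 0.

    Parameters
    ----------
    x : float or array-like
        Raw mean intensity in [0, 255].
    bg : float or array-like
        System background intensity in [0, 127.5).

    Returns
    -------
    float or ndarray
        Adjusted intensity, clamped to [0, 255].  Exactly 0 at ``x == bg``,
        exactly 127.5 at ``x == 127.5``, the identity map when ``bg == 0``,
        and non-decreasing in ``x``.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0) or np.any(x_arr > INTENSITY_MAX):
        raise RangeError("intensity outside [0, 255]")
    _check_background(bg)
    bg_arr = np.asarray(bg, dtype=float)
    adjusted = MIDPOINT / (MIDPOINT - bg_arr) * (x_arr - MIDPOINT) + MIDPOINT
    adjusted = np.clip(adjusted, 0.0, INTENSITY_MAX)
    if np.isscalar(x) and np.isscalar(bg):
        return float(adjusted)
    return adjusted


def distribution_score(measurement: IntensityMeasurement) -> DistributionScore:
    """Score one measurement: adjusted organ minus adjusted muscle intensity.

    The same background is applied to both intensities (they come from the
    same image).  The result lies in [-255, 255] and is antisymmetric under
    swapping organ and muscle.
    """
    score = score_value(
        measurement.organ_intensity, measurement.muscle_intensity, measurement.background
    )
    return DistributionScore(measurement.compound_id, measurement.organ, float(score))


def score_value(organ_intensity, muscle_intensity, background):
    """Vectorized distribution score from raw intensities."""
    return exposure_adjust(organ_intensity, background) - exposure_adjust(
        muscle_intensity, background
    )


def assign_quantiles(scores: Sequence[float]) -> np.ndarray:
    """Label scores for one organ: -1 if negative, else ascending quartiles 0-3.

    Quartile edges fall at ranks ceil(k*n/4) over the n non-negative scores;
    tied scores share the label of their lowest rank.  The labeling depends
    only on the rank order of the non-negative scores, so it is invariant
    under any strictly increasing transform.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise EmptyInputError("no scores to label")
    labels = np.full(scores.shape, -1, dtype=int)
    nonneg = scores >= 0
    n = int(nonneg.sum())
    if n == 0:
        return labels
    vals = scores[nonneg]
    order = np.argsort(vals, kind="stable")
    # min-rank for ties: number of strictly smaller values
    min_rank = np.searchsorted(vals[order], vals, side="left")
    edges = np.ceil(np.arange(1, 5) * n / 4.0)
    labels[nonneg] = np.searchsorted(edges, min_rank, side="right")
    return labels


def high_scoring(quantile: int) -> bool:
    """True iff the quantile label marks a high-scoring compound (label >= 2)."""
    if quantile not in VALID_QUANTILES:
        raise LabelError(f"quantile label {quantile!r} not in {VALID_QUANTILES}")
    return quantile >= HIGH_THRESHOLD
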