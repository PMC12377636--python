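"""Chemical-space segmentation in the (logD, TPSA) plane.

Two fixed segmentations of the hydrophobicity/polarity plane, one per
clearance organ, with thresholds read off the uptake scatterplots:

* **liver** — six regions from logD bands at -1 and 2.3 crossed with a TPSA
  band at 90 A^2.  The high-TPSA row is I, II, III left-to-right by
  increasing logD; the low-TPSA row is IV, V, VI.  Regions IV (hydrophilic
  cations, low TPSA) and VI (lipophilic, low TPSA) are where hepatic uptake
  concentrates.
* **kidney** — four regions from logD bands at -5, 0 and 5.5 (TPSA is not
  used: renally cleared compounds span high TPSA).  Regions II and III
  (logD between -5 and 5.5) are where renal uptake concentrates.

Boundary conventions: bands are lower-closed/upper-open, except the liver
middle logD band which is closed on both ends (-1 <= logD <= 2.3) so that
the named uptake regions are strict ("logD less than -1 or greater than
2.3").  The low-TPSA row requires TPSA < 90 strictly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

LIVER_LOGD_THRESHOLDS = (-1.0, 2.3)
LIVER_TPSA_THRESHOLD = 90.0
KIDNEY_LOGD_THRESHOLDS = (-5.0, 0.0, 5.5)

LIVER_REGIONS = ("I", "II", "III", "IV", "V", "VI")
KIDNEY_REGIONS = ("I", "II", "III", "IV")


@dataclass(frozen=True)
class RegionScheme:
    """Configurable thresholds for one organ's segmentation scheme."""

    scheme: str  # "liver" or "kidney"
    logd_thresholds: tuple[float, ...]
    tpsa_threshold: float | None = None

    def __post_init__(self):
        if self.scheme not in ("liver", "kidney"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if list(self.logd_thresholds) != sorted(self.logd_thresholds):
            raise ValueError("logD thresholds must be strictly increasing")
        if self.scheme == "liver" and (
            len(self.logd_thresholds) != 2 or self.tpsa_threshold is None
        ):
            raise ValueError("liver scheme needs 2 logD thresholds and a TPSA threshold")
        if self.scheme == "kidney" and len(self.logd_thresholds) != 3:
            raise ValueError("kidney scheme needs 3 logD thresholds")

    @property
    def labels(self) -> tuple[str, ...]:
        return LIVER_REGIONS if self.scheme == "liver" else KIDNEY_REGIONS


DEFAULT_LIVER_SCHEME = RegionScheme("liver", LIVER_LOGD_THRESHOLDS, LIVER_TPSA_THRESHOLD)
DEFAULT_KIDNEY_SCHEME = RegionScheme("kidney", KIDNEY_LOGD_THRESHOLDS)


def _check_finite(*values):
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"non-finite coordinate {v!r}")


def liver_region(logd: float, tpsa: float, scheme: RegionScheme = DEFAULT_LIVER_SCHEME) -> str:
    """Assign the liver-scheme region for one compound.

    Returns one of I-VI.  IV iff TPSA < 90 and logD < -1; VI iff TPSA < 90
    and logD > 2.3; V for the middle logD band below 90; I/II/III mirror
    IV/V/VI at TPSA >= 90.
    """
    _check_finite(logd, tpsa)
    if tpsa < 0:
        raise ValueError(f"negative TPSA {tpsa}")
    lo, hi = scheme.logd_thresholds
    col = 0 if logd < lo else (2 if logd > hi else 1)
    row = 1 if tpsa < scheme.tpsa_threshold else 0
    return LIVER_REGIONS[3 * row + col]


def kidney_region(logd: float, scheme: RegionScheme = DEFAULT_KIDNEY_SCHEME) -> str:
    """Assign the kidney-scheme region (I-IV) from logD alone.

    Bands are lower-closed: I iff logD < -5; II iff -5 <= logD < 0;
    III iff 0 <= logD < 5.5; IV iff logD >= 5.5.
    """
    _check_finite(logd)
    idx = int(np.searchsorted(scheme.logd_thresholds, logd, side="right"))
    return KIDNEY_REGIONS[idx]


def liver_regions(logd, tpsa, scheme: RegionScheme = DEFAULT_LIVER_SCHEME) -> np.ndarray:
    """Vectorized :func:`liver_region` over arrays of coordinates."""
    logd = np.asarray(logd, dtype=float)
    tpsa = np.asarray(tpsa, dtype=float)
    if not (np.all(np.isfinite(logd)) and np.all(np.isfinite(tpsa))):
        raise ValueError("non-finite coordinates")
    lo, hi = scheme.logd_thresholds
    col = np.where(logd < lo, 0, np.where(logd > hi, 2, 1))
    row = np.where(tpsa < scheme.tpsa_threshold, 1, 0)
    return np.asarray(LIVER_REGIONS)[3 * row + col]


def kidney_regions(logd, scheme: RegionScheme = DEFAULT_KIDNEY_SCHEME) -> np.ndarray:
    """Vectorized :func:`kidney_region` over an array of logD values."""
    logd = np.asarray(logd, dtype=float)
    if not np.all(np.isfinite(logd)):
        raise ValueError("non-finite coordinates")
    idx = np.searchsorted(np.asarray(scheme.logd_thresholds), logd, side="right")
    return np.asarray(KIDNEY_REGIONS)[idx]


def assign_region(organ: str, logd, tpsa=None, scheme: RegionScheme | None = None):
    """Region label(s) for ``organ`` ("liver" needs TPSA, "kidney" does not)."""
    if organ == "liver":
        sch = scheme or DEFAULT_LIVER_SCHEME
        if np.isscalar(logd):
            return liver_region(float(logd), float(tpsa), sch)
        return liver_regions(logd, tpsa, sch)
    if organ == "kidney":
        sch = scheme or DEFAULT_KIDNEY_SCHEME
        if np.isscalar(logd):
            return kidney_region(float(logd), sch)
        return kidney_regions(logd, sch)
    raise ValueError(f"no segmentation scheme for organ {organ!r}")
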