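"""Hypergeometric enrichment of high-scoring compounds in chemical-space regions.

For a stratum (organ, skeleton type, region, optional charge filter) the
question is whether the region holds more high-scoring compounds of the
type than a random draw from that type would.  With

* ``y`` — total compounds of the type,
* ``x`` — high-scoring compounds of the type,
* ``n`` — compounds of the type in the region (after the charge filter),
* ``m`` — high-scoring compounds of the type in the region,

the point probability under random placement is the hypergeometric pmf

    P(X = m) = C(x, m) * C(y - x, n - m) / C(y, n)

and the upper tail P(X >= m) sums the pmf from m to min(x, n).  Both are
reported for every stratum: the point mass is what the published table
prints; the tail is the conventional enrichment p-value.  No
multiple-testing correction is applied; reports carry the number of strata
tested.

Probabilities are computed in log space (log-gamma binomials +
log-sum-exp), exact to well below reporting precision for populations in
the hundreds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .errors import CountConsistencyError, StratumSpecError

POSITIVE, NEGATIVE, NEUTRAL = "positive", "negative", "neutral_or_zwitterion"
_CHARGE_FILTERS = {
    POSITIVE: lambda c: c > 0,
    NEGATIVE: lambda c: c < 0,
    NEUTRAL: lambda c: c == 0,
}


def _check_counts(m: int, y: int, x: int, n: int) -> None:
    for name, v in (("m", m), ("y", y), ("x", x), ("n", n)):
        if v != int(v) or v < 0:
            raise CountConsistencyError(f"count {name}={v} must be a non-negative integer")
    if x > y or n > y:
        raise CountConsistencyError(f"x={x} and n={n} must not exceed y={y}")
    if m > x or m > n:
        raise CountConsistencyError(f"m={m} must not exceed x={x} or n={n}")


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def _log_pmf_range(k: np.ndarray, y: int, x: int, n: int) -> np.ndarray:
    return _log_binom(x, k) + _log_binom(y - x, n - k) - _log_binom(y, n)


def hypergeom_pmf(m: int, y: int, x: int, n: int) -> float:
    """P(X = m) drawing n from a population of y containing x successes.

    Returns 0.0 for feasible counts below the support floor
    max(0, n - (y - x)) (more region non-successes than exist in the type).
    """
    _check_counts(m, y, x, n)
    if m < n - (y - x):
        return 0.0
    return float(np.exp(_log_pmf_range(np.array([m]), y, x, n)[0]))


def hypergeom_upper_tail(m: int, y: int, x: int, n: int) -> float:
    """P(X >= m); equals 1 whenever m is at or below the support floor."""
    _check_counts(m, y, x, n)
    if m <= max(0, n - (y - x)):
        return 1.0
    k = np.arange(m, min(x, n) + 1)
    return float(min(1.0, np.exp(logsumexp(_log_pmf_range(k, y, x, n)))))


@dataclass(frozen=True)
class StratumSpec:
    """One enrichment stratum: which compounds form the population and region.

    ``skeleton=None`` pools all skeletons; ``charge=None`` applies no charge
    filter.  A charge filter restricts the *region* membership counts
    (n, m) only — the type totals (y, x) always cover every compound of the
    type, matching how the published counts are defined.
    """

    organ: str
    region: str
    skeleton: str | None = None
    charge: str | None = None  # "positive" | "negative" | "neutral_or_zwitterion"

    def describe(self) -> str:
        parts = [self.organ, self.skeleton or "all skeletons", f"region {self.region}"]
        if self.charge:
            parts.append(self.charge)
        return ", ".join(parts)


@dataclass(frozen=True)
class EnrichmentRow:
    """Counts and probabilities for one stratum (the published table's quintet)."""

    organ: str
    skeleton: str
    region: str
    charge: str
    x: int
    y: int
    m: int
    n: int
    p_pmf: float
    p_tail: float


@dataclass(frozen=True)
class ChargeBreakdownRow:
    """High-scoring percentage within one net-charge bin of a stratum."""

    organ: str
    region: str
    skeleton: str
    net_charge: int
    n_in_bin: int
    n_high_in_bin: int

    @property
    def pct_high(self) -> float:
        return 100.0 * self.n_high_in_bin / self.n_in_bin


# columns expected on the scored long-format table
_REQUIRED = ("compound_id", "organ", "skeleton", "net_charge", "region", "high")


def _validate_scored(scored: pd.DataFrame) -> None:
    missing = [c for c in _REQUIRED if c not in scored.columns]
    if missing:
        raise StratumSpecError(f"scored table missing columns: {missing}")


def _stratum_counts(scored: pd.DataFrame, spec: StratumSpec) -> tuple[int, int, int, int]:
    sub = scored[scored["organ"] == spec.organ]
    if sub.empty:
        raise StratumSpecError(f"no scored rows for organ {spec.organ!r}")
    if spec.skeleton is not None:
        if spec.skeleton not in set(scored["skeleton"]):
            raise StratumSpecError(f"unknown skeleton {spec.skeleton!r}")
        sub = sub[sub["skeleton"] == spec.skeleton]
    if spec.region not in set(scored.loc[scored["organ"] == spec.organ, "region"]):
        known = sorted(set(scored.loc[scored["organ"] == spec.organ, "region"]))
        # a threshold region can legitimately be empty; only reject labels
        # outside the scheme entirely
        from .segmentation import KIDNEY_REGIONS, LIVER_REGIONS

        if spec.region not in LIVER_REGIONS + KIDNEY_REGIONS:
            raise StratumSpecError(f"unknown region {spec.region!r} (observed: {known})")
    y = len(sub)
    x = int(sub["high"].sum())
    in_region = sub[sub["region"] == spec.region]
    if spec.charge is not None:
        if spec.charge not in _CHARGE_FILTERS:
            raise StratumSpecError(f"unknown charge filter {spec.charge!r}")
        in_region = in_region[_CHARGE_FILTERS[spec.charge](in_region["net_charge"])]
    n = len(in_region)
    m = int(in_region["high"].sum())
    return x, y, m, n


def build_enrichment_table(
    scored: pd.DataFrame, strata: list[StratumSpec]
) -> list[EnrichmentRow]:
    """Count and test every stratum against the scored long-format table.

    ``scored`` needs one row per (compound, organ) with columns
    compound_id, organ, skeleton, net_charge, region, high.
    """
    _validate_scored(scored)
    rows = []
    for spec in strata:
        x, y, m, n = _stratum_counts(scored, spec)
        rows.append(
            EnrichmentRow(
                organ=spec.organ,
                skeleton=spec.skeleton or "all",
                region=spec.region,
                charge=spec.charge or "any",
                x=x,
                y=y,
                m=m,
                n=n,
                p_pmf=hypergeom_pmf(m, y, x, n),
                p_tail=hypergeom_upper_tail(m, y, x, n),
            )
        )
    return rows


def enrichment_frame(rows: list[EnrichmentRow]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in rows])


def charge_breakdown(
    scored: pd.DataFrame, organ: str, region: str, skeleton: str | None = None
) -> list[ChargeBreakdownRow]:
    """Per-net-charge high-scoring percentages within one (organ, region).

    Bins with no compounds are omitted (no denominator).  Percentages are
    exact here; rounding to integers happens only at report time.
    """
    _validate_scored(scored)
    sub = scored[(scored["organ"] == organ) & (scored["region"] == region)]
    if skeleton is not None:
        sub = sub[sub["skeleton"] == skeleton]
    rows = []
    for charge, grp in sub.groupby("net_charge", sort=True):
        rows.append(
            ChargeBreakdownRow(
                organ=organ,
                region=region,
                skeleton=skeleton or "all",
                net_charge=int(charge),
                n_in_bin=len(grp),
                n_high_in_bin=int(grp["high"].sum()),
            )
        )
    return rows


def round_half_away(value: float) -> int:
    """Round to nearest integer, halves away from zero (report-time only)."""
    return int(np.sign(value) * np.floor(abs(value) + 0.5))
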