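"""Model/Results objects tying the biodistribution pipeline together.

:class:`BiodistributionModel` is built from a per-compound descriptor table
and a per-(compound, organ) intensity table; :meth:`~BiodistributionModel.fit`
runs the full pipeline — exposure-adjusted distribution scores, per-organ
quantile labels, chemical-space region assignment, and hypergeometric
enrichment over the configured strata — and returns a
:class:`BiodistributionResults` holding the scored table, the enrichment
table, per-row validation outcomes and a text ``summary()``.

Example
-------
>>> from fluorodist import synthetic, BiodistributionModel
>>> records, truth = synthetic.generate_library(synthetic.SyntheticConfig(seed=7))
>>> res = BiodistributionModel.from_records(records).fit()
>>> print(res.summary())          # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import scoring
from .descriptors import (
    FluorophoreRecord,
    ValidationReport,
    descriptor_frame,
    records_from_frame,
)
from .enrichment import (
    EnrichmentRow,
    StratumSpec,
    build_enrichment_table,
    charge_breakdown,
    enrichment_frame,
    round_half_away,
)
from .errors import JoinError, SchemaError
from .segmentation import (
    DEFAULT_KIDNEY_SCHEME,
    DEFAULT_LIVER_SCHEME,
    RegionScheme,
    kidney_regions,
    liver_regions,
)
from .synthetic import intensity_frame, summarize_library

INTENSITY_COLUMNS = ("id", "organ", "organ_intensity", "muscle_intensity", "background")

# the published table's strata: per-cyanine-type, positively charged, in the
# organ's concentrated-uptake regions
DEFAULT_STRATA = (
    StratumSpec("liver", "IV", "pentamethine", "positive"),
    StratumSpec("liver", "VI", "heptamethine", "positive"),
    StratumSpec("kidney", "III", "pentamethine", "positive"),
    StratumSpec("kidney", "III", "heptamethine", "positive"),
)


class BiodistributionModel:
    """Scoring + segmentation + enrichment pipeline over one compound library.

    Parameters
    ----------
    descriptors : DataFrame
        Required columns: id, skeleton, mw, logd, tpsa, net_charge.
    intensities : DataFrame
        Long format, one row per (compound, organ): id, organ,
        organ_intensity, muscle_intensity, background — all on [0, 255].
    strata : sequence of StratumSpec, optional
        Enrichment strata to test; defaults to the four cyanine strata in
        the organ-specific uptake regions.
    liver_scheme, kidney_scheme : RegionScheme, optional
        Segmentation thresholds; defaults are logD {-1, 2.3} x TPSA 90 for
        the liver and logD {-5, 0, 5.5} for the kidney.
    """

    def __init__(
        self,
        descriptors: pd.DataFrame,
        intensities: pd.DataFrame,
        strata=DEFAULT_STRATA,
        liver_scheme: RegionScheme = DEFAULT_LIVER_SCHEME,
        kidney_scheme: RegionScheme = DEFAULT_KIDNEY_SCHEME,
    ):
        missing = [c for c in INTENSITY_COLUMNS if c not in intensities.columns]
        if missing:
            raise SchemaError(missing)
        self.records, self.validation = records_from_frame(descriptors)
        self.intensities = intensities.copy()
        self.intensities["id"] = self.intensities["id"].astype(str)
        self.strata = list(strata)
        self.liver_scheme = liver_scheme
        self.kidney_scheme = kidney_scheme

        known = {r.id for r in self.records} | set(self.validation.issues)
        orphans = sorted(set(self.intensities["id"]) - known)
        if orphans:
            raise JoinError(orphans)

    @classmethod
    def from_tables(cls, descriptor_path, intensity_path, **kwargs) -> "BiodistributionModel":
        """Build from CSV/TSV files on disk."""
        dpath, ipath = Path(descriptor_path), Path(intensity_path)
        dsep = "\t" if dpath.suffix.lower() in (".tsv", ".tab") else ","
        isep = "\t" if ipath.suffix.lower() in (".tsv", ".tab") else ","
        return cls(
            pd.read_csv(dpath, sep=dsep, dtype={"id": str}),
            pd.read_csv(ipath, sep=isep, dtype={"id": str}),
            **kwargs,
        )

    @classmethod
    def from_records(cls, records: list[FluorophoreRecord], **kwargs) -> "BiodistributionModel":
        """Build from records carrying their own intensity measurements."""
        return cls(descriptor_frame(records), intensity_frame(records), **kwargs)

    def fit(self) -> "BiodistributionResults":
        """Run score -> quantile -> segment -> enrich and collect results."""
        desc = descriptor_frame(self.records) if self.records else pd.DataFrame()
        merged = self.intensities.merge(desc, on="id", how="inner")

        # isolate rows whose image is unusable (background >= 127.5) or whose
        # intensities fall outside [0, 255]; the run continues without them
        bad_bg = (merged["background"] >= scoring.MIDPOINT) | (merged["background"] < 0)
        out_of_range = np.zeros(len(merged), dtype=bool)
        for col in ("organ_intensity", "muscle_intensity"):
            out_of_range |= (merged[col] < 0) | (merged[col] > scoring.INTENSITY_MAX)
        for _, row in merged[bad_bg].iterrows():
            self.validation.add(
                row["id"], [f"{row['organ']}: degenerate background {row['background']}"]
            )
        for _, row in merged[out_of_range & ~bad_bg].iterrows():
            self.validation.add(row["id"], [f"{row['organ']}: intensity outside [0, 255]"])
        usable = merged[~(bad_bg | out_of_range)].reset_index(drop=True)

        usable["score"] = scoring.score_value(
            usable["organ_intensity"].to_numpy(),
            usable["muscle_intensity"].to_numpy(),
            usable["background"].to_numpy(),
        )
        usable["quantile"] = -1
        for organ, idx in usable.groupby("organ").groups.items():
            usable.loc[idx, "quantile"] = scoring.assign_quantiles(
                usable.loc[idx, "score"].to_numpy()
            )
        usable["high"] = usable["quantile"] >= scoring.HIGH_THRESHOLD

        usable["region"] = ""
        liver = usable["organ"] == "liver"
        kidney = usable["organ"] == "kidney"
        if liver.any():
            usable.loc[liver, "region"] = liver_regions(
                usable.loc[liver, "logd"], usable.loc[liver, "tpsa"], self.liver_scheme
            )
        if kidney.any():
            usable.loc[kidney, "region"] = kidney_regions(
                usable.loc[kidney, "logd"], self.kidney_scheme
            )
        other = ~(liver | kidney)
        usable.loc[other, "region"] = "unsegmented"

        scored = usable.rename(columns={"id": "compound_id"})
        segmented = scored[scored["region"] != "unsegmented"]
        rows = build_enrichment_table(segmented, self.strata) if len(segmented) else []
        summary = summarize_library(self.records) if self.records else {}
        return BiodistributionResults(
            model=self,
            scored=scored,
            enrichment_rows=rows,
            library_summary=summary,
            validation=self.validation,
        )


@dataclass
class BiodistributionResults:
    """Fitted pipeline output: scored table, enrichment tests, diagnostics."""

    model: BiodistributionModel
    scored: pd.DataFrame
    enrichment_rows: list[EnrichmentRow]
    library_summary: dict
    validation: ValidationReport = field(default_factory=ValidationReport)

    @property
    def enrichment(self) -> pd.DataFrame:
        return enrichment_frame(self.enrichment_rows)

    def charge_breakdown(self, organ: str, region: str, skeleton: str | None = None):
        """Per-net-charge high-scoring percentages within one (organ, region)."""
        return charge_breakdown(self.scored, organ, region, skeleton)

    def high_counts(self, organ: str) -> tuple[int, int]:
        """(high-scoring, total) compounds scored for ``organ``."""
        sub = self.scored[self.scored["organ"] == organ]
        return int(sub["high"].sum()), len(sub)

    def summary(self) -> str:
        """Human-readable report: library means, per-organ high counts,
        every enrichment stratum with its counts and probabilities."""
        lines = ["Biodistribution enrichment analysis", "=" * 60]
        if self.library_summary:
            s = self.library_summary
            lines.append(
                f"Library: n={s['n']}  mean MW={s['mean_mw']:.1f} Da  "
                f"mean logD={s['mean_logd']:.2f}  mean TPSA={s['mean_tpsa']:.1f} A^2  "
                f"mean charge={s['mean_net_charge']:+.2f}"
            )
        for organ in sorted(self.scored["organ"].unique()):
            high, total = self.high_counts(organ)
            pct = 100.0 * high / total if total else 0.0
            lines.append(f"{organ}: {high}/{total} high-scoring ({round_half_away(pct)}%)")
        lines.append("-" * 60)
        lines.append(
            f"{'stratum':<44}{'x':>5}{'y':>5}{'m':>5}{'n':>5}  {'%high':>5}  "
            f"{'p_pmf':>9}  {'p_tail':>9}"
        )
        for r in self.enrichment_rows:
            label = f"{r.organ}, {r.skeleton}, region {r.region}, {r.charge}"
            pct = f"{round_half_away(100.0 * r.m / r.n)}%" if r.n else "--"
            lines.append(
                f"{label:<44}{r.x:>5}{r.y:>5}{r.m:>5}{r.n:>5}  {pct:>5}  "
                f"{r.p_pmf:>9.3g}  {r.p_tail:>9.3g}"
            )
        lines.append(f"strata tested: {len(self.enrichment_rows)} (no multiplicity correction)")
        if not self.validation.ok:
            lines.append(f"validation: {len(self.validation.issues)} row(s) excluded")
        return "\n".join(lines)

    def save(self, out_dir) -> dict[str, Path]:
        """Write scored table, enrichment table and JSON report to a directory."""
        import json

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "scored": out / "scored.csv",
            "enrichment": out / "enrichment.csv",
            "report": out / "report.json",
            "summary": out / "summary.txt",
        }
        self.scored.to_csv(paths["scored"], index=False)
        self.enrichment.to_csv(paths["enrichment"], index=False)
        report = {
            "library_summary": self.library_summary,
            "enrichment": [vars(r) for r in self.enrichment_rows],
            "n_strata_tested": len(self.enrichment_rows),
            "validation_issues": self.validation.issues,
        }
        paths["report"].write_text(json.dumps(report, indent=2))
        paths["summary"].write_text(self.summary() + "\n")
        return paths
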