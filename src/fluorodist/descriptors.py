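"""Physicochemical descriptor tables for fluorophore libraries.

The feature table downstream stages consume holds, per compound: skeleton
class, molecular weight (Da), logD at pH 7.4, TPSA (A^2), integer net
(formal) charge, rotatable-bond count and hydrogen-bond donor/acceptor
counts.  Descriptors other than logD can be computed from a structure
string; logD is always an input column — the library's values come from a
specific commercial predictor and recomputing them with a different one
would silently shift region assignments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

from .errors import EmptyInputError, SchemaError, StructureParseError
from .scoring import IntensityMeasurement

SKELETONS = (
    "trimethine",
    "pentamethine",
    "heptamethine",
    "phenoxazine",
    "squaraine",
    "other",
)

REQUIRED_COLUMNS = ("id", "skeleton", "mw", "logd", "tpsa", "net_charge")
OPTIONAL_COLUMNS = (
    "rotatable_bonds",
    "hbond_donors",
    "hbond_acceptors",
    "smiles",
    "emission_nm",
)

CATION, ANION, NEUTRAL_OR_ZWITTERION = "cation", "anion", "neutral_or_zwitterion"


@dataclass(frozen=True)
class ChargeState:
    """Sign-based ionization category plus charge magnitude."""

    category: str
    magnitude: int


@dataclass
class FluorophoreRecord:
    """One compound: identity, skeleton class, descriptors, optional intensities."""

    id: str
    skeleton: str
    mw: float
    logd: float
    tpsa: float
    net_charge: int
    rotatable_bonds: int = 0
    hbond_donors: int = 0
    hbond_acceptors: int = 0
    smiles: str | None = None
    emission_nm: float | None = None
    intensities: dict[str, IntensityMeasurement] = field(default_factory=dict)

    def validate(self) -> list[str]:
        """Return invariant violations (empty list when valid)."""
        problems = []
        if not (self.mw > 0 and math.isfinite(self.mw)):
            problems.append(f"mw={self.mw} must be positive and finite")
        if not (self.tpsa >= 0 and math.isfinite(self.tpsa)):
            problems.append(f"tpsa={self.tpsa} must be non-negative and finite")
        if not math.isfinite(self.logd):
            problems.append(f"logd={self.logd} must be finite")
        if self.net_charge != int(self.net_charge):
            problems.append(f"net_charge={self.net_charge} must be an integer")
        for name in ("rotatable_bonds", "hbond_donors", "hbond_acceptors"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                problems.append(f"{name}={v} must be a non-negative integer")
        if self.skeleton not in SKELETONS:
            problems.append(f"skeleton={self.skeleton!r} not in {SKELETONS}")
        return problems

    @property
    def charge_state(self) -> ChargeState:
        return classify_charge(self.net_charge)

    @property
    def hbond_total(self) -> int:
        return self.hbond_donors + self.hbond_acceptors


def classify_charge(net_charge: int) -> ChargeState:
    """Cation iff net charge > 0, anion iff < 0, else neutral/zwitterion."""
    net_charge = int(net_charge)
    if net_charge > 0:
        category = CATION
    elif net_charge < 0:
        category = ANION
    else:
        category = NEUTRAL_OR_ZWITTERION
    return ChargeState(category, abs(net_charge))


@dataclass
class ValidationReport:
    """Rows that failed invariants or parsing, keyed by compound id."""

    issues: dict[str, list[str]] = field(default_factory=dict)

    def add(self, compound_id: str, problems: list[str]) -> None:
        self.issues.setdefault(str(compound_id), []).extend(problems)

    @property
    def ok(self) -> bool:
        return not self.issues

    def __str__(self) -> str:
        if self.ok:
            return "all rows valid"
        lines = [f"{len(self.issues)} invalid row(s):"]
        for cid, probs in self.issues.items():
            lines.append(f"  {cid}: {'; '.join(probs)}")
        return "\n".join(lines)


def load_descriptor_table(path) -> tuple[list[FluorophoreRecord], ValidationReport]:
    """Read a CSV/TSV descriptor table into validated records.

    Rows violating invariants (or with unparseable numerics) are collected
    into the returned :class:`ValidationReport`, never silently dropped
    from accounting.  Missing required columns raise :class:`SchemaError`.
    """
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.read_csv(path, sep=sep, dtype={"id": str})
    return records_from_frame(df)


def records_from_frame(df: pd.DataFrame) -> tuple[list[FluorophoreRecord], ValidationReport]:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(missing)
    report = ValidationReport()
    records = []
    for _, row in df.iterrows():
        cid = str(row["id"])
        try:
            rec = FluorophoreRecord(
                id=cid,
                skeleton=str(row["skeleton"]),
                mw=float(row["mw"]),
                logd=float(row["logd"]),
                tpsa=float(row["tpsa"]),
                net_charge=int(float(row["net_charge"])),
                rotatable_bonds=int(row.get("rotatable_bonds", 0) or 0),
                hbond_donors=int(row.get("hbond_donors", 0) or 0),
                hbond_acceptors=int(row.get("hbond_acceptors", 0) or 0),
                smiles=(str(row["smiles"]) if "smiles" in df.columns and pd.notna(row["smiles"]) else None),
                emission_nm=(
                    float(row["emission_nm"])
                    if "emission_nm" in df.columns and pd.notna(row["emission_nm"])
                    else None
                ),
            )
        except (TypeError, ValueError) as exc:
            report.add(cid, [f"unparseable value: {exc}"])
            continue
        problems = rec.validate()
        if problems:
            report.add(cid, problems)
        else:
            records.append(rec)
    return records, report


def descriptor_frame(records: Iterable[FluorophoreRecord]) -> pd.DataFrame:
    """Records -> descriptor DataFrame (inverse of :func:`records_from_frame`)."""
    records = list(records)
    if not records:
        raise EmptyInputError("no records")
    return pd.DataFrame(
        {
            "id": [r.id for r in records],
            "skeleton": [r.skeleton for r in records],
            "mw": [r.mw for r in records],
            "logd": [r.logd for r in records],
            "tpsa": [r.tpsa for r in records],
            "net_charge": [r.net_charge for r in records],
            "rotatable_bonds": [r.rotatable_bonds for r in records],
            "hbond_donors": [r.hbond_donors for r in records],
            "hbond_acceptors": [r.hbond_acceptors for r in records],
            "smiles": [r.smiles for r in records],
            "emission_nm": [r.emission_nm for r in records],
        }
    )


def write_descriptor_table(records: Iterable[FluorophoreRecord], path) -> None:
    path = Path(path)
    sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    descriptor_frame(records).to_csv(path, sep=sep, index=False)


LOGD_SUPPLIED_EXTERNALLY = "supplied-externally"


def compute_descriptors(smiles: str) -> dict:
    """Compute the computable descriptor subset from a structure string.

    Returns mw, tpsa, net_charge, rotatable_bonds, hbond_donors,
    hbond_acceptors; ``logd`` is ``None`` with an explicit
    ``logd_source = "supplied-externally"`` marker — it must come from the
    same predictor as the rest of the library.  The input is canonicalized
    first, so atom ordering in the string does not matter.
    """
    from rdkit import Chem
    from rdkit.Chem import Descriptors, rdMolDescriptors

    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise StructureParseError(f"cannot parse structure string {smiles!r}")
    mol = Chem.MolFromSmiles(Chem.MolToSmiles(mol))  # canonical form
    return {
        "mw": float(Descriptors.MolWt(mol)),
        "tpsa": float(rdMolDescriptors.CalcTPSA(mol)),
        "net_charge": int(Chem.GetFormalCharge(mol)),
        "rotatable_bonds": int(rdMolDescriptors.CalcNumRotatableBonds(mol)),
        "hbond_donors": int(rdMolDescriptors.CalcNumHBD(mol)),
        "hbond_acceptors": int(rdMolDescriptors.CalcNumHBA(mol)),
        "logd": None,
        "logd_source": LOGD_SUPPLIED_EXTERNALLY,
    }
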