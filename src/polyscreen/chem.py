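"""Activity-table ingestion, unit handling and dataset curation.

Compound potencies arrive as IC50 or Ki measurements in assorted
concentration units.  Everything is normalised to molar internally;
IC50 values are converted to Ki with the approximation Ki = IC50/2 and
Ki is mapped to a free-energy-scale binding affinity (BA, kcal/mol)

    BA = 1.3633 * log10(Ki[M])

so that Ki = 0.1 uM corresponds to -9.54 kcal/mol and Ki = 1 uM to
-8.18 kcal/mol, the two potency thresholds used throughout screening.

Curation keeps measurements on a single protein target from one
organism (human by default), aggregates replicate measurements of the
same molecule, and accepts a dataset only when at least ``min_size``
compounds survive, so that downstream regressors have enough training
signal.
"""

from __future__ import annotations

import csv
import json
import logging
import math
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from rdkit import Chem, RDLogger

logger = logging.getLogger(__name__)

# slope of the Ki -> binding-affinity map, kcal/mol per log10 unit
BA_PER_LOG10_KI = 1.3633

#: accepted concentration unit strings and their value in molar
UNIT_TO_MOLAR: dict[str, float] = {
    "nM": 1e-9,
    "uM": 1e-6,
    "μM": 1e-6,  # Greek mu
    "µM": 1e-6,  # micro sign
    "M": 1.0,
}


class ActivityType(str, Enum):
    IC50 = "IC50"
    KI = "Ki"


class DomainError(ValueError):
    """Raised when a quantity violates its physical domain (e.g. Ki <= 0)."""


class UsageError(ValueError):
    """Raised on API misuse such as mixed target ids in one curation call."""


class ConfigurationError(ValueError):
    """Raised for malformed dialects, missing columns or bad config files."""


@dataclass(frozen=True)
class ActivityRecord:
    """One compound-target potency measurement, value in molar."""

    compound_id: str
    smiles: str
    activity_type: ActivityType
    activity_value: float
    organism: str
    target_id: str
    target_is_single_protein: bool = True

    def __post_init__(self) -> None:
        if not self.smiles:
            raise ValueError("smiles must be nonempty")
        if not (self.activity_value > 0 and math.isfinite(self.activity_value)):
            raise ValueError(f"activity_value must be positive and finite, got {self.activity_value}")
        if not isinstance(self.activity_type, ActivityType):
            object.__setattr__(self, "activity_type", ActivityType(self.activity_type))

    def ki_molar(self) -> float:
        """Ki-equivalent value in molar (IC50 rows are halved)."""
        if self.activity_type is ActivityType.IC50:
            return ic50_to_ki(self.activity_value)
        return self.activity_value


@dataclass(frozen=True)
class CurationCriteria:
    """Dataset acceptance rules: organism, target type, minimum size."""

    min_size: int = 250
    required_organism: str = "Homo sapiens"
    require_single_protein: bool = True

    def __post_init__(self) -> None:
        if self.min_size < 1:
            raise ValueError("min_size must be >= 1")


@dataclass
class CuratedDataset:
    """BA-labelled compound set for one target, in deterministic order."""

    target_id: str
    compound_ids: list[str]
    smiles: list[str]
    ba: np.ndarray  # kcal/mol

    def __post_init__(self) -> None:
        self.ba = np.asarray(self.ba, dtype=float)
        if not (len(self.compound_ids) == len(self.smiles) == len(self.ba)):
            raise ValueError("parallel record arrays must have equal length")
        if self.ba.size and not np.all(np.isfinite(self.ba)):
            raise ValueError("all BA labels must be finite")

    @property
    def n(self) -> int:
        return len(self.compound_ids)

    def records(self) -> Iterable[tuple[str, str, float]]:
        return zip(self.compound_ids, self.smiles, self.ba.tolist())

    def to_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["compound_id", "canonical_smiles", "ba_kcal_mol"])
            for cid, smi, ba in self.records():
                writer.writerow([cid, smi, repr(ba)])

    @classmethod
    def from_csv(cls, path: str | Path, target_id: str | None = None) -> "CuratedDataset":
        cids, smis, bas = [], [], []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                cids.append(row["compound_id"])
                smis.append(row["canonical_smiles"])
                bas.append(float(row["ba_kcal_mol"]))
        return cls(target_id or Path(path).stem, cids, smis, np.array(bas))


@dataclass(frozen=True)
class CurationRejection:
    """Outcome of curation when a dataset fails an acceptance rule."""

    target_id: str
    rule: str
    detail: str = ""

    def __bool__(self) -> bool:  # rejections are falsy, datasets truthy
        return False


# ---------------------------------------------------------------------------
# potency conversions


def ic50_to_ki(ic50: float) -> float:
    """Approximate Ki (molar) from IC50 (molar) as IC50/2."""
    if not ic50 > 0:
        raise DomainError(f"IC50 must be positive, got {ic50}")
    return ic50 / 2.0


def ki_to_ba(ki: float) -> float:
    """Binding affinity in kcal/mol from Ki in molar: 1.3633 * log10(Ki)."""
    if not ki > 0:
        raise DomainError(f"Ki must be positive, got {ki}")
    return BA_PER_LOG10_KI * math.log10(ki)


def ba_to_ki(ba: float) -> float:
    """Inverse of :func:`ki_to_ba`: Ki in molar from BA in kcal/mol."""
    return 10.0 ** (ba / BA_PER_LOG10_KI)


# ---------------------------------------------------------------------------
# parsing


DEFAULT_DIALECT: dict[str, str] = {
    "compound_id": "compound_id",
    "smiles": "smiles",
    "activity_type": "activity_type",
    "activity_value": "activity_value",
    "units": "units",
    "organism": "organism",
    "target_id": "target_id",
    "single_protein": "single_protein",
}

_TRUTHY = {"1", "true", "yes", "y", "single", "single protein"}


@dataclass
class ParseResult:
    """Parsed records plus per-reason drop counts."""

    records: list[ActivityRecord]
    dropped: Counter = field(default_factory=Counter)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def parse_activity_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> ParseResult:
    """Read a CSV/TSV activity table into :class:`ActivityRecord` rows.

    ``dialect`` maps the canonical field names of :data:`DEFAULT_DIALECT`
    to the column headers actually present in the file.  Unit strings are
    normalised to molar; rows with a missing or unparsable value, unknown
    unit, nonpositive value or empty SMILES are dropped and counted in
    the result's ``dropped`` counter.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    colmap = dict(DEFAULT_DIALECT)
    if dialect:
        unknown = set(dialect) - set(DEFAULT_DIALECT)
        if unknown:
            raise ConfigurationError(f"unknown dialect keys: {sorted(unknown)}")
        colmap.update(dialect)

    sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
    result = ParseResult(records=[])
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter=sep)
        if reader.fieldnames is None:
            logger.warning("empty activity table %s", path)
            return result
        missing = [c for c in colmap.values() if c not in reader.fieldnames]
        if missing:
            raise ConfigurationError(f"missing required columns in {path}: {missing}")
        for row in reader:
            rec = _parse_row(row, colmap, result.dropped)
            if rec is not None:
                result.records.append(rec)
    if not result.records:
        logger.warning("no parsable rows in %s", path)
    return result


def _parse_row(row: Mapping[str, str], colmap: Mapping[str, str], dropped: Counter) -> ActivityRecord | None:
    smiles = (row.get(colmap["smiles"]) or "").strip()
    if not smiles:
        dropped["missing_smiles"] += 1
        return None
    raw_value = (row.get(colmap["activity_value"]) or "").strip()
    try:
        value = float(raw_value)
    except ValueError:
        dropped["unparsable_value"] += 1
        return None
    if not (value > 0 and math.isfinite(value)):
        dropped["nonpositive_value"] += 1
        return None
    unit = (row.get(colmap["units"]) or "").strip()
    if unit not in UNIT_TO_MOLAR:
        dropped["unknown_unit"] += 1
        return None
    atype_raw = (row.get(colmap["activity_type"]) or "").strip()
    try:
        atype = ActivityType(atype_raw if atype_raw != "KI" else "Ki")
    except ValueError:
        dropped["unknown_activity_type"] += 1
        return None
    return ActivityRecord(
        compound_id=(row.get(colmap["compound_id"]) or "").strip(),
        smiles=smiles,
        activity_type=atype,
        activity_value=value * UNIT_TO_MOLAR[unit],
        organism=(row.get(colmap["organism"]) or "").strip(),
        target_id=(row.get(colmap["target_id"]) or "").strip(),
        target_is_single_protein=(row.get(colmap["single_protein"]) or "").strip().lower() in _TRUTHY,
    )


# ---------------------------------------------------------------------------
# standardisation and curation


def canonical_smiles(smiles: str) -> str | None:
    """RDKit canonical SMILES, or None when the string does not parse."""
    RDLogger.DisableLog("rdApp.error")
    try:
        mol = Chem.MolFromSmiles(smiles)
    finally:
        RDLogger.EnableLog("rdApp.error")
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def standardize_records(records: Sequence[ActivityRecord]) -> list[ActivityRecord]:
    """Canonicalise SMILES and merge replicate measurements.

    Records sharing the same (canonical SMILES, target) are merged into a
    single Ki record whose value is the geometric mean of the individual
    Ki-equivalents — the natural average for log-scaled potencies.  The
    merged record keeps the lexicographically smallest compound_id of the
    group.  Records whose SMILES cannot be canonicalised are dropped with
    a warning.  Output order is deterministic: sorted by canonical SMILES
    then compound_id.  The operation is idempotent.
    """
    groups: dict[tuple[str, str], list[tuple[str, ActivityRecord]]] = {}
    for rec in records:
        canon = canonical_smiles(rec.smiles)
        if canon is None or canon == "":
            logger.warning("dropping uncanonizable SMILES %r (%s)", rec.smiles, rec.compound_id)
            continue
        groups.setdefault((canon, rec.target_id), []).append((canon, rec))

    merged: list[ActivityRecord] = []
    for (canon, target_id), members in groups.items():
        kis = np.array([rec.ki_molar() for _, rec in members])
        gmean_ki = float(np.exp(np.mean(np.log(kis))))
        first = min(members, key=lambda cr: cr[1].compound_id)[1]
        merged.append(
            ActivityRecord(
                compound_id=first.compound_id,
                smiles=canon,
                activity_type=ActivityType.KI,
                activity_value=gmean_ki,
                organism=first.organism,
                target_id=target_id,
                target_is_single_protein=first.target_is_single_protein,
            )
        )
    merged.sort(key=lambda r: (r.smiles, r.compound_id))
    return merged


def curate_dataset(
    records: Sequence[ActivityRecord],
    criteria: CurationCriteria = CurationCriteria(),
) -> CuratedDataset | CurationRejection:
    """Apply organism / single-protein / size rules and label with BA.

    ``records`` must be standardised and all refer to the same target.
    Returns a :class:`CuratedDataset` when at least ``criteria.min_size``
    records survive the filters, otherwise a :class:`CurationRejection`
    naming the failed rule.
    """
    target_ids = {r.target_id for r in records}
    if len(target_ids) > 1:
        raise UsageError(f"curate_dataset expects one target, got {sorted(target_ids)}")
    target_id = next(iter(target_ids)) if target_ids else ""

    surviving = [
        r
        for r in records
        if r.organism == criteria.required_organism
        and (r.target_is_single_protein or not criteria.require_single_protein)
    ]
    if len(surviving) < criteria.min_size:
        return CurationRejection(
            target_id,
            "min_size",
            f"{len(surviving)} qualifying records < min_size {criteria.min_size}",
        )
    surviving.sort(key=lambda r: (canonical_smiles(r.smiles) or r.smiles, r.compound_id))
    return CuratedDataset(
        target_id=target_id,
        compound_ids=[r.compound_id for r in surviving],
        smiles=[r.smiles for r in surviving],
        ba=np.array([ki_to_ba(r.ki_molar()) for r in surviving]),
    )


def write_curation_report(path: str | Path, parse: ParseResult, outcome) -> None:
    """JSON report of drop counts and the curation outcome."""
    payload: dict = {
        "n_parsed": len(parse.records),
        "dropped": dict(parse.dropped),
    }
    if isinstance(outcome, CuratedDataset):
        payload["accepted"] = True
        payload["target_id"] = outcome.target_id
        payload["n_curated"] = outcome.n
    else:
        payload["accepted"] = False
        payload["target_id"] = outcome.target_id
        payload["failed_rule"] = outcome.rule
        payload["detail"] = outcome.detail
    Path(path).write_text(json.dumps(payload, indent=2))
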