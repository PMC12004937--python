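"""Rule-based ADMET and synthetic-accessibility range screening.

Property profiles (toxicity, half-life, bioavailability, lipophilicity,
solubility, permeability, plus a synthetic accessibility score) are
*consumed* from files produced by external predictors; this module only
applies optimal-range rules to them.  Shipped defaults cover the
lipophilicity windows logP in [0, 3] and logD in [1, 3]; every other
interval is user-supplied configuration, and properties without a
configured range are skipped with a warning rather than silently
passed.

Interval boundaries are inclusive by default, matching the closed
"0-3"-style ranges such tables print.  SAS runs from 1 (easy to make)
to 10 (hard); the default cutoff of 6 is a deliberately loose filter.
"""

from __future__ import annotations

import csv
import json
import logging
import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import math

import yaml

logger = logging.getLogger(__name__)

#: screened properties, in the fixed order used for attrition attribution
PROPERTY_ORDER = ("FDAMDD", "T_half", "F_20", "logP", "logS", "logD", "Caco2")

SAS_PROPERTY = "SAS"
DEFAULT_SAS_MAX = 6.0


class RangeConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ADMETProfile:
    """Property values for one compound; absent keys mean 'not measured'."""

    compound_id: str
    properties: Mapping[str, float]

    def __post_init__(self) -> None:
        for name, value in self.properties.items():
            if value is None or not math.isfinite(value):
                raise ValueError(f"{self.compound_id}: property {name} must be finite when present")
        sas = self.properties.get(SAS_PROPERTY)
        if sas is not None and not 1.0 <= sas <= 10.0:
            raise ValueError(f"{self.compound_id}: SAS {sas} outside [1, 10]")


@dataclass(frozen=True)
class PropertyRange:
    lo: float
    hi: float
    lo_inclusive: bool = True
    hi_inclusive: bool = True

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise RangeConfigError(f"lower bound {self.lo} exceeds upper bound {self.hi}")

    def contains(self, value: float) -> bool:
        above = value >= self.lo if self.lo_inclusive else value > self.lo
        below = value <= self.hi if self.hi_inclusive else value < self.hi
        return above and below


@dataclass
class RangeTable:
    """Optimal-range intervals per property."""

    intervals: dict[str, PropertyRange]
    provenance: str = "defaults"

    def screened(self) -> list[str]:
        return [p for p in PROPERTY_ORDER if p in self.intervals]


def default_ranges() -> RangeTable:
    return RangeTable(
        intervals={
            "logP": PropertyRange(0.0, 3.0),
            "logD": PropertyRange(1.0, 3.0),
        },
        provenance="shipped defaults (lipophilicity windows)",
    )


def load_ranges(path: str | Path | None = None) -> RangeTable:
    """Load a YAML/JSON range table, merged over the shipped defaults.

    The file maps property names to ``[lo, hi]`` pairs or to mappings
    with ``lo``/``hi`` and optional ``lo_inclusive``/``hi_inclusive``
    flags.  Properties with no configured interval are reported in a
    warning and skipped during evaluation.
    """
    table = default_ranges()
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise RangeConfigError("range config must be a mapping of property -> interval")
        for name, spec in raw.items():
            if isinstance(spec, (list, tuple)):
                if len(spec) != 2:
                    raise RangeConfigError(f"{name}: interval must be [lo, hi]")
                interval = PropertyRange(float(spec[0]), float(spec[1]))
            elif isinstance(spec, dict):
                interval = PropertyRange(
                    float(spec["lo"]),
                    float(spec["hi"]),
                    bool(spec.get("lo_inclusive", True)),
                    bool(spec.get("hi_inclusive", True)),
                )
            else:
                raise RangeConfigError(f"{name}: unsupported interval spec {spec!r}")
            table.intervals[name] = interval
        table.provenance = str(path)
    unscreened = [p for p in PROPERTY_ORDER if p not in table.intervals]
    if unscreened:
        warnings.warn(
            f"no optimal range configured for {unscreened}; these properties are not screened",
            stacklevel=2,
        )
    return table


@dataclass
class ProfileEvaluation:
    compound_id: str
    per_property: dict[str, tuple[bool, str]]  # property -> (passed, reason)
    overall: bool


def evaluate_profile(profile: ADMETProfile, ranges: RangeTable) -> ProfileEvaluation:
    """Check each configured range; overall is the conjunction.

    A property configured in the range table but absent from the
    profile fails with reason ``missing``.
    """
    per_property: dict[str, tuple[bool, str]] = {}
    for name in ranges.intervals:
        if name == SAS_PROPERTY:
            continue  # SAS is screened by its own cutoff, not an interval
        interval = ranges.intervals[name]
        value = profile.properties.get(name)
        if value is None:
            per_property[name] = (False, "missing")
        elif interval.contains(value):
            per_property[name] = (True, "in range")
        else:
            per_property[name] = (False, f"{value} outside [{interval.lo}, {interval.hi}]")
    overall = all(ok for ok, _ in per_property.values())
    return ProfileEvaluation(profile.compound_id, per_property, overall)


@dataclass
class FilterResult:
    survivors: list[str]
    attrition: Counter  # first-failing rule -> count
    evaluations: dict[str, ProfileEvaluation]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {"survivors": self.survivors, "attrition": dict(self.attrition)},
                indent=2,
            )
        )


def filter_compounds(
    profiles: Sequence[ADMETProfile],
    ranges: RangeTable,
    sas_max: float = DEFAULT_SAS_MAX,
) -> FilterResult:
    """Apply all range rules plus the SAS cutoff to a profile list.

    Survivors pass every configured interval and have SAS <= sas_max.
    Attrition counts attribute each failing compound to its *first*
    failing rule in the fixed property order (SAS last); the full
    per-property evaluation is retained alongside.  Output order
    follows input order.
    """
    seen: set[str] = set()
    survivors: list[str] = []
    attrition: Counter = Counter()
    evaluations: dict[str, ProfileEvaluation] = {}
    screened = [p for p in PROPERTY_ORDER if p in ranges.intervals] + [
        p for p in ranges.intervals if p not in PROPERTY_ORDER and p != SAS_PROPERTY
    ]
    for profile in profiles:
        if profile.compound_id in seen:
            raise ValueError(f"duplicate compound_id {profile.compound_id}")
        seen.add(profile.compound_id)
        evaluation = evaluate_profile(profile, ranges)
        evaluations[profile.compound_id] = evaluation

        first_fail = next((p for p in screened if not evaluation.per_property[p][0]), None)
        sas = profile.properties.get(SAS_PROPERTY)
        sas_ok = sas is not None and sas <= sas_max
        if first_fail is not None:
            attrition[first_fail] += 1
        elif not sas_ok:
            attrition[SAS_PROPERTY] += 1
        else:
            survivors.append(profile.compound_id)
    return FilterResult(survivors=survivors, attrition=attrition, evaluations=evaluations)


def read_profiles_csv(path: str | Path) -> list[ADMETProfile]:
    """Read profiles from CSV with header compound_id,FDAMDD,...,SAS.

    Empty cells become missing values.
    """
    profiles: list[ADMETProfile] = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            cid = row.pop("compound_id")
            props = {k: float(v) for k, v in row.items() if v not in (None, "")}
            profiles.append(ADMETProfile(compound_id=cid, properties=props))
    return profiles


def write_profiles_csv(profiles: Sequence[ADMETProfile], path: str | Path) -> None:
    columns = list(PROPERTY_ORDER) + [SAS_PROPERTY]
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["compound_id", *columns])
        for p in profiles:
            writer.writerow([p.compound_id] + [p.properties.get(c, "") for c in columns])
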