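"""Cross-target matrix construction and screening logic.

The central artifact is the all-against-all cross-target matrix: for
every (inhibitor dataset i, target model j) pair, model j predicts the
binding affinity of every compound in dataset i, and the off-diagonal
cell stores the strongest predicted affinity (the maximum absolute BA,
i.e. the most negative kcal/mol value).  Diagonal cells store the
model's own cross-validation Pearson R.  An off-diagonal cell stronger
(more negative) than the side-effect threshold (-9.54 kcal/mol,
Ki = 0.1 uM) marks a potential side-effect interaction; hERG, the
cardiac anti-target, carries its own stricter bound (-8.18 kcal/mol,
Ki = 1 uM).

On top of the matrix sit the screening rules: side-effect
classification, drug-repurposing search (compounds weak on their
origin target but predicted potent on the therapeutic target and
clean everywhere else), and lead reports combining potency,
off-target, hERG, ADMET-range and synthetic-accessibility flags.
All threshold comparisons are strict, and equality with a threshold
counts as the safe side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .admet import ADMETProfile, RangeTable, evaluate_profile
from .chem import CuratedDataset
from .models import ConsensusModel, pearson_r

logger = logging.getLogger(__name__)

HERG_TARGET_ID = "hERG"


class ScreeningConfigError(ValueError):
    pass


@dataclass(frozen=True)
class ScreeningThresholds:
    """Potency / side-effect / hERG cutoffs in kcal/mol (strict comparisons)."""

    side_effect_ba: float = -9.54
    herg_ba: float = -8.18
    potency_ba: float = -9.54

    def __post_init__(self) -> None:
        for name in ("side_effect_ba", "herg_ba", "potency_ba"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")


@dataclass
class CrossTargetMatrix:
    """Cross-prediction grid: CV R on the diagonal, max-|BA| off it.

    ``predictions[(dataset_id, model_id)]`` retains the per-compound
    prediction vector behind each cell for drill-down.
    """

    dataset_ids: list[str]
    model_ids: list[str]
    values: np.ndarray  # (n_datasets, n_models)
    predictions: dict[tuple[str, str], np.ndarray] = field(default_factory=dict)
    argmax_compound: dict[tuple[str, str], str] = field(default_factory=dict)

    @property
    def grid_size(self) -> int:
        return len(self.dataset_ids) * len(self.model_ids)

    def entry(self, dataset_id: str, model_id: str) -> float:
        i = self.dataset_ids.index(dataset_id)
        j = self.model_ids.index(model_id)
        return float(self.values[i, j])

    def offdiag_mask(self) -> np.ndarray:
        rows = np.array(self.dataset_ids)[:, None]
        cols = np.array(self.model_ids)[None, :]
        return rows != cols

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.dataset_ids, columns=self.model_ids)

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="dataset")


def cross_grid_cells(n_datasets: int, n_models: int) -> int:
    """Total number of cross-prediction cells in the full grid."""
    if n_datasets < 0 or n_models < 0:
        raise ValueError("grid dimensions must be nonnegative")
    return n_datasets * n_models


def grid_partition(n_datasets: int, n_models: int, n_flagged: int) -> tuple[int, int]:
    """Partition the full grid count into flagged and remaining cells.

    Returns ``(total_cells, total_cells - n_flagged)``; the remainder
    covers the unflagged off-diagonal cells together with the diagonal
    (which stores CV R rather than an affinity).
    """
    total = cross_grid_cells(n_datasets, n_models)
    if not 0 <= n_flagged <= total:
        raise ValueError(f"n_flagged must lie in [0, {total}], got {n_flagged}")
    return total, total - n_flagged


def build_cross_matrix(
    models: Sequence[ConsensusModel],
    datasets: Sequence[CuratedDataset],
) -> CrossTargetMatrix:
    """Predict every model on every dataset and assemble the grid.

    Off-diagonal cell (i, j): the prediction of model j over the
    compounds of dataset i with maximum absolute value (ties broken by
    the first occurrence in the dataset's deterministic order).
    Diagonal cell (i, i): model i's cross-validation Pearson R.
    """
    model_by_id: dict[str, ConsensusModel] = {}
    for m in models:
        if m.target_id in model_by_id:
            raise ScreeningConfigError(f"duplicate model for target {m.target_id}")
        model_by_id[m.target_id] = m
    dataset_ids = [d.target_id for d in datasets]
    model_ids = list(model_by_id)
    values = np.full((len(datasets), len(model_ids)), np.nan)
    matrix = CrossTargetMatrix(dataset_ids, model_ids, values)

    for j, mid in enumerate(model_ids):
        model = model_by_id[mid]
        if not model.members:
            raise ScreeningConfigError(f"model {mid} is not fitted")
        for i, dataset in enumerate(datasets):
            if dataset.target_id == mid:
                if model.cv_report is None:
                    raise ScreeningConfigError(f"model {mid} lacks a CV report for the diagonal")
                values[i, j] = model.cv_report.pearson_r
                continue
            preds = model.predict(dataset.smiles, dataset.compound_ids)
            matrix.predictions[(dataset.target_id, mid)] = preds
            finite = np.where(np.isfinite(preds))[0]
            if finite.size == 0:
                raise ScreeningConfigError(f"model {mid} produced no finite prediction on {dataset.target_id}")
            best = finite[np.argmax(np.abs(preds[finite]))]
            values[i, j] = preds[best]
            matrix.argmax_compound[(dataset.target_id, mid)] = dataset.compound_ids[best]
    return matrix


@dataclass
class SideEffectSummary:
    """Strict-threshold classification of the cross-target grid."""

    flags: pd.DataFrame  # boolean, dataset rows x model columns; diagonal False
    n_flagged: int
    n_unflagged: int  # remaining cells of the full grid, diagonal included
    grid_size: int
    threshold: float


def classify_side_effects(
    matrix: CrossTargetMatrix,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> SideEffectSummary:
    """Flag off-diagonal cells with predicted BA below the threshold.

    A cell is a potential side-effect interaction iff its max-|BA|
    entry is strictly less than ``thresholds.side_effect_ba``.  The
    flagged and unflagged counts partition the *full* grid (diagonal
    cells included among the unflagged), matching the bookkeeping used
    when a whole dataset-by-model grid is reported.
    """
    off = matrix.offdiag_mask()
    flagged = off & (matrix.values < thresholds.side_effect_ba)
    n_flagged = int(flagged.sum())
    return SideEffectSummary(
        flags=pd.DataFrame(flagged, index=matrix.dataset_ids, columns=matrix.model_ids),
        n_flagged=n_flagged,
        n_unflagged=matrix.grid_size - n_flagged,
        grid_size=matrix.grid_size,
        threshold=thresholds.side_effect_ba,
    )


@dataclass
class ScreenCandidate:
    """A compound entering lead screening with its prediction profile."""

    compound_id: str
    smiles: str
    origin_dataset: str
    therapeutic_ba: float  # potency evidence on the therapeutic target, kcal/mol
    predictions: dict[str, float]  # target_id -> predicted BA
    experimental_ba: float | None = None  # on the origin dataset's target


def _predict_profiles(
    dataset: CuratedDataset,
    models: Sequence[ConsensusModel],
) -> dict[str, np.ndarray]:
    return {m.target_id: m.predict(dataset.smiles, dataset.compound_ids) for m in models}


def find_repurposing(
    datasets: Sequence[CuratedDataset],
    models: Sequence[ConsensusModel],
    therapeutic_target: str,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    herg_target: str = HERG_TARGET_ID,
) -> list[ScreenCandidate]:
    """Search non-therapeutic datasets for repurposing candidates.

    A compound from an origin dataset qualifies iff (a) its
    experimental BA on the origin target is weaker than the potency
    threshold, (b) its predicted BA on the therapeutic target is
    stronger than the potency threshold, (c) its predicted BA on every
    other modeled target is weaker than the side-effect threshold, and
    (d) its predicted hERG BA is weaker than the hERG threshold.
    """
    model_ids = {m.target_id for m in models}
    if therapeutic_target not in model_ids:
        raise ScreeningConfigError(f"no model for therapeutic target {therapeutic_target}")
    if herg_target not in model_ids:
        raise ScreeningConfigError(f"no model for hERG anti-target {herg_target!r}")

    candidates: list[ScreenCandidate] = []
    for dataset in datasets:
        if dataset.target_id in (therapeutic_target,):
            continue
        profiles = _predict_profiles(dataset, models)
        for idx, (cid, smi, exp_ba) in enumerate(dataset.records()):
            if not exp_ba > thresholds.potency_ba:  # (a) weak on origin
                continue
            preds = {tid: float(vec[idx]) for tid, vec in profiles.items()}
            if not np.all(np.isfinite(list(preds.values()))):
                continue
            if not preds[therapeutic_target] < thresholds.potency_ba:  # (b)
                continue
            off_targets = [
                tid for tid in preds if tid not in (therapeutic_target, herg_target)
            ]
            if not all(preds[tid] > thresholds.side_effect_ba for tid in off_targets):  # (c)
                continue
            if not preds[herg_target] > thresholds.herg_ba:  # (d)
                continue
            candidates.append(
                ScreenCandidate(
                    compound_id=cid,
                    smiles=smi,
                    origin_dataset=dataset.target_id,
                    therapeutic_ba=preds[therapeutic_target],
                    predictions=preds,
                    experimental_ba=float(exp_ba),
                )
            )
    return candidates


def potent_inhibitors(
    dataset: CuratedDataset,
    models: Sequence[ConsensusModel],
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> list[ScreenCandidate]:
    """Candidates from the therapeutic dataset itself.

    Selects compounds whose *experimental* BA on the therapeutic target
    is stronger than the potency threshold and attaches predicted BA
    profiles over all models for downstream screening.
    """
    profiles = _predict_profiles(dataset, models)
    out = []
    for idx, (cid, smi, exp_ba) in enumerate(dataset.records()):
        if not exp_ba < thresholds.potency_ba:
            continue
        preds = {tid: float(vec[idx]) for tid, vec in profiles.items()}
        out.append(
            ScreenCandidate(
                compound_id=cid,
                smiles=smi,
                origin_dataset=dataset.target_id,
                therapeutic_ba=float(exp_ba),
                predictions=preds,
                experimental_ba=float(exp_ba),
            )
        )
    return out


@dataclass
class LeadReport:
    """Per-compound screening verdict with one flag per rule family."""

    compound_id: str
    origin_dataset: str
    predicted_ba_per_target: dict[str, float]
    flags: dict[str, bool]
    failed_rules: list[str]
    verdict: bool

    def __post_init__(self) -> None:
        assert self.verdict == all(self.flags.values())


FLAG_NAMES = ("potent_on_therapeutic", "herg_safe", "off_target_clean", "admet_pass", "sas_pass")


def screen_leads(
    candidates: Sequence[ScreenCandidate],
    therapeutic_target: str,
    profiles: Mapping[str, ADMETProfile],
    ranges: RangeTable,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
    sas_max: float = 6.0,
    herg_target: str = HERG_TARGET_ID,
) -> list[LeadReport]:
    """Combine potency, off-target, hERG, ADMET and SAS rules per compound.

    The verdict is the conjunction of the five flags; every failed rule
    is listed.  Candidates without an ADMET profile fail the ADMET flag
    with reason ``admet:missing``.
    """
    reports: list[LeadReport] = []
    for cand in candidates:
        failed: list[str] = []
        flags: dict[str, bool] = {}

        flags["potent_on_therapeutic"] = cand.therapeutic_ba < thresholds.potency_ba
        if not flags["potent_on_therapeutic"]:
            failed.append(f"potency:ba {cand.therapeutic_ba:.2f} not < {thresholds.potency_ba}")

        herg_pred = cand.predictions.get(herg_target, np.nan)
        flags["herg_safe"] = bool(np.isfinite(herg_pred) and herg_pred > thresholds.herg_ba)
        if not flags["herg_safe"]:
            failed.append(f"herg:ba {herg_pred:.2f} not > {thresholds.herg_ba}")

        off_bad = [
            tid
            for tid, ba in cand.predictions.items()
            if tid not in (therapeutic_target, herg_target)
            and not ba > thresholds.side_effect_ba
        ]
        flags["off_target_clean"] = not off_bad
        if off_bad:
            failed.append("off_target:" + ",".join(sorted(off_bad)))

        profile = profiles.get(cand.compound_id)
        if profile is None:
            flags["admet_pass"] = False
            failed.append("admet:missing")
            flags["sas_pass"] = False
            failed.append("sas:missing")
        else:
            evaluation = evaluate_profile(profile, ranges)
            flags["admet_pass"] = evaluation.overall
            if not evaluation.overall:
                failed.extend(f"admet:{p}" for p, (ok, _) in evaluation.per_property.items() if not ok)
            sas = profile.properties.get("SAS")
            flags["sas_pass"] = sas is not None and sas <= sas_max
            if not flags["sas_pass"]:
                failed.append("sas:missing" if sas is None else f"sas:{sas:.2f} > {sas_max}")

        reports.append(
            LeadReport(
                compound_id=cand.compound_id,
                origin_dataset=cand.origin_dataset,
                predicted_ba_per_target=dict(cand.predictions),
                flags=flags,
                failed_rules=failed,
                verdict=all(flags.values()),
            )
        )
    return reports


def prediction_correlation(
    dataset: CuratedDataset,
    model_a: ConsensusModel,
    model_b: ConsensusModel,
) -> float:
    """Pearson R between two models' predictions over one compound set.

    A high correlation suggests the two targets present similar binding
    environments to this chemistry (a similarity *hypothesis*, not a
    structural claim).
    """
    if dataset.n == 0:
        raise ScreeningConfigError("prediction_correlation needs a nonempty dataset")
    a = model_a.predict(dataset.smiles, dataset.compound_ids)
    b = model_b.predict(dataset.smiles, dataset.compound_ids)
    finite = np.isfinite(a) & np.isfinite(b)
    return pearson_r(a[finite], b[finite])
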