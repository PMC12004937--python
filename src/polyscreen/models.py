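"""Per-target consensus binding-affinity regressors.

For each curated target dataset, one regressor is trained per
(fingerprint provider, random seed) pair; the consensus prediction is
the mean over seeds within a provider, then the mean across providers.
The default configuration mirrors common QSAR practice: an RBF-kernel
support-vector regressor (C=10, epsilon=0.1, gamma=1/n_features), two
fingerprint providers and ten seed replicates.  Gradient-boosted trees
and random forests are available through the same spec.

Model quality is summarised by 10-fold cross-validation: out-of-fold
predictions are pooled over the whole dataset and scored with the
Pearson correlation coefficient R and the root-mean-square deviation
(RMSD, kcal/mol).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.model_selection import KFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from .chem import CuratedDataset
from .embeddings import FingerprintProvider, embed_dataset

logger = logging.getLogger(__name__)

ALGORITHMS = ("svm", "gbdt", "rf")

# SVR ignores the random seed entirely; tree ensembles do not.
_SEED_SENSITIVE = {"svm": False, "gbdt": True, "rf": True}


class ValidationError(ValueError):
    pass


@dataclass(frozen=True)
class RegressorSpec:
    """Algorithm choice, hyperparameter overrides, and base seed."""

    algorithm: str = "svm"
    hyperparameters: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.algorithm not in ALGORITHMS:
            raise ValueError(f"algorithm must be one of {ALGORITHMS}, got {self.algorithm!r}")


@dataclass
class CVReport:
    """Pooled out-of-fold cross-validation summary."""

    pearson_r: float
    rmsd: float  # kcal/mol
    k: int = 10
    split_seed: int = 0
    fold_assignments: np.ndarray | None = None
    pooled_predictions: np.ndarray | None = None  # out-of-fold, dataset order
    observed: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError(f"Pearson R out of range: {self.pearson_r}")
        if self.rmsd < 0:
            raise ValueError("RMSD must be nonnegative")


def pearson_r(x: Sequence[float], y: Sequence[float]) -> float:
    """Product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("pearson_r expects two equal-length 1-D vectors")
    if x.size < 2:
        raise ValidationError("pearson_r needs at least two observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc * xc).sum() * (yc * yc).sum())
    if denom == 0:
        raise ValidationError("undefined correlation: zero variance input")
    return float(np.clip((xc * yc).sum() / denom, -1.0, 1.0))


def rmsd(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Root-mean-square deviation between predictions and observations."""
    pred = np.asarray(pred, dtype=float)
    obs = np.asarray(obs, dtype=float)
    if pred.shape != obs.shape or pred.ndim != 1 or pred.size < 1:
        raise ValidationError("rmsd expects two equal-length nonempty 1-D vectors")
    return float(np.sqrt(np.mean((pred - obs) ** 2)))


def _make_estimator(spec: RegressorSpec, n_features: int, seed: int):
    params = dict(spec.hyperparameters)
    if spec.algorithm == "svm":
        defaults = {"kernel": "rbf", "C": 10.0, "epsilon": 0.1, "gamma": 1.0 / max(n_features, 1)}
        defaults.update(params)
        # features are standardized first so that gamma = 1/n_features is a
        # sensible kernel width regardless of the provider's raw scaling
        return make_pipeline(StandardScaler(), SVR(**defaults))
    if spec.algorithm == "gbdt":
        return GradientBoostingRegressor(random_state=seed, **params)
    return RandomForestRegressor(random_state=seed, **params)


def train_member(features: np.ndarray, ba: np.ndarray, spec: RegressorSpec):
    """Fit a single member regressor; reproducible given ``spec.seed``."""
    features = np.asarray(features, dtype=float)
    ba = np.asarray(ba, dtype=float)
    if features.ndim != 2 or features.shape[0] != ba.shape[0]:
        raise ValidationError("features must be (n, d) aligned with ba")
    if not (np.all(np.isfinite(features)) and np.all(np.isfinite(ba))):
        raise ValidationError("non-finite values in training data")
    est = _make_estimator(spec, features.shape[1], spec.seed)
    est.fit(features, ba)
    return est


def _fit_members(features: np.ndarray, ba: np.ndarray, spec: RegressorSpec, n_seeds: int) -> list:
    """Fit ``n_seeds`` members with seeds spec.seed+0..n_seeds-1.

    Seed-insensitive algorithms (SVM) yield bit-identical members, so a
    single fit is shared across the member slots.
    """
    if not _SEED_SENSITIVE[spec.algorithm]:
        est = train_member(features, ba, spec)
        return [est] * n_seeds
    members = []
    for i in range(n_seeds):
        member_spec = RegressorSpec(spec.algorithm, spec.hyperparameters, spec.seed + i)
        members.append(train_member(features, ba, member_spec))
    return members


@dataclass
class ConsensusModel:
    """Averaged multi-provider, multi-seed regressor for one target."""

    target_id: str
    providers: list[FingerprintProvider]
    members: dict[str, list]  # provider_id -> fitted estimators, one per seed
    spec: RegressorSpec
    n_seeds: int
    excluded: list[tuple[str, str]] = field(default_factory=list)
    cv_report: CVReport | None = None

    @property
    def member_count(self) -> int:
        return sum(len(m) for m in self.members.values())

    def predict(self, smiles_list: Sequence[str], compound_ids: Sequence[str] | None = None) -> np.ndarray:
        """Consensus BA predictions; invalid SMILES yield NaN.

        Embedding and member prediction are batched; member slots that
        share one fitted estimator (seed-insensitive algorithms) are
        predicted once and weighted by their multiplicity.
        """
        if compound_ids is None:
            compound_ids = ["" for _ in smiles_list]
        n = len(smiles_list)
        out = np.full(n, np.nan)
        if n == 0:
            return out
        provider_sums = np.zeros(n)
        valid = np.ones(n, dtype=bool)
        for provider in self.providers:
            rows = np.zeros((n, provider.dimension))
            ok = np.zeros(n, dtype=bool)
            for j, (cid, smi) in enumerate(zip(compound_ids, smiles_list)):
                try:
                    vec = np.asarray(provider.embed_record(cid, smi), dtype=float)
                except Exception:
                    continue
                if np.all(np.isfinite(vec)):
                    rows[j] = vec
                    ok[j] = True
            valid &= ok
            if not valid.any():
                return out
            members = self.members[provider.provider_id]
            unique: dict[int, tuple[object, int]] = {}
            for est in members:
                key = id(est)
                unique[key] = (est, unique.get(key, (est, 0))[1] + 1)
            member_sum = np.zeros(valid.sum())
            X = rows[valid]
            for est, count in unique.values():
                member_sum += count * est.predict(X)
            provider_sums[valid] += member_sum / len(members)
        out[valid] = provider_sums[valid] / len(self.providers)
        return out


def predict_ba(model: ConsensusModel, smiles_list: Sequence[str]) -> np.ndarray:
    """Functional alias for :meth:`ConsensusModel.predict`."""
    return model.predict(smiles_list)


def _embeddings_by_provider(dataset: CuratedDataset, providers: Sequence[FingerprintProvider]):
    """Embed a dataset with each provider; keep rows embeddable by all."""
    results = {p.provider_id: embed_dataset(p, dataset) for p in providers}
    kept = None
    for res in results.values():
        kept = set(res.kept_indices) if kept is None else kept & set(res.kept_indices)
    kept = sorted(kept or [])
    matrices = {}
    for pid, res in results.items():
        pos = {idx: row for row, idx in enumerate(res.kept_indices)}
        matrices[pid] = res.matrix[[pos[i] for i in kept]]
    exclusions: list[tuple[str, str]] = []
    for res in results.values():
        exclusions.extend(res.exclusions)
    return kept, matrices, exclusions


def train_consensus(
    dataset: CuratedDataset,
    providers: Sequence[FingerprintProvider],
    spec: RegressorSpec = RegressorSpec(),
    n_seeds: int = 10,
    cv_k: int | None = 10,
    split_seed: int = 0,
) -> ConsensusModel:
    """Train the full provider x seed member grid for one target.

    Per provider, ``n_seeds`` members are fitted with seeds
    ``spec.seed + 0 .. n_seeds - 1``; the consensus prediction averages
    member predictions within a provider and then across providers.
    Compounds failing embedding under any provider are excluded and
    reported.  When ``cv_k`` is set, a pooled out-of-fold CV report is
    attached.
    """
    if not providers:
        raise ValidationError("at least one fingerprint provider is required")
    kept, matrices, exclusions = _embeddings_by_provider(dataset, providers)
    ba = dataset.ba[kept]
    members = {
        p.provider_id: _fit_members(matrices[p.provider_id], ba, spec, n_seeds) for p in providers
    }
    model = ConsensusModel(
        target_id=dataset.target_id,
        providers=list(providers),
        members=members,
        spec=spec,
        n_seeds=n_seeds,
        excluded=exclusions,
    )
    if cv_k:
        model.cv_report = cross_validate(dataset, providers, spec, k=cv_k, n_seeds=n_seeds, split_seed=split_seed)
    return model


def cross_validate(
    dataset: CuratedDataset,
    providers: Sequence[FingerprintProvider],
    spec: RegressorSpec = RegressorSpec(),
    k: int = 10,
    n_seeds: int = 10,
    split_seed: int = 0,
) -> CVReport:
    """k-fold CV with pooled out-of-fold consensus predictions.

    The shuffled fold split is deterministic given ``split_seed`` and is
    recorded in the report.  R and RMSD are computed once on the pooled
    out-of-fold prediction vector covering every embeddable compound.
    """
    kept, matrices, _ = _embeddings_by_provider(dataset, providers)
    ba = dataset.ba[kept]
    n = len(kept)
    if n < k:
        raise ValidationError(f"dataset has {n} usable records, fewer than k={k} folds")
    folds = np.empty(n, dtype=int)
    pooled = np.empty(n)
    splitter = KFold(n_splits=k, shuffle=True, random_state=split_seed)
    for fold_idx, (train_idx, test_idx) in enumerate(splitter.split(np.arange(n))):
        folds[test_idx] = fold_idx
        per_provider = []
        for p in providers:
            X = matrices[p.provider_id]
            members = _fit_members(X[train_idx], ba[train_idx], spec, n_seeds)
            preds = np.mean([est.predict(X[test_idx]) for est in members], axis=0)
            per_provider.append(preds)
        pooled[test_idx] = np.mean(per_provider, axis=0)
    return CVReport(
        pearson_r=pearson_r(pooled, ba),
        rmsd=rmsd(pooled, ba),
        k=k,
        split_seed=split_seed,
        fold_assignments=folds,
        pooled_predictions=pooled,
        observed=ba,
    )


# ---------------------------------------------------------------------------
# persistence


def save_model(model: ConsensusModel, path: str | Path) -> None:
    """Serialize a consensus model plus a JSON metadata sidecar."""
    path = Path(path)
    joblib.dump(model, path)
    meta = {
        "target_id": model.target_id,
        "algorithm": model.spec.algorithm,
        "base_seed": model.spec.seed,
        "n_seeds": model.n_seeds,
        "provider_ids": [p.provider_id for p in model.providers],
        "member_count": model.member_count,
        "cv": None
        if model.cv_report is None
        else {
            "pearson_r": model.cv_report.pearson_r,
            "rmsd": model.cv_report.rmsd,
            "k": model.cv_report.k,
            "split_seed": model.cv_report.split_seed,
        },
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def load_model(path: str | Path) -> ConsensusModel:
    return joblib.load(path)
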