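"""Shared fixtures: fingerprint providers and synthetic worlds.

The expensive study-scale pipeline (12 targets x 300 compounds, full
consensus training and cross-target matrix) is built once per session
and shared by every test that needs trained models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pytest

from polyscreen.chem import CuratedDataset
from polyscreen.embeddings import BaselineNgramProvider
from polyscreen.models import CVReport, RegressorSpec, train_consensus
from polyscreen.screen import build_cross_matrix
from polyscreen.synthetic import WorldParams, generate_world, world_to_datasets


def default_providers() -> list[BaselineNgramProvider]:
    """The two standard fingerprint providers used throughout the tests."""
    return [
        BaselineNgramProvider(dimension=512, hash_seed=101),
        BaselineNgramProvider(dimension=256, hash_seed=202),
    ]


@pytest.fixture(scope="session")
def providers():
    return default_providers()


@pytest.fixture(scope="session")
def small_world():
    """A light 4-target world for unit-level pipeline tests."""
    return generate_world(
        WorldParams(n_targets=4, n_families=3, compounds_per_target=120, noise_sd=0.3, seed=7)
    )


@pytest.fixture(scope="session")
def small_datasets(small_world) -> list[CuratedDataset]:
    return world_to_datasets(small_world)


@pytest.fixture(scope="session")
def small_models(small_datasets, providers):
    spec = RegressorSpec()
    return [
        train_consensus(d, providers, spec, n_seeds=3, cv_k=5) for d in small_datasets
    ]


@pytest.fixture(scope="session")
def study_world():
    """The standard study conditions: 12 targets, 4 families, 300/target."""
    return generate_world(WorldParams(seed=1))


@pytest.fixture(scope="session")
def study_datasets(study_world) -> list[CuratedDataset]:
    return world_to_datasets(study_world)


@pytest.fixture(scope="session")
def study_models(study_datasets, providers):
    spec = RegressorSpec()
    return [
        train_consensus(d, providers, spec, n_seeds=10, cv_k=10) for d in study_datasets
    ]


@pytest.fixture(scope="session")
def study_matrix(study_models, study_datasets):
    return build_cross_matrix(study_models, study_datasets)


@dataclass
class StubModel:
    """Minimal stand-in for a fitted consensus model with fixed outputs."""

    target_id: str
    by_smiles: dict[str, float]
    members: dict = field(default_factory=lambda: {"stub": [object()]})
    cv_report: CVReport = field(default_factory=lambda: CVReport(pearson_r=0.9, rmsd=0.5))

    def predict(self, smiles_list, compound_ids=None):
        return np.array([self.by_smiles.get(s, np.nan) for s in smiles_list])
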