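"""Synthetic screening worlds with planted ground truth.

Every pipeline stage — curation, embedding, consensus regression,
cross-target prediction, side-effect/repurposing screening — is
exercisable without any external download on worlds generated here.
A world emulates the statistical structure the analysis assumes:

* targets grouped into *families* whose latent binding vectors are
  close (within-family cosine ~0.94, cross-family small), mirroring
  the fact that paralogous proteins present similar binding sites;
* each family anchored by a *prototype* molecule (a simple hetero-atom
  chain SMILES); a target's inhibitor set consists of token-level
  mutants of that prototype, so chemical similarity decays with the
  number of mutations;
* a true affinity surface  ba_true(c, t) = ba0 - s * max(0, cos(u_c, t_vec))
  where ``u_c`` is a centered linear projection of the compound's
  n-gram fingerprint.  Because ``u_c`` is a function of the SMILES
  string, fingerprints carry real signal about ba_true and regression
  models can genuinely learn the surface — recovery tests are not
  vacuous;
* observed activities  ba_obs = ba_true + N(0, noise_sd)  written as
  alternating IC50/Ki rows in ChEMBL-style activity tables, exercising
  the unit and IC50->Ki->BA conversions;
* planted truth (side-effect pairs, repurposable compounds, clean
  leads) recorded by thresholding ``ba_true`` — never the noisy
  observations — at the screening thresholds.

The therapeutic target (named GABRA5 after the screening use case) and
the hERG anti-target each form a singleton family, so repurposable
compounds planted as low-mutation variants of the therapeutic
prototype are potent there and clean everywhere else.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .admet import ADMETProfile, SAS_PROPERTY
from .chem import (
    ActivityRecord,
    ActivityType,
    BA_PER_LOG10_KI,
    CurationCriteria,
    CuratedDataset,
    ba_to_ki,
    canonical_smiles,
    curate_dataset,
    standardize_records,
)
from .embeddings import BaselineNgramProvider
from .screen import ScreeningThresholds

logger = logging.getLogger(__name__)

THERAPEUTIC_ID = "GABRA5"
HERG_ID = "hERG"

_CHAIN_ATOMS = ("C", "N", "O", "S")


class WorldParamError(ValueError):
    pass


@dataclass(frozen=True)
class WorldParams:
    """Generator knobs; defaults define the standard study conditions."""

    n_targets: int = 12
    n_families: int = 4
    compounds_per_target: int = 300
    noise_sd: float = 0.3  # kcal/mol, additive on observed BA
    ba0: float = -6.0  # weakest-binding baseline, kcal/mol
    potency_scale: float = 6.0  # kcal/mol span of the affinity surface
    latent_dim: int = 64
    seed: int = 0
    max_mutations: int = 14
    chain_length: tuple[int, int] = (16, 24)  # prototype token count range
    n_repurpose: int = 4  # planted repurposable compounds
    family_jitter: float = 0.25  # latent spread of targets within a family

    def __post_init__(self) -> None:
        if self.n_targets < 3:
            raise WorldParamError("need at least 3 targets (therapeutic, hERG, one side-effect)")
        if not 3 <= self.n_families <= self.n_targets:
            raise WorldParamError("n_families must lie in [3, n_targets]")
        if self.compounds_per_target < 2:
            raise WorldParamError("compounds_per_target must be >= 2")
        if self.noise_sd < 0 or self.potency_scale <= 0:
            raise WorldParamError("noise_sd must be >= 0 and potency_scale > 0")
        if self.latent_dim < 4:
            raise WorldParamError("latent_dim must be >= 4")


@dataclass
class SyntheticTarget:
    target_id: str
    family: int
    vector: np.ndarray  # unit norm, latent_dim


@dataclass
class SyntheticCompound:
    compound_id: str
    smiles: str
    origin_target: str
    ba_true: dict[str, float]  # target_id -> true affinity, kcal/mol
    ba_observed: float  # on the origin target


@dataclass
class PlantedTruth:
    """Ground-truth labels derived by thresholding ba_true."""

    side_effect_pairs: set[tuple[str, str]]  # (dataset_id, target_id), i != j
    repurposable_compounds: set[str]
    clean_leads: set[str]
    thresholds: ScreeningThresholds


@dataclass
class SyntheticWorld:
    params: WorldParams
    targets: list[SyntheticTarget]
    compounds_by_target: dict[str, list[SyntheticCompound]]
    planted: PlantedTruth

    @property
    def target_ids(self) -> list[str]:
        return [t.target_id for t in self.targets]

    def all_compounds(self) -> list[SyntheticCompound]:
        return [c for tid in self.target_ids for c in self.compounds_by_target[tid]]


# ---------------------------------------------------------------------------
# construction helpers


def _random_chain(rng: np.random.Generator, lo: int, hi: int) -> list[str]:
    length = int(rng.integers(lo, hi + 1))
    return [_CHAIN_ATOMS[i] for i in rng.integers(0, len(_CHAIN_ATOMS), size=length)]


def _mutate_chain(rng: np.random.Generator, tokens: Sequence[str], k: int) -> list[str]:
    """Apply k random substitutions/insertions/deletions to an atom chain."""
    out = list(tokens)
    for _ in range(k):
        op = rng.random()
        if op < 0.7 or len(out) <= 6:  # substitute
            pos = int(rng.integers(0, len(out)))
            out[pos] = _CHAIN_ATOMS[int(rng.integers(0, len(_CHAIN_ATOMS)))]
        elif op < 0.85:  # insert
            pos = int(rng.integers(0, len(out) + 1))
            out.insert(pos, _CHAIN_ATOMS[int(rng.integers(0, len(_CHAIN_ATOMS)))])
        else:  # delete
            pos = int(rng.integers(0, len(out)))
            out.pop(pos)
    return out


class _LatentMap:
    """Whitened projection of baseline fingerprints to latent space.

    A reference sample of random chains (and their mutants) estimates
    the fingerprint mean and covariance; latent coordinates are the top
    principal components scaled to unit variance.  Whitening makes the
    latent cloud approximately isotropic, so alignments between
    unrelated compounds and targets concentrate near zero with spread
    ~1/sqrt(latent_dim) — unrelated dataset/target pairs then sit well
    clear of the potency thresholds.
    """

    def __init__(self, rng: np.random.Generator, latent_dim: int, chain_lo: int, chain_hi: int):
        self.provider = BaselineNgramProvider(
            dimension=256, hash_seed=int(rng.integers(0, 2**31))
        )
        reference: list[str] = []
        for _ in range(128):
            chain = _random_chain(rng, chain_lo, chain_hi)
            reference.append("".join(chain))
            for _ in range(3):
                k = int(rng.integers(1, 15))
                reference.append("".join(_mutate_chain(rng, chain, k)))
        fps = np.array([self.provider.embed(s) for s in reference])
        self.mean = fps.mean(axis=0)
        centered = fps - self.mean
        cov = centered.T @ centered / (len(reference) - 1)
        eigvals, eigvecs = np.linalg.eigh(cov)
        order = np.argsort(eigvals)[::-1][:latent_dim]
        scale = 1.0 / np.sqrt(np.maximum(eigvals[order], 1e-8))
        self.projection = (eigvecs[:, order] * scale).T  # (latent_dim, fp_dim)

    def __call__(self, smiles: str) -> np.ndarray:
        vec = self.projection @ (self.provider.embed(smiles) - self.mean)
        norm = np.linalg.norm(vec)
        return vec / norm if norm > 0 else vec


def _target_ids(n_targets: int) -> list[str]:
    ids = [THERAPEUTIC_ID, HERG_ID]
    ids += [f"T{i:02d}" for i in range(3, n_targets + 1)]
    return ids


def _family_assignment(n_targets: int, n_families: int) -> list[int]:
    """Families 0 (therapeutic) and 1 (hERG) are singletons; the rest
    spread round-robin over the remaining families."""
    families = [0, 1]
    for i in range(n_targets - 2):
        families.append(2 + i % (n_families - 2))
    return families


def generate_world(params: WorldParams = WorldParams()) -> SyntheticWorld:
    """Build a reproducible synthetic world from one seeded generator."""
    rng = np.random.default_rng(params.seed)
    latent = _LatentMap(rng, params.latent_dim, *params.chain_length)

    # family prototypes, rejected until their latent directions are distinct,
    # then orthogonalized so cross-family alignments are zero-mean by design
    families = sorted(set(_family_assignment(params.n_targets, params.n_families)))
    prototypes: dict[int, list[str]] = {}
    bases: dict[int, np.ndarray] = {}
    for fam in families:
        for _ in range(200):
            tokens = _random_chain(rng, *params.chain_length)
            base = latent("".join(tokens))
            for other in bases.values():  # Gram-Schmidt against earlier families
                base = base - float(base @ other) * other
            norm = np.linalg.norm(base)
            if norm >= 0.5:  # keep prototypes with a strong idiosyncratic part
                prototypes[fam] = tokens
                bases[fam] = base / norm
                break
        else:
            raise WorldParamError("could not sample sufficiently distinct family prototypes")

    assignment = _family_assignment(params.n_targets, params.n_families)
    targets: list[SyntheticTarget] = []
    for tid, fam in zip(_target_ids(params.n_targets), assignment):
        eta = rng.standard_normal(params.latent_dim)
        eta /= np.linalg.norm(eta)
        vector = bases[fam] + params.family_jitter * eta
        vector /= np.linalg.norm(vector)
        targets.append(SyntheticTarget(target_id=tid, family=fam, vector=vector))

    target_vecs = {t.target_id: t.vector for t in targets}
    fam_of = {t.target_id: t.family for t in targets}

    def affinity_profile(smiles: str) -> dict[str, float]:
        u = latent(smiles)
        return {
            tid: params.ba0 - params.potency_scale * max(0.0, float(u @ vec))
            for tid, vec in target_vecs.items()
        }

    compounds_by_target: dict[str, list[SyntheticCompound]] = {}
    for target in targets:
        proto = prototypes[target.family]
        seen: set[str] = set()
        members: list[SyntheticCompound] = []
        while len(members) < params.compounds_per_target:
            k = int(rng.integers(0, params.max_mutations + 1))
            smiles = "".join(_mutate_chain(rng, proto, k))
            canon = canonical_smiles(smiles)
            if canon is None or canon in seen:
                continue
            seen.add(canon)
            ba_true = affinity_profile(smiles)
            members.append(
                SyntheticCompound(
                    compound_id=f"{target.target_id}-C{len(members):04d}",
                    smiles=smiles,
                    origin_target=target.target_id,
                    ba_true=ba_true,
                    ba_observed=ba_true[target.target_id]
                    + float(rng.normal(0.0, params.noise_sd)),
                )
            )
        compounds_by_target[target.target_id] = members

    # plant repurposable compounds: low-mutation variants of the therapeutic
    # prototype slipped into the first cross-family side-effect dataset
    donor = next(
        t.target_id for t in targets if t.family not in (fam_of[THERAPEUTIC_ID], fam_of[HERG_ID])
    )
    donor_members = compounds_by_target[donor]
    donor_seen = {canonical_smiles(c.smiles) for c in donor_members}
    planted_ids: list[str] = []
    slot = len(donor_members) - 1
    injected = 0
    while injected < min(params.n_repurpose, len(donor_members)):
        k = int(rng.integers(0, 3))
        smiles = "".join(_mutate_chain(rng, prototypes[fam_of[THERAPEUTIC_ID]], k))
        canon = canonical_smiles(smiles)
        if canon is None or canon in donor_seen:
            continue
        donor_seen.add(canon)
        ba_true = affinity_profile(smiles)
        cid = f"{donor}-R{injected:02d}"
        donor_members[slot] = SyntheticCompound(
            compound_id=cid,
            smiles=smiles,
            origin_target=donor,
            ba_true=ba_true,
            ba_observed=ba_true[donor] + float(rng.normal(0.0, params.noise_sd)),
        )
        planted_ids.append(cid)
        slot -= 1
        injected += 1

    world = SyntheticWorld(
        params=params,
        targets=targets,
        compounds_by_target=compounds_by_target,
        planted=None,  # filled below
    )
    world.planted = planted_truth(world)
    return world


def planted_truth(
    world: SyntheticWorld,
    thresholds: ScreeningThresholds = ScreeningThresholds(),
) -> PlantedTruth:
    """Derive ground-truth screening labels by thresholding ba_true.

    Side-effect pairs: (dataset i, target j), i != j, where some
    compound of dataset i truly binds target j below the side-effect
    threshold.  Repurposable compounds and clean leads apply the full
    rule conjunctions on the noise-free affinity surface.
    """
    tids = world.target_ids
    side_effect_pairs: set[tuple[str, str]] = set()
    for ds in tids:
        for tj in tids:
            if tj == ds:
                continue
            strongest = min(c.ba_true[tj] for c in world.compounds_by_target[ds])
            if strongest < thresholds.side_effect_ba:
                side_effect_pairs.add((ds, tj))

    def clean_elsewhere(c: SyntheticCompound, exempt: set[str]) -> bool:
        return all(
            c.ba_true[tid] > thresholds.side_effect_ba
            for tid in tids
            if tid not in exempt and tid != HERG_ID
        ) and c.ba_true[HERG_ID] > thresholds.herg_ba

    repurposable: set[str] = set()
    for ds in tids:
        if ds == THERAPEUTIC_ID:
            continue
        for c in world.compounds_by_target[ds]:
            if (
                c.ba_true[ds] > thresholds.potency_ba
                and c.ba_true[THERAPEUTIC_ID] < thresholds.potency_ba
                and clean_elsewhere(c, exempt={THERAPEUTIC_ID})
            ):
                repurposable.add(c.compound_id)

    clean_leads: set[str] = set()
    for c in world.compounds_by_target[THERAPEUTIC_ID]:
        if c.ba_true[THERAPEUTIC_ID] < thresholds.potency_ba and clean_elsewhere(
            c, exempt={THERAPEUTIC_ID}
        ):
            clean_leads.add(c.compound_id)

    return PlantedTruth(
        side_effect_pairs=side_effect_pairs,
        repurposable_compounds=repurposable,
        clean_leads=clean_leads,
        thresholds=thresholds,
    )


# ---------------------------------------------------------------------------
# world -> pipeline inputs


def world_activity_records(world: SyntheticWorld, target_id: str) -> list[ActivityRecord]:
    """ChEMBL-style activity rows for one target's inhibitor set.

    Rows alternate between IC50 (nM) and Ki (uM) entries, with IC50
    written as 2x the Ki-equivalent so that parsing and conversion
    reproduce the observed BA exactly.
    """
    records = []
    for idx, comp in enumerate(world.compounds_by_target[target_id]):
        ki = ba_to_ki(comp.ba_observed)
        if idx % 2 == 0:
            atype, value = ActivityType.IC50, 2.0 * ki
        else:
            atype, value = ActivityType.KI, ki
        records.append(
            ActivityRecord(
                compound_id=comp.compound_id,
                smiles=comp.smiles,
                activity_type=atype,
                activity_value=value,
                organism="Homo sapiens",
                target_id=target_id,
                target_is_single_protein=True,
            )
        )
    return records


def _write_activity_csv(records: Sequence[ActivityRecord], path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(
            [
                "compound_id",
                "smiles",
                "activity_type",
                "activity_value",
                "units",
                "organism",
                "target_id",
                "single_protein",
            ]
        )
        for r in records:
            if r.activity_type is ActivityType.IC50:
                value, unit = r.activity_value / 1e-9, "nM"
            else:
                value, unit = r.activity_value / 1e-6, "uM"
            writer.writerow(
                [
                    r.compound_id,
                    r.smiles,
                    r.activity_type.value,
                    repr(value),
                    unit,
                    r.organism,
                    r.target_id,
                    "true" if r.target_is_single_protein else "false",
                ]
            )


def world_to_datasets(
    world: SyntheticWorld,
    out_dir: str | Path | None = None,
    criteria: CurationCriteria | None = None,
) -> list[CuratedDataset]:
    """Run every target's activity table through standardization+curation.

    When ``out_dir`` is given, the per-target activity tables are also
    written as CSV in the ingestion dialect.  The curated BA labels
    reproduce the world's observed BA to floating-point accuracy.
    """
    if criteria is None:
        criteria = CurationCriteria(
            min_size=min(250, world.params.compounds_per_target)
        )
    datasets: list[CuratedDataset] = []
    for tid in world.target_ids:
        records = world_activity_records(world, tid)
        if out_dir is not None:
            out = Path(out_dir)
            out.mkdir(parents=True, exist_ok=True)
            _write_activity_csv(records, out / f"activity_{tid}.csv")
        outcome = curate_dataset(standardize_records(records), criteria)
        if not isinstance(outcome, CuratedDataset):
            raise WorldParamError(
                f"synthetic dataset {tid} failed curation: {outcome.rule} ({outcome.detail})"
            )
        datasets.append(outcome)
    return datasets


def generate_admet_profiles(
    world: SyntheticWorld,
    seed: int | None = None,
) -> list[ADMETProfile]:
    """ADMET/SAS profile stubs aligned with the planted screening truth.

    Planted clean leads and repurposable compounds receive in-range
    lipophilicity and easy SAS; every other compound draws from wide
    distributions so that range rules have real attrition.
    """
    rng = np.random.default_rng(world.params.seed + 7919 if seed is None else seed)
    favored = world.planted.clean_leads | world.planted.repurposable_compounds
    profiles = []
    for comp in world.all_compounds():
        if comp.compound_id in favored:
            props = {
                "FDAMDD": float(rng.uniform(0.0, 0.3)),
                "T_half": float(rng.uniform(0.3, 0.8)),
                "F_20": float(rng.uniform(0.0, 0.3)),
                "logP": float(rng.uniform(0.5, 2.5)),
                "logS": float(rng.uniform(-3.5, -1.0)),
                "logD": float(rng.uniform(1.2, 2.8)),
                "Caco2": float(rng.uniform(-5.0, -4.5)),
                SAS_PROPERTY: float(rng.uniform(1.5, 4.5)),
            }
        else:
            props = {
                "FDAMDD": float(rng.uniform(0.0, 1.0)),
                "T_half": float(rng.uniform(0.0, 1.0)),
                "F_20": float(rng.uniform(0.0, 1.0)),
                "logP": float(rng.uniform(-1.0, 5.0)),
                "logS": float(rng.uniform(-6.5, 0.5)),
                "logD": float(rng.uniform(0.0, 4.0)),
                "Caco2": float(rng.uniform(-6.5, -4.0)),
                SAS_PROPERTY: float(rng.uniform(1.0, 9.0)),
            }
        profiles.append(ADMETProfile(compound_id=comp.compound_id, properties=props))
    return profiles


def generate_ppi_edge_lists(
    n_networks: int = 24,
    nodes_per_network: int = 260,
    pool_size: int = 1600,
    seed: int = 0,
) -> list[tuple[str, list[tuple[str, str, int]]]]:
    """Toy STRING-style edge lists: one seed-anchored network each.

    Node names draw from a shared protein pool so that merged networks
    overlap (deduplication is non-trivial).  Each network is connected
    (spanning tree from the seed plus random extra edges) with integer
    confidence scores in the STRING 0-1000 dialect.
    """
    rng = np.random.default_rng(seed)
    pool = [f"P{i:04d}" for i in range(pool_size)]
    out = []
    for net_idx in range(n_networks):
        seed_gene = f"SEED{net_idx + 1:02d}"
        members = [seed_gene] + [
            pool[i] for i in rng.choice(pool_size, size=nodes_per_network - 1, replace=False)
        ]
        edges: list[tuple[str, str, int]] = []
        for i in range(1, len(members)):
            j = int(rng.integers(0, i))  # attach to an earlier node: connected
            edges.append((members[j], members[i], int(rng.integers(400, 1000))))
        for _ in range(nodes_per_network):
            a, b = rng.choice(len(members), size=2, replace=False)
            edges.append((members[int(a)], members[int(b)], int(rng.integers(150, 1000))))
        out.append((seed_gene, edges))
    return out


def write_ppi_edge_lists(
    edge_lists: Sequence[tuple[str, Sequence[tuple[str, str, int]]]],
    out_dir: str | Path,
) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for seed_gene, edges in edge_lists:
        path = out / f"ppi_{seed_gene}.tsv"
        with open(path, "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for u, v, score in edges:
                fh.write(f"{u}\t{v}\t{score}\n")
        paths.append(path)
    return paths


def write_truth_tables(world: SyntheticWorld, out_dir: str | Path) -> None:
    """CSV truth tables for scoring pipeline output against the plant."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "true_side_effect_pairs.csv", "w") as fh:
        fh.write("dataset_id,target_id\n")
        for ds, tj in sorted(world.planted.side_effect_pairs):
            fh.write(f"{ds},{tj}\n")
    with open(out / "true_compound_labels.csv", "w") as fh:
        fh.write("compound_id,repurposable,clean_lead\n")
        for comp in world.all_compounds():
            fh.write(
                f"{comp.compound_id},"
                f"{int(comp.compound_id in world.planted.repurposable_compounds)},"
                f"{int(comp.compound_id in world.planted.clean_leads)}\n"
            )


def score_flag_recovery(
    true_pairs: set[tuple[str, str]],
    predicted_pairs: set[tuple[str, str]],
    all_pairs: Sequence[tuple[str, str]],
) -> tuple[float, float]:
    """(sensitivity, specificity) of recovered side-effect pairs."""
    true_pos = sum(1 for p in all_pairs if p in true_pairs and p in predicted_pairs)
    false_neg = sum(1 for p in all_pairs if p in true_pairs and p not in predicted_pairs)
    true_neg = sum(1 for p in all_pairs if p not in true_pairs and p not in predicted_pairs)
    false_pos = sum(1 for p in all_pairs if p not in true_pairs and p in predicted_pairs)
    sensitivity = true_pos / (true_pos + false_neg) if (true_pos + false_neg) else float("nan")
    specificity = true_neg / (true_neg + false_pos) if (true_neg + false_pos) else float("nan")
    return sensitivity, specificity
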