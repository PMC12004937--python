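"""PPI and drug-target network assembly from STRING-style edge lists.

Each protein-protein interaction network grows from one seed gene (a
receptor subunit of interest).  Edge lists are consumed from tab-
separated files with ``protein1, protein2, combined_score`` columns;
both the 0-1000 integer score dialect used by STRING exports and
already-normalised 0-1 scores are auto-detected.  Networks are capped
to a fixed size (201 proteins by default) by greedy max-confidence
expansion from the seed, then merged: the total node count with
multiplicity and the deduplicated union feed the target-curation
bookkeeping.  Curated inhibitor datasets finally attach as a bipartite
drug-target network with experimental binding affinities on the links
and exactly one flagged therapeutic target.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .chem import CuratedDataset

logger = logging.getLogger(__name__)

DEFAULT_CAP = 201
HERG_TARGET_ID = "hERG"


class NetworkError(ValueError):
    pass


@dataclass
class PPINetwork:
    """One seed-anchored protein interaction network."""

    seed_gene: str
    graph: nx.Graph  # edge attribute "confidence" in [0, 1]

    def __post_init__(self) -> None:
        if self.seed_gene not in self.graph:
            raise NetworkError(f"seed gene {self.seed_gene!r} absent from network")
        if any(u == v for u, v in self.graph.edges):
            raise NetworkError("self-edges are not allowed")

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def core_nodes(self) -> set[str]:
        """Proteins directly interacting with the seed."""
        return set(self.graph.neighbors(self.seed_gene))

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("protein1\tprotein2\tcombined_score\n")
            for u, v, data in sorted(self.graph.edges(data=True)):
                fh.write(f"{u}\t{v}\t{data['confidence']:.3f}\n")


def parse_string_edges(path: str | Path, seed_gene: str) -> PPINetwork:
    """Read a STRING-style TSV edge list anchored at ``seed_gene``.

    Reversed duplicate rows collapse to one undirected edge keeping the
    highest confidence; self-edges are dropped.  Scores above 1 are
    interpreted in the 0-1000 dialect and divided by 1000.
    """
    rows: list[tuple[str, str, float]] = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        try:
            i1, i2, isc = (header.index(c) for c in ("protein1", "protein2", "combined_score"))
        except ValueError as exc:
            raise NetworkError(f"{path}: expected protein1/protein2/combined_score columns") from exc
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) <= max(i1, i2, isc) or not line.strip():
                continue
            rows.append((parts[i1], parts[i2], float(parts[isc])))
    scale = 1000.0 if any(score > 1.0 for _, _, score in rows) else 1.0
    graph = nx.Graph()
    for u, v, score in rows:
        if u == v:
            continue
        confidence = score / scale
        if graph.has_edge(u, v):
            confidence = max(confidence, graph[u][v]["confidence"])
        graph.add_edge(u, v, confidence=confidence)
    if seed_gene not in graph:
        raise NetworkError(f"seed gene {seed_gene!r} not present in {path}")
    return PPINetwork(seed_gene=seed_gene, graph=graph)


def cap_network(net: PPINetwork, cap: int = DEFAULT_CAP) -> PPINetwork:
    """Trim a network to at most ``cap`` proteins around its seed.

    Starting from the seed, the node with the highest-confidence edge
    into the retained set is added repeatedly (lexicographic id order
    breaks ties) until the cap is reached or no connected node remains;
    the edge set is the induced subgraph.  Idempotent.
    """
    if cap < 1:
        raise NetworkError("cap must be >= 1")
    if net.n_nodes <= cap:
        return net
    retained = {net.seed_gene}
    # best confidence from each frontier node into the retained set
    best: dict[str, float] = {}
    for nbr in net.graph.neighbors(net.seed_gene):
        best[nbr] = net.graph[net.seed_gene][nbr]["confidence"]
    while len(retained) < cap and best:
        node = min(best, key=lambda n: (-best[n], n))
        del best[node]
        retained.add(node)
        for nbr in net.graph.neighbors(node):
            if nbr in retained:
                continue
            conf = net.graph[node][nbr]["confidence"]
            if conf > best.get(nbr, -1.0):
                best[nbr] = conf
    return PPINetwork(seed_gene=net.seed_gene, graph=net.graph.subgraph(retained).copy())


def merge_dedup(nets: Sequence[PPINetwork]) -> tuple[int, set[str]]:
    """Total node count with multiplicity and the deduplicated union."""
    if not nets:
        raise NetworkError("merge_dedup needs at least one network")
    total = sum(net.n_nodes for net in nets)
    unique: set[str] = set()
    for net in nets:
        unique |= net.nodes
    return total, unique


@dataclass
class DTINetwork:
    """Bipartite compound-target network with BA-annotated links."""

    targets: list[str]
    therapeutic_target: str
    compounds: set[str]
    links: list[tuple[str, str, float]]  # (compound_id, target_id, ba)
    excluded_proteins: int = 0

    def __post_init__(self) -> None:
        if self.therapeutic_target not in self.targets:
            raise NetworkError(f"therapeutic target {self.therapeutic_target!r} not among targets")
        target_set = set(self.targets)
        for cid, tid, _ in self.links:
            if tid not in target_set or cid not in self.compounds:
                raise NetworkError(f"dangling link ({cid}, {tid})")

    @property
    def side_effect_targets(self) -> list[str]:
        return [t for t in self.targets if t != self.therapeutic_target]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("compound_id\ttarget_id\tba_kcal_mol\n")
            for cid, tid, ba in self.links:
                fh.write(f"{cid}\t{tid}\t{ba:.4f}\n")


def build_dti(
    unique_proteins: set[str],
    curated: Sequence[CuratedDataset],
    therapeutic: str,
) -> DTINetwork:
    """Attach curated inhibitor datasets to the deduplicated protein pool.

    One target node per curated dataset; links carry experimental BA.
    The hERG anti-target is admitted even though it sits outside the
    PPI union.  ``excluded_proteins`` counts pool members without a
    curated dataset.
    """
    targets = []
    for dataset in curated:
        if dataset.target_id not in unique_proteins and dataset.target_id != HERG_TARGET_ID:
            raise NetworkError(f"curated target {dataset.target_id} not in the protein pool")
        targets.append(dataset.target_id)
    if therapeutic not in targets:
        raise NetworkError(f"therapeutic target {therapeutic!r} has no curated dataset")
    links: list[tuple[str, str, float]] = []
    compounds: set[str] = set()
    for dataset in curated:
        for cid, _, ba in dataset.records():
            links.append((cid, dataset.target_id, float(ba)))
            compounds.add(cid)
    excluded = len(unique_proteins - set(targets))
    return DTINetwork(
        targets=targets,
        therapeutic_target=therapeutic,
        compounds=compounds,
        links=links,
        excluded_proteins=excluded,
    )


def write_bookkeeping(
    path: str | Path,
    nets: Sequence[PPINetwork],
    dti: DTINetwork | None = None,
) -> None:
    """JSON report of capping/merging/curation bookkeeping."""
    total, unique = merge_dedup(nets)
    payload: dict = {
        "n_networks": len(nets),
        "nodes_with_multiplicity": total,
        "unique_proteins": len(unique),
        "per_network": {net.seed_gene: net.n_nodes for net in nets},
    }
    if dti is not None:
        payload["curated_targets"] = len(dti.targets)
        payload["excluded_proteins"] = dti.excluded_proteins
        payload["links"] = len(dti.links)
        payload["therapeutic_target"] = dti.therapeutic_target
    Path(path).write_text(json.dumps(payload, indent=2))
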