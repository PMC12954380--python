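"""Cofactor extraction, edge-to-edge distances and tunneling pathway graphs.

Electron tunneling between protein redox cofactors falls off exponentially
with the edge-to-edge distance — the minimum distance between any pair of
heavy atoms of the two cofactors.  In the Moser–Dutton picture a step of
up to ~15 Å supports physiologically efficient rates, and transfer remains
possible out to ~20 Å.  This module extracts cofactor heterogroups (hemes,
iron–sulfur clusters, flavins, nicotinamides) from coordinate files,
computes the pairwise edge-to-edge distance matrix, builds the distance-
thresholded transfer graph, and finds bottleneck-optimal electron routes
(minimising the longest single tunneling step).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gemmi
import networkx as nx
import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist

logger = logging.getLogger(__name__)

__all__ = [
    "AtomRecord",
    "CofactorInstance",
    "Pathway",
    "DEFAULT_REGISTRY",
    "EFFICIENT_MAX_A",
    "POSSIBLE_MAX_A",
    "parse_structure",
    "identify_cofactors",
    "edge_to_edge",
    "distance_matrix",
    "build_transfer_graph",
    "find_path",
    "min_group_distance",
]

# Moser-Dutton style step thresholds (Å): <=15 efficient, <=20 still possible.
EFFICIENT_MAX_A = 15.0
POSSIBLE_MAX_A = 20.0

# residue code -> cofactor kind; user-overridable because predicted models
# frequently mislabel b- vs c-type hemes
DEFAULT_REGISTRY: dict[str, str] = {
    "HEM": "heme_b",
    "HEC": "heme_c",
    "FES": "fe2s2",
    "SF4": "fe4s4",
    "F3S": "fe3s4",
    "FAD": "FAD",
    "NAP": "NADP",
    "NDP": "NADP",
}

HEME_KINDS = {"heme_b", "heme_c"}

# Conjugated-core atom names per kind, for the optional "conjugated" edge
# mode: porphyrin ring + Fe for hemes, isoalloxazine for FAD, nicotinamide
# ring + amide for NADP, whole cluster for FeS.  Names follow PDB chemical
# component dictionary conventions.
_PORPHYRIN_CORE = (
    {"FE", "NA", "NB", "NC", "ND", "CHA", "CHB", "CHC", "CHD"}
    | {f"C{i}{r}" for i in range(1, 5) for r in "ABCD"}
)
_ISOALLOXAZINE = {
    "N1", "C2", "O2", "N3", "C4", "O4", "C4X", "C4A", "N5", "C5X", "C5A",
    "C6", "C7", "C8", "C9", "C9A", "N10", "C10",
}
_NICOTINAMIDE = {"N1N", "C2N", "C3N", "C4N", "C5N", "C6N", "C7N", "O7N", "N7N"}
CONJUGATED_ATOMS: dict[str, set[str] | None] = {
    "heme_b": _PORPHYRIN_CORE,
    "heme_c": _PORPHYRIN_CORE,
    "fe2s2": None,   # whole cluster is the redox core
    "fe4s4": None,
    "fe3s4": None,
    "FAD": _ISOALLOXAZINE,
    "NADP": _NICOTINAMIDE,
}


@dataclass
class AtomRecord:
    """One atom from a coordinate file."""

    serial: int
    name: str
    element: str
    residue_name: str
    chain: str
    residue_seq: int
    xyz: tuple[float, float, float]
    is_hydrogen: bool = False

    def __post_init__(self) -> None:
        if not self.element:
            raise ValueError(f"atom {self.serial} has empty element")
        if not all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial} has non-finite coordinates")


@dataclass
class CofactorInstance:
    """A recognised redox cofactor: kind plus its heavy atoms."""

    kind: str
    label: str
    atoms: list[AtomRecord]

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(f"cofactor {self.label} has no atoms")
        if self.kind in HEME_KINDS and not any(a.element.upper() == "FE" for a in self.atoms):
            raise ValueError(f"heme cofactor {self.label} contains no iron atom")

    def coords(self, mode: str = "all") -> np.ndarray:
        """Heavy-atom coordinates, (n, 3); ``mode='conjugated'`` restricts to
        the conjugated redox core where one is defined for the kind."""
        atoms = self.atoms
        if mode == "conjugated":
            core = CONJUGATED_ATOMS.get(self.kind)
            if core is not None:
                sel = [a for a in atoms if a.name.strip().upper() in core]
                if sel:
                    atoms = sel
        elif mode != "all":
            raise ValueError(f"unknown atom mode {mode!r}")
        return np.array([a.xyz for a in atoms], dtype=float)


@dataclass
class Pathway:
    """An electron-transfer route through the transfer graph."""

    labels: list[str]
    step_distances: list[float]
    step_classes: list[str]
    connected: bool = True

    @property
    def bottleneck(self) -> float | None:
        return max(self.step_distances) if self.step_distances else None

    def to_dict(self) -> dict:
        return {
            "connected": self.connected,
            "labels": self.labels,
            "steps": [
                {"from": a, "to": b, "distance_A": d, "class": c}
                for a, b, d, c in zip(self.labels, self.labels[1:],
                                      self.step_distances, self.step_classes)
            ],
            "bottleneck_A": self.bottleneck,
        }


# ---------------------------------------------------------------------------
# Structure parsing
# ---------------------------------------------------------------------------

def parse_structure(path: str | Path) -> list[AtomRecord]:
    """Parse ATOM/HETATM records from a PDB (or mmCIF) file.

    Only the first MODEL is used.  For alternate conformations the
    highest-occupancy altloc is kept (ties go to the one encountered
    first).  Hydrogens are parsed and flagged, not dropped.
    """
    path = Path(path)
    try:
        st = gemmi.read_structure(str(path))
    except (RuntimeError, ValueError) as exc:
        raise ValueError(f"cannot parse structure file {path}: {exc}") from exc
    if len(st) == 0:
        raise ValueError(f"no models in {path}")
    model = st[0]

    records: list[AtomRecord] = []
    chosen: dict[tuple, tuple[float, int]] = {}  # altloc group -> (occ, position)
    for chain in model:
        for res in chain:
            for atom in res:
                key = (chain.name, res.seqid.num, res.name, atom.name)
                rec = AtomRecord(
                    serial=atom.serial,
                    name=atom.name,
                    element=atom.element.name,
                    residue_name=res.name,
                    chain=chain.name,
                    residue_seq=res.seqid.num,
                    xyz=(atom.pos.x, atom.pos.y, atom.pos.z),
                    is_hydrogen=bool(atom.element.is_hydrogen),
                )
                if key in chosen:
                    occ, pos = chosen[key]
                    if atom.occ > occ:  # strict: ties keep the first
                        chosen[key] = (atom.occ, pos)
                        records[pos] = rec
                else:
                    chosen[key] = (atom.occ, len(records))
                    records.append(rec)
    if not records:
        raise ValueError(f"no atoms found in {path}")
    return records


def identify_cofactors(
    atoms: Iterable[AtomRecord],
    registry: Mapping[str, str] | None = None,
) -> list[CofactorInstance]:
    """Group recognised heterogroup atoms into cofactor instances.

    One instance per (chain, residue number, residue name); hydrogens are
    excluded from instance atoms.  Residue codes not in the registry are
    ignored (logged at debug level) — they are protein or solvent.
    """
    registry = dict(DEFAULT_REGISTRY if registry is None else registry)
    groups: dict[tuple[str, int, str], list[AtomRecord]] = {}
    skipped: set[str] = set()
    for atom in atoms:
        code = atom.residue_name.strip().upper()
        if code not in registry:
            skipped.add(code)
            continue
        if atom.is_hydrogen:
            continue
        groups.setdefault((atom.chain, atom.residue_seq, code), []).append(atom)
    if skipped:
        logger.debug("ignored non-cofactor residues: %s", sorted(skipped))
    instances = [
        CofactorInstance(
            kind=registry[code],
            label=f"{chain}:{code}:{seq}",
            atoms=members,
        )
        for (chain, seq, code), members in sorted(groups.items())
    ]
    return instances


# ---------------------------------------------------------------------------
# Distances and graphs
# ---------------------------------------------------------------------------

def edge_to_edge(a: CofactorInstance, b: CofactorInstance, mode: str = "all") -> float:
    """Minimum heavy-atom pair distance between two cofactors, in Å."""
    if a is b or a.label == b.label:
        raise ValueError("edge_to_edge requires two distinct cofactors")
    return float(cdist(a.coords(mode), b.coords(mode)).min())


def distance_matrix(
    cofactors: Sequence[CofactorInstance], mode: str = "all"
) -> pd.DataFrame:
    """Symmetric labelled matrix of edge-to-edge distances; diagonal is NaN."""
    if len(cofactors) < 2:
        raise ValueError("need at least 2 cofactors for a distance matrix")
    labels = [c.label for c in cofactors]
    if len(set(labels)) != len(labels):
        raise ValueError("cofactor labels must be unique")
    n = len(cofactors)
    mat = np.full((n, n), np.nan)
    for i in range(n):
        for j in range(i + 1, n):
            d = edge_to_edge(cofactors[i], cofactors[j], mode)
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def classify_step(distance: float, efficient_max: float = EFFICIENT_MAX_A) -> str:
    return "efficient" if distance <= efficient_max else "possible"


def build_transfer_graph(
    cofactors: Sequence[CofactorInstance],
    cutoff: float = POSSIBLE_MAX_A,
    efficient_max: float = EFFICIENT_MAX_A,
    mode: str = "all",
) -> nx.Graph:
    """Undirected graph of cofactors with edges at edge-to-edge ≤ cutoff.

    Each edge carries ``distance`` (Å) and ``classification``: "efficient"
    for ≤ 15 Å steps, "possible" for longer steps within the cutoff.  Nodes
    and edges are inserted in sorted label order so iteration is
    deterministic.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ordered = sorted(cofactors, key=lambda c: c.label)
    g = nx.Graph(cutoff=cutoff, efficient_max=efficient_max, mode=mode)
    for c in ordered:
        g.add_node(c.label, kind=c.kind, n_atoms=len(c.atoms))
    for i, a in enumerate(ordered):
        for b in ordered[i + 1:]:
            d = edge_to_edge(a, b, mode)
            if d <= cutoff:
                g.add_edge(a.label, b.label, distance=d,
                           classification=classify_step(d, efficient_max))
    return g


def find_path(graph: nx.Graph, source_label: str, target_label: str) -> Pathway:
    """Bottleneck-optimal route from source to target.

    Minimises the maximum single-step distance (the rate-limiting tunneling
    step); among such routes prefers fewer steps, then lexicographically
    smallest label sequence.  A disconnected pair yields an explicit
    unconnected result, not an exception.
    """
    for lbl in (source_label, target_label):
        if lbl not in graph:
            raise KeyError(f"label {lbl!r} not in graph")
    if source_label == target_label:
        return Pathway(labels=[source_label], step_distances=[], step_classes=[])

    weights = sorted({d["distance"] for _, _, d in graph.edges(data=True)})
    efficient_max = graph.graph.get("efficient_max", EFFICIENT_MAX_A)
    for w in weights:
        sub = graph.edge_subgraph(
            (u, v) for u, v, d in graph.edges(data=True) if d["distance"] <= w
        )
        if source_label in sub and target_label in sub and nx.has_path(sub, source_label, target_label):
            best = min(
                nx.all_shortest_paths(sub, source_label, target_label),
                key=tuple,
            )
            dists = [graph[u][v]["distance"] for u, v in zip(best, best[1:])]
            classes = [classify_step(d, efficient_max) for d in dists]
            return Pathway(labels=list(best), step_distances=dists, step_classes=classes)
    return Pathway(labels=[], step_distances=[], step_classes=[], connected=False)


def min_group_distance(
    group_a: Sequence[CofactorInstance],
    group_b: Sequence[CofactorInstance],
    mode: str = "all",
) -> float:
    """Minimum edge-to-edge distance between two sets of cofactors.

    The metric behind questions like "how far are the soluble-domain hemes
    from the nearest membrane-domain cofactor".
    """
    if not group_a or not group_b:
        raise ValueError("both cofactor groups must be non-empty")
    return min(edge_to_edge(a, b, mode) for a in group_a for b in group_b
               if a.label != b.label)


# ---------------------------------------------------------------------------
# Output helpers
# ---------------------------------------------------------------------------

def write_distance_matrix(matrix: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    matrix.to_csv(path)
    return path


def write_edge_list(graph: nx.Graph, path: str | Path) -> Path:
    """Edge list TSV: label_a, label_b, distance_A, class."""
    path = Path(path)
    rows = [
        {"label_a": u, "label_b": v, "distance_A": d["distance"],
         "class": d["classification"]}
        for u, v, d in sorted(graph.edges(data=True))
    ]
    pd.DataFrame(rows, columns=["label_a", "label_b", "distance_A", "class"]).to_csv(
        path, sep="\t", index=False
    )
    return path


def write_pathway(pathway: Pathway, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(pathway.to_dict(), indent=2) + "\n")
    return path
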