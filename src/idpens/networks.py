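"""Intramolecular interaction persistence and residue-network analysis.

Per frame, residue-pair interactions are detected by class — salt bridge,
aromatic, amino-aromatic, hydrophobic — from class-specific atom groups and
distance cutoffs (0.5 nm for salt bridges and hydrophobics, 0.6 nm for
aromatic and amino-aromatic by convention).  The persistence of a pair is
the exact fraction of frames in which the interaction is present.  Pairs
whose persistence reaches a threshold (20% by default) become edges of a
simple weighted residue graph, which is then analyzed for hubs (high-degree
residues), connected components, and exhaustive cycle-free paths between
two residues (depth-first search that never revisits a node).

Atom groups: Lys NZ and Arg NE/NH1/NH2 versus Asp OD1/OD2 and Glu OE1/OE2
for salt bridges (His optional); ring centroids of Phe/Tyr/Trp/His for
aromatics; side-chain carbons of Ala/Val/Leu/Ile/Met/Pro/Phe for
hydrophobics.  Reduced topologies that carry a single side-chain reference
pseudo-atom (CB) per residue map it to the class groups by residue type.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .ensemble_io import ConformationalEnsemble, EnsembleError

__all__ = [
    "INTERACTION_CLASSES",
    "PersistenceMatrix",
    "InteractionGraph",
    "PathSet",
    "contact_persistence",
    "build_interaction_graph",
    "find_hubs",
    "connected_components",
    "enumerate_paths",
]

INTERACTION_CLASSES = ("salt_bridge", "aromatic", "amino_aromatic", "hydrophobic")

DEFAULT_CUTOFFS = {
    "salt_bridge": 0.5,
    "aromatic": 0.6,
    "amino_aromatic": 0.6,
    "hydrophobic": 0.5,
}

_BACKBONE = {"N", "CA", "C", "O", "H"}
_BASIC_ATOMS = {"LYS": ("NZ",), "ARG": ("NE", "NH1", "NH2")}
_BASIC_ATOMS_HIS = {"HIS": ("ND1", "NE2")}
_ACIDIC_ATOMS = {"ASP": ("OD1", "OD2"), "GLU": ("OE1", "OE2")}
_RING_ATOMS = {
    "PHE": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TYR": ("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),
    "TRP": ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"),
    "HIS": ("CG", "ND1", "CD2", "CE1", "NE2"),
}
_HYDROPHOBIC_RES = frozenset({"ALA", "VAL", "LEU", "ILE", "MET", "PRO", "PHE"})


@dataclass
class PersistenceMatrix:
    """R x R symmetric matrix of exact contact persistences (k/F)."""

    matrix: np.ndarray
    counts: np.ndarray  # integer frame counts, so k/F stays exact
    residue_ids: list[int]
    interaction_class: str
    distance_cutoff: float
    n_frames: int

    def persistence(self, res_i: int, res_j: int) -> Fraction:
        i = self.residue_ids.index(res_i)
        j = self.residue_ids.index(res_j)
        return Fraction(int(self.counts[i, j]), self.n_frames)

    def pairs_above(self, threshold: float) -> list[tuple[int, int, float]]:
        out = []
        R = len(self.residue_ids)
        for i in range(R):
            for j in range(i + 1, R):
                if self.matrix[i, j] >= threshold and self.matrix[i, j] > 0:
                    out.append((self.residue_ids[i], self.residue_ids[j],
                                float(self.matrix[i, j])))
        return out


@dataclass
class InteractionGraph:
    """Persistence-weighted simple residue graph."""

    graph: nx.Graph
    persistence_threshold: float
    interaction_class: str

    @property
    def nodes(self) -> list[int]:
        return sorted(self.graph.nodes)

    @property
    def edges(self) -> list[tuple[int, int, float]]:
        return sorted(
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in self.graph.edges(data=True)
        )


@dataclass
class PathSet:
    paths: list[list[int]]
    truncated: bool


def _residue_groups(ensemble: ConformationalEnsemble, interaction_class: str,
                    include_his: bool):
    """Per-residue (atom indices, centroid flag) groups for the two roles.

    Symmetric classes return the same group map for both roles.  A residue
    whose class-specific heavy atoms are absent but which carries a CB
    pseudo-atom falls back to that single reference atom.
    """
    top = ensemble.topology
    atoms_by_res: dict[int, list[int]] = {}
    name_of_res: dict[int, str] = {}
    for a, (aname, rid, rname) in enumerate(
            zip(top.atom_names, top.residue_ids, top.residue_names)):
        atoms_by_res.setdefault(int(rid), []).append(a)
        name_of_res[int(rid)] = rname

    def group(rid: int, wanted: tuple[str, ...]) -> list[int] | None:
        names = {top.atom_names[a]: a for a in atoms_by_res[rid]}
        found = [names[w] for w in wanted if w in names]
        if found:
            return found
        if "CB" in names:  # reduced topology: single side-chain reference
            return [names["CB"]]
        return None

    basic_map = dict(_BASIC_ATOMS)
    if include_his:
        basic_map.update(_BASIC_ATOMS_HIS)

    def collect(spec_map: dict[str, tuple[str, ...]]):
        out = {}
        for rid, rname in name_of_res.items():
            if rname in spec_map:
                g = group(rid, spec_map[rname])
                if g is not None:
                    out[rid] = g
        return out

    if interaction_class == "salt_bridge":
        return collect(basic_map), collect(_ACIDIC_ATOMS), (False, False)
    if interaction_class == "aromatic":
        rings = collect(_RING_ATOMS)
        return rings, rings, (True, True)
    if interaction_class == "amino_aromatic":
        return collect(basic_map), collect(_RING_ATOMS), (False, True)
    if interaction_class == "hydrophobic":
        out = {}
        for rid, rname in name_of_res.items():
            if rname in _HYDROPHOBIC_RES:
                sc = [a for a in atoms_by_res[rid]
                      if top.atom_names[a] not in _BACKBONE
                      and top.elements[a].capitalize() == "C"]
                if sc:
                    out[rid] = sc
        return out, out, (False, False)
    raise EnsembleError(f"unknown interaction class {interaction_class!r}")


def contact_persistence(
    ensemble: ConformationalEnsemble,
    interaction_class: str = "salt_bridge",
    distance_cutoff: float | None = None,
    include_his: bool = False,
    min_sequence_separation: int | None = None,
) -> PersistenceMatrix:
    """Per-pair interaction persistence over the ensemble frames.

    A contact in a frame is a minimum group-atom (or centroid-centroid,
    for aromatic rings) distance at or below the cutoff.  Persistence is
    the exact rational (frames with contact) / (total frames).
    ``min_sequence_separation`` defaults to 2 for the hydrophobic class and
    no filter otherwise.
    """
    if distance_cutoff is None:
        distance_cutoff = DEFAULT_CUTOFFS[interaction_class]
    if min_sequence_separation is None:
        min_sequence_separation = 2 if interaction_class == "hydrophobic" else 0
    groups_a, groups_b, (cent_a, cent_b) = _residue_groups(
        ensemble, interaction_class, include_his)
    residues = sorted(set(int(r) for r in ensemble.topology.residue_ids))
    if not groups_a or not groups_b:
        raise EnsembleError(
            f"no residues provide atoms for interaction class {interaction_class!r}")
    pos = {r: k for k, r in enumerate(residues)}
    R = len(residues)
    counts = np.zeros((R, R), dtype=np.int64)
    res_a = sorted(groups_a)
    res_b = sorted(groups_b)

    def stacked(frame, groups, order, centroid):
        coords, labels = [], []
        for k, rid in enumerate(order):
            pts = frame[groups[rid]]
            if centroid:
                pts = pts.mean(axis=0, keepdims=True)
            coords.append(pts)
            labels.extend([k] * len(pts))
        return np.concatenate(coords, axis=0), np.array(labels)

    for f in range(ensemble.n_frames):
        frame = ensemble.frames[f]
        A, la = stacked(frame, groups_a, res_a, cent_a)
        B, lb = stacked(frame, groups_b, res_b, cent_b)
        D = cdist(A, B)
        minmat = np.full((len(res_a), len(res_b)), np.inf)
        np.minimum.at(minmat, (la[:, None], lb[None, :]), D)
        hit_a, hit_b = np.where(minmat <= distance_cutoff)
        seen = set()
        for ia, ib in zip(hit_a, hit_b):
            ri, rj = res_a[ia], res_b[ib]
            if ri == rj or abs(ri - rj) < min_sequence_separation:
                continue
            # symmetric key: a pair qualifying in both role orientations
            # (possible e.g. for His in amino-aromatic) counts once per frame
            key = (min(ri, rj), max(ri, rj))
            if key in seen:
                continue
            seen.add(key)
            counts[pos[ri], pos[rj]] += 1
            counts[pos[rj], pos[ri]] += 1
    matrix = counts / ensemble.n_frames
    np.fill_diagonal(matrix, 0.0)
    return PersistenceMatrix(matrix, counts, residues, interaction_class,
                             float(distance_cutoff), ensemble.n_frames)


def build_interaction_graph(matrix: PersistenceMatrix,
                            persistence_threshold: float = 0.20
                            ) -> InteractionGraph:
    """Edges for every residue pair with persistence >= threshold."""
    g = nx.Graph()
    g.add_nodes_from(matrix.residue_ids)
    for i, j, w in matrix.pairs_above(persistence_threshold):
        g.add_edge(i, j, weight=w)
    return InteractionGraph(g, float(persistence_threshold),
                            matrix.interaction_class)


def _as_graph(graph) -> nx.Graph:
    return graph.graph if isinstance(graph, InteractionGraph) else graph


def find_hubs(graph, min_degree: int = 3) -> list[int]:
    """Residues connected to at least ``min_degree`` neighbors, sorted by id.

    The conventional hub definition is "at least three interactions"; pass
    ``min_degree=4`` for the stricter more-than-three variant.
    """
    g = _as_graph(graph)
    return sorted(n for n, d in g.degree if d >= min_degree)


def connected_components(graph) -> list[set[int]]:
    """Maximal connected sets of non-isolated nodes, largest first."""
    g = _as_graph(graph)
    comps = [set(c) for c in nx.connected_components(g) if len(c) > 1]
    return sorted(comps, key=lambda c: (-len(c), min(c)))


def enumerate_paths(graph, source: int, target: int,
                    max_paths: int = 100000) -> PathSet:
    """All simple paths source -> target, in lexicographic node order.

    Depth-first search over sorted neighbors; a node is never visited twice
    within one path, so cycles cannot trap the search.  If more than
    ``max_paths`` paths exist the list is truncated and flagged.
    """
    g = _as_graph(graph)
    if source == target:
        raise EnsembleError("source and target must differ")
    for node in (source, target):
        if node not in g:
            raise EnsembleError(f"node {node} not in graph")
    paths: list[list[int]] = []
    truncated = False
    stack = [source]
    on_path = {source}

    def dfs(node: int) -> bool:
        nonlocal truncated
        if node == target:
            if len(paths) >= max_paths:
                truncated = True
                return False
            paths.append(list(stack))
            return True
        for nb in sorted(g.neighbors(node)):
            if nb in on_path:
                continue
            stack.append(nb)
            on_path.add(nb)
            ok = dfs(nb)
            stack.pop()
            on_path.remove(nb)
            if not ok:
                return False
        return True

    dfs(source)
    return PathSet(paths, truncated)
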