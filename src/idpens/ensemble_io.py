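"""Coordinate-ensemble containers and I/O.

The central object is the :class:`ConformationalEnsemble`: a fixed atom
topology plus ``F`` frames of Cartesian coordinates.  Everything downstream
(PCA, free-energy landscapes, clustering, secondary structure, interaction
networks) consumes this type.  Coordinates are stored in nanometres
internally; the PDB boundary converts from/to angstroms.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "EnsembleError",
    "StructuralModel",
    "ConformationalEnsemble",
    "selection_indices",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "concatenate_ensembles",
    "superpose_ensemble",
    "pairwise_rmsd_matrix",
]

ANGSTROM_PER_NM = 10.0

#: atoms making up the peptide main chain, in the sense used for
#: "main-chain RMSD" throughout the package
MAINCHAIN_ATOMS = ("N", "CA", "C", "O")


class EnsembleError(ValueError):
    """Raised for malformed ensembles or inconsistent multi-model input."""


def _as_float_array(x, name: str, shape_tail: tuple[int, ...]) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.shape[-len(shape_tail):] != shape_tail:
        raise EnsembleError(f"{name} must have trailing shape {shape_tail}, got {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise EnsembleError(f"{name} contains non-finite values")
    return arr


@dataclass
class StructuralModel:
    """A single conformation: per-atom annotations plus one coordinate set.

    Parameters
    ----------
    atom_names, residue_names, residue_ids, elements
        Per-atom annotation lists of equal length ``A``.  Residue ids are
        taken verbatim from the input (no renumbering) and must be
        monotone non-decreasing.
    coordinates
        ``(A, 3)`` array in nm.
    """

    atom_names: list[str]
    residue_names: list[str]
    residue_ids: list[int]
    elements: list[str]
    coordinates: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        if n < 1:
            raise EnsembleError("StructuralModel must contain at least one atom")
        for name in ("residue_names", "residue_ids", "elements"):
            if len(getattr(self, name)) != n:
                raise EnsembleError(f"{name} length differs from atom_names length {n}")
        self.coordinates = _as_float_array(self.coordinates, "coordinates", (3,))
        if self.coordinates.shape != (n, 3):
            raise EnsembleError(
                f"coordinates shape {self.coordinates.shape} inconsistent with {n} atoms"
            )
        rid = np.asarray(self.residue_ids)
        if np.any(np.diff(rid) < 0):
            raise EnsembleError("residue_ids must be monotone non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)


@dataclass
class Topology:
    """Atom table shared by every frame of an ensemble (no coordinates)."""

    atom_names: list[str]
    residue_names: list[str]
    residue_ids: list[int]
    elements: list[str]

    def __post_init__(self) -> None:
        n = len(self.atom_names)
        if n < 1:
            raise EnsembleError("Topology must contain at least one atom")
        for name in ("residue_names", "residue_ids", "elements"):
            if len(getattr(self, name)) != n:
                raise EnsembleError(f"{name} length differs from atom_names length {n}")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    def __eq__(self, other) -> bool:  # type: ignore[override]
        if not isinstance(other, Topology):
            return NotImplemented
        return (
            self.atom_names == other.atom_names
            and self.residue_names == other.residue_names
            and self.residue_ids == other.residue_ids
            and self.elements == other.elements
        )

    def residue_index_map(self) -> dict[int, list[int]]:
        """Map residue id -> atom indices."""
        out: dict[int, list[int]] = {}
        for i, rid in enumerate(self.residue_ids):
            out.setdefault(int(rid), []).append(i)
        return out


@dataclass
class ConformationalEnsemble:
    """Atom topology plus ``F`` frames of coordinates (nm)."""

    topology: Topology
    frames: np.ndarray
    frame_labels: list[str] | None = None
    source_units: str = "nm"

    def __post_init__(self) -> None:
        self.frames = _as_float_array(self.frames, "frames", (3,))
        if self.frames.ndim != 3:
            raise EnsembleError(f"frames must be (F, A, 3), got shape {self.frames.shape}")
        if self.frames.shape[0] < 1:
            raise EnsembleError("ensemble must contain at least one frame")
        if self.frames.shape[1] != self.topology.n_atoms:
            raise EnsembleError(
                f"frames carry {self.frames.shape[1]} atoms but topology has "
                f"{self.topology.n_atoms}"
            )
        if self.frame_labels is not None and len(self.frame_labels) != self.frames.shape[0]:
            raise EnsembleError("frame_labels length differs from number of frames")
        if self.source_units not in ("nm", "angstrom"):
            raise EnsembleError(f"unknown source_units {self.source_units!r}")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.topology.n_atoms

    def model(self, frame: int) -> StructuralModel:
        """Extract one frame as a :class:`StructuralModel`."""
        t = self.topology
        return StructuralModel(
            list(t.atom_names),
            list(t.residue_names),
            list(t.residue_ids),
            list(t.elements),
            self.frames[frame].copy(),
        )

    def subset(self, frame_indices: Sequence[int]) -> "ConformationalEnsemble":
        """New ensemble restricted to the given frames (topology shared)."""
        idx = np.asarray(frame_indices, dtype=int)
        labels = None
        if self.frame_labels is not None:
            labels = [self.frame_labels[i] for i in idx]
        return ConformationalEnsemble(self.topology, self.frames[idx].copy(), labels)


# ---------------------------------------------------------------------------
# atom selections
# ---------------------------------------------------------------------------

def selection_indices(topology: Topology, selection) -> np.ndarray:
    """Resolve a selection into atom indices.

    ``selection`` may be ``"all"``, ``"ca"``, ``"mainchain"``, an explicit
    index sequence, or a predicate ``f(atom_name, residue_name, residue_id,
    element) -> bool``.
    """
    if isinstance(selection, str):
        key = selection.lower()
        if key == "all":
            return np.arange(topology.n_atoms)
        if key == "ca":
            return np.array(
                [i for i, a in enumerate(topology.atom_names) if a == "CA"], dtype=int
            )
        if key == "mainchain":
            return np.array(
                [i for i, a in enumerate(topology.atom_names) if a in MAINCHAIN_ATOMS],
                dtype=int,
            )
        raise EnsembleError(f"unknown selection string {selection!r}")
    if callable(selection):
        return np.array(
            [
                i
                for i in range(topology.n_atoms)
                if selection(
                    topology.atom_names[i],
                    topology.residue_names[i],
                    topology.residue_ids[i],
                    topology.elements[i],
                )
            ],
            dtype=int,
        )
    return np.asarray(selection, dtype=int)


# ---------------------------------------------------------------------------
# PDB I/O (via biotite)
# ---------------------------------------------------------------------------

def _precheck_model_atom_counts(path) -> None:
    """Verify all MODEL blocks carry the same number of coordinate records.

    Biotite raises an unspecific error on ragged multi-model files; this
    pre-scan names the offending MODEL as the I/O contract requires.
    """
    counts: list[tuple[int, int]] = []  # (model serial, atom count)
    current: int | None = None
    n = 0
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                if current is not None:
                    counts.append((current, n))
                try:
                    current = int(line[6:].split()[0])
                except (IndexError, ValueError):
                    current = len(counts) + 1
                n = 0
            elif rec in ("ATOM  ", "HETATM"):
                n += 1
            elif rec == "ENDMDL":
                if current is not None:
                    counts.append((current, n))
                    current = None
                    n = 0
    if current is not None:
        counts.append((current, n))
    if len(counts) > 1:
        ref_serial, ref_count = counts[0]
        for serial, count in counts[1:]:
            if count != ref_count:
                raise EnsembleError(
                    f"MODEL {serial} has {count} atoms but MODEL {ref_serial} "
                    f"has {ref_count}"
                )


def read_multimodel_pdb(path) -> ConformationalEnsemble:
    """Read a (multi-)MODEL PDB file into an ensemble, one frame per MODEL.

    Coordinates are converted angstrom -> nm.  The topology is taken from
    the first model; all models must share atom count and atom identity.
    """
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    _precheck_model_atom_counts(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if isinstance(stack, struc.AtomArray):  # single bare coordinate block
        stack = struc.stack([stack])
    if stack.array_length() == 0:
        raise EnsembleError(f"{path}: no atoms found")
    topology = Topology(
        [str(a) for a in stack.atom_name],
        [str(r) for r in stack.res_name],
        [int(r) for r in stack.res_id],
        [str(e).capitalize() for e in stack.element],
    )
    frames = np.asarray(stack.coord, dtype=float) / ANGSTROM_PER_NM
    return ConformationalEnsemble(topology, frames, source_units="angstrom")


def write_multimodel_pdb(ensemble: ConformationalEnsemble, path) -> None:
    """Write the ensemble as a multi-MODEL PDB file (nm -> angstrom)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    if ensemble.n_frames < 1:
        raise EnsembleError("cannot write an ensemble without frames")
    t = ensemble.topology
    array = struc.AtomArray(t.n_atoms)
    array.atom_name = np.array(t.atom_names, dtype="U6")
    array.res_name = np.array(t.residue_names, dtype="U5")
    array.res_id = np.array(t.residue_ids, dtype=int)
    array.element = np.array([e.upper() for e in t.elements], dtype="U2")
    array.chain_id = np.full(t.n_atoms, "A", dtype="U4")
    array.hetero = np.zeros(t.n_atoms, dtype=bool)
    stack = struc.from_template(array, ensemble.frames * ANGSTROM_PER_NM)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))
    if ensemble.n_frames == 1:
        # keep the one-frame file a proper single MODEL/ENDMDL block
        text = Path(path).read_text()
        if "MODEL" not in text:
            body = text.rstrip("\n")
            Path(path).write_text(f"MODEL        1\n{body}\nENDMDL\nEND\n")


# ---------------------------------------------------------------------------
# concatenation
# ---------------------------------------------------------------------------

def concatenate_ensembles(
    ensembles: Sequence[ConformationalEnsemble],
    discard_head: int | Sequence[int] = 0,
) -> ConformationalEnsemble:
    """Concatenate replicate ensembles into one macro-ensemble.

    ``discard_head`` frames are dropped from the start of each member
    (equilibration stripping).  Frame labels record the source replicate
    as ``r1``, ``r2``, ...
    """
    ensembles = list(ensembles)
    if not ensembles:
        raise EnsembleError("need at least one ensemble to concatenate")
    if isinstance(discard_head, (int, np.integer)):
        discards = [int(discard_head)] * len(ensembles)
    else:
        discards = [int(d) for d in discard_head]
        if len(discards) != len(ensembles):
            raise EnsembleError("discard_head length differs from number of ensembles")
    ref_top = ensembles[0].topology
    blocks = []
    labels: list[str] = []
    for k, (ens, disc) in enumerate(zip(ensembles, discards)):
        if ens.topology != ref_top:
            raise EnsembleError(f"ensemble {k + 1} topology differs from the first")
        if disc < 0 or disc >= ens.n_frames:
            raise EnsembleError(
                f"discard_head={disc} leaves no frames in member {k + 1} "
                f"(F={ens.n_frames})"
            )
        blocks.append(ens.frames[disc:])
        labels.extend([f"r{k + 1}"] * (ens.n_frames - disc))
    return ConformationalEnsemble(ref_top, np.concatenate(blocks, axis=0), labels)


# ---------------------------------------------------------------------------
# superposition and RMSD
# ---------------------------------------------------------------------------

def kabsch_fit(mobile: np.ndarray, reference: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Optimal rigid fit of ``mobile`` onto ``reference`` (both (N, 3), nm).

    Returns ``(rotation matrix, translation, rmsd)`` such that
    ``mobile @ R.T + t`` minimizes the RMSD to ``reference``.
    """
    mob_c = mobile.mean(axis=0)
    ref_c = reference.mean(axis=0)
    rot, rssd = Rotation.align_vectors(reference - ref_c, mobile - mob_c)
    rmsd = rssd / np.sqrt(mobile.shape[0])
    rmat = rot.as_matrix()
    t = ref_c - mob_c @ rmat.T
    return rmat, t, float(rmsd)


def superpose_ensemble(
    ensemble: ConformationalEnsemble,
    selection="ca",
    reference: int | str = "iterative-mean",
    tol: float = 1e-12,
    max_iter: int = 100,
) -> ConformationalEnsemble:
    """Least-squares superpose every frame on a common reference.

    ``reference`` is either a frame index or ``"iterative-mean"``: fit all
    frames to the current selection mean, recompute the mean, and iterate
    until it shifts by less than ``tol`` (nm) or ``max_iter`` rounds have
    run (an already-superposed ensemble is a fixed point, so the operation
    is idempotent).  The fit is computed on the selected atoms and the
    resulting rigid transform is applied to all atoms, so intra-frame
    distances are untouched.
    """
    idx = selection_indices(ensemble.topology, selection)
    if idx.size < 3:
        raise EnsembleError("superposition needs a selection of at least 3 atoms")
    frames = ensemble.frames.copy()

    def _fit_all(ref_coords: np.ndarray) -> None:
        for f in range(frames.shape[0]):
            rmat, t, _ = kabsch_fit(frames[f, idx], ref_coords)
            frames[f] = frames[f] @ rmat.T + t

    if reference == "iterative-mean":
        ref = frames[:, idx].mean(axis=0)
        for _ in range(max_iter):
            _fit_all(ref)
            new_ref = frames[:, idx].mean(axis=0)
            shift = float(np.max(np.linalg.norm(new_ref - ref, axis=1)))
            ref = new_ref
            if shift < tol:
                break
    else:
        ref = frames[int(reference), idx].copy()
        _fit_all(ref)
    labels = list(ensemble.frame_labels) if ensemble.frame_labels is not None else None
    return ConformationalEnsemble(ensemble.topology, frames, labels)


def pairwise_rmsd_matrix(
    ensemble: ConformationalEnsemble,
    selection="mainchain",
    fit: bool = True,
) -> np.ndarray:
    """F x F matrix of least-squares RMSDs (nm) over the selection.

    With ``fit=True`` (default) every pair is optimally superposed before
    the RMSD is taken; with ``fit=False`` the coordinates are compared as
    stored (useful after a single global superposition).
    """
    idx = selection_indices(ensemble.topology, selection)
    if idx.size == 0:
        raise EnsembleError("empty selection for RMSD matrix")
    X = ensemble.frames[:, idx, :]
    F, A = X.shape[0], X.shape[1]
    if not fit:
        diff = X[:, None] - X[None, :]
        msd = np.einsum("fgaj,fgaj->fg", diff, diff) / A
        return np.sqrt(np.maximum(msd, 0.0))
    Xc = X - X.mean(axis=1, keepdims=True)
    # batched Kabsch over all pairs: cross-covariances H_fg = Xc_f^T Xc_g
    H = np.einsum("fai,gaj->fgij", Xc, Xc)
    U, S, Vt = np.linalg.svd(H)
    det = np.linalg.det(U) * np.linalg.det(Vt)
    S_corr = S.copy()
    S_corr[..., -1] *= np.sign(det)
    sq_norm = np.einsum("fai,fai->f", Xc, Xc)
    msd = (sq_norm[:, None] + sq_norm[None, :] - 2.0 * S_corr.sum(axis=-1)) / A
    msd = np.maximum(msd, 0.0)
    np.fill_diagonal(msd, 0.0)
    out = np.sqrt(msd)
    return (out + out.T) / 2.0
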