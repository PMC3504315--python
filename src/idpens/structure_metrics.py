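"""Secondary structure (Kabsch-Sander) and solvent-accessible surface.

Secondary structure is assigned per frame from backbone hydrogen bonds
using the Kabsch-Sander electrostatic model: the bond energy between the
C=O of residue i and the N-H of residue j is

    E = 0.084 * (1/r_ON + 1/r_CH - 1/r_OH - 1/r_CN) * 332   kcal/mol

(distances in angstrom) and a hydrogen bond is called at E < -0.5 kcal/mol.
n-turns (i -> i+3, i+4, i+5) define the helix classes G (3-10), H (alpha)
and I (pi) through two consecutive turns, with the DSSP priority H > G > I;
residues inside isolated turns are T, everything else C.  Strand classes
are out of scope (disordered-chain analyses here report helix/coil only).

Solvent-accessible surface is computed with the Shrake-Rupley sphere-point
quadrature: per atom, points on a sphere of radius r_vdw + r_probe are
tested against all neighbor spheres; the accessible fraction times the
sphere area is the atom's contribution.  The point set is a deterministic
golden-spiral covering, so results are exactly reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .ensemble_io import ConformationalEnsemble, EnsembleError

__all__ = [
    "SS_CLASSES",
    "SecondaryStructureProfile",
    "SASProfile",
    "assign_secondary_structure",
    "helical_content_summary",
    "shrake_rupley_sas",
    "basin_structure_report",
    "VDW_RADII",
]

SS_CLASSES = ("H", "G", "I", "T", "C")

_Q1Q2_F = 0.084 * 332.0  # Kabsch-Sander electrostatic prefactor, kcal/mol * A
_HBOND_ENERGY_CUTOFF = -0.5  # kcal/mol
_NM_TO_ANG = 10.0

#: van der Waals radii (nm); pseudo-atoms default to carbon
VDW_RADII = {"C": 0.17, "N": 0.155, "O": 0.152, "S": 0.18, "H": 0.12}
DEFAULT_VDW = 0.17


@dataclass
class SecondaryStructureProfile:
    """F x R class assignments over {H, G, I, T, C} plus residue ids."""

    assignments: np.ndarray  # (F, R) of single-character strings
    residue_ids: list[int]

    @property
    def n_frames(self) -> int:
        return self.assignments.shape[0]

    @property
    def n_residues(self) -> int:
        return self.assignments.shape[1]

    def persistence(self) -> pd.DataFrame:
        """Per-residue fraction of frames in each class (rows sum to 1)."""
        data = {
            cls: (self.assignments == cls).mean(axis=0) for cls in SS_CLASSES
        }
        return pd.DataFrame(data, index=self.residue_ids)


@dataclass
class SASProfile:
    """Per-frame and per-residue solvent-accessible surface (nm^2)."""

    total_sas: np.ndarray          # (F,)
    per_residue_sas: np.ndarray    # (F, R)
    residue_ids: list[int]
    probe_radius: float
    n_points: int


# ---------------------------------------------------------------------------
# Kabsch-Sander secondary structure
# ---------------------------------------------------------------------------

def _backbone_arrays(ensemble: ConformationalEnsemble):
    """Per-residue backbone atom indices (N, CA, C, O, H; H may be -1)."""
    top = ensemble.topology
    residues: list[int] = []
    index: dict[int, dict[str, int]] = {}
    for a, (name, rid) in enumerate(zip(top.atom_names, top.residue_ids)):
        rid = int(rid)
        if rid not in index:
            index[rid] = {}
            residues.append(rid)
        if name in ("N", "CA", "C", "O", "H") and name not in index[rid]:
            index[rid][name] = a
    idx = {}
    for name in ("N", "CA", "C", "O"):
        rows = []
        for rid in residues:
            if name not in index[rid]:
                raise EnsembleError(f"residue {rid} lacks backbone atom {name}")
            rows.append(index[rid][name])
        idx[name] = np.array(rows, dtype=int)
    idx["H"] = np.array([index[rid].get("H", -1) for rid in residues], dtype=int)
    return residues, idx


def _amide_hydrogens(coords: np.ndarray, idx, proline: np.ndarray) -> np.ndarray:
    """Amide H positions; reconstructed at 0.1 nm from N along the
    anti-bisector of C(i-1)-N-CA where no H atom is present."""
    R = idx["N"].size
    H = np.full((R, 3), np.nan)
    has_h = idx["H"] >= 0
    H[has_h] = coords[idx["H"][has_h]]
    for i in range(1, R):
        if not has_h[i] and not proline[i]:
            n = coords[idx["N"][i]]
            d1 = n - coords[idx["C"][i - 1]]
            d2 = n - coords[idx["CA"][i]]
            d = d1 / np.linalg.norm(d1) + d2 / np.linalg.norm(d2)
            H[i] = n + 0.1 * d / np.linalg.norm(d)
    return H


def _hbond_energy(c: np.ndarray, o: np.ndarray,
                  n: np.ndarray, h: np.ndarray) -> float:
    """Kabsch-Sander energy (kcal/mol) for acceptor C=O and donor N-H."""
    r_on = np.linalg.norm(o - n) * _NM_TO_ANG
    r_ch = np.linalg.norm(c - h) * _NM_TO_ANG
    r_oh = np.linalg.norm(o - h) * _NM_TO_ANG
    r_cn = np.linalg.norm(c - n) * _NM_TO_ANG
    if min(r_on, r_ch, r_oh, r_cn) < 0.5:  # atoms essentially clashing
        return -9.9
    return _Q1Q2_F * (1.0 / r_on + 1.0 / r_ch - 1.0 / r_oh - 1.0 / r_cn)


def _assign_frame(coords: np.ndarray, idx, H: np.ndarray,
                  proline: np.ndarray) -> np.ndarray:
    R = idx["N"].size
    # turn_n[n][i]: hydrogen bond CO(i) -> NH(i+n)
    turns = {n: np.zeros(R, dtype=bool) for n in (3, 4, 5)}
    for n in (3, 4, 5):
        for i in range(R - n):
            j = i + n
            if proline[j] or not np.all(np.isfinite(H[j])):
                continue
            e = _hbond_energy(coords[idx["C"][i]], coords[idx["O"][i]],
                              coords[idx["N"][j]], H[j])
            if e < _HBOND_ENERGY_CUTOFF:
                turns[n][i] = True
    ss = np.full(R, "C", dtype="U1")
    # minimal helices: two consecutive n-turns at i-1 and i
    for n, cls in ((4, "H"), (3, "G"), (5, "I")):  # DSSP priority H > G > I
        for i in range(1, R - n):
            if turns[n][i - 1] and turns[n][i]:
                for k in range(i, i + n):
                    if ss[k] == "C":
                        ss[k] = cls
    # isolated turns: residues spanned by any n-turn
    for n in (3, 4, 5):
        for i in np.where(turns[n])[0]:
            for k in range(i + 1, i + n):
                if k < R and ss[k] == "C":
                    ss[k] = "T"
    return ss


def assign_secondary_structure(ensemble: ConformationalEnsemble
                               ) -> SecondaryStructureProfile:
    """Kabsch-Sander helix/turn/coil assignment for every frame."""
    residues, idx = _backbone_arrays(ensemble)
    top = ensemble.topology
    res_name_of = {int(r): n for r, n in zip(top.residue_ids, top.residue_names)}
    proline = np.array([res_name_of[r] == "PRO" for r in residues])
    F = ensemble.n_frames
    out = np.full((F, len(residues)), "C", dtype="U1")
    for f in range(F):
        coords = ensemble.frames[f]
        H = _amide_hydrogens(coords, idx, proline)
        out[f] = _assign_frame(coords, idx, H, proline)
    return SecondaryStructureProfile(out, residues)


def helical_content_summary(profile: SecondaryStructureProfile,
                            frames=None) -> dict:
    """Mean/max helical class counts and percentages over a frame subset.

    Percentages are of the full chain length R.  Returns a dict with keys
    ``mean_alpha``, ``mean_310``, ``mean_pi`` (mean residue counts),
    ``max_alpha``, ``max_310``, ``max_pi`` (per-frame maxima),
    ``pct_alpha`` .. and ``total_helical_pct``.
    """
    if frames is None:
        A = profile.assignments
    else:
        idx = np.asarray(frames, dtype=int)
        A = profile.assignments[idx] if idx.size else profile.assignments[:0]
    if A.shape[0] == 0:
        raise EnsembleError("empty frame subset")
    R = A.shape[1]
    out = {}
    for cls, tag in (("H", "alpha"), ("G", "310"), ("I", "pi")):
        counts = (A == cls).sum(axis=1)
        out[f"mean_{tag}"] = float(counts.mean())
        out[f"max_{tag}"] = int(counts.max())
        out[f"pct_{tag}"] = float(counts.mean() / R * 100.0)
    helical = np.isin(A, ("H", "G", "I")).sum(axis=1)
    out["total_helical_pct"] = float(helical.mean() / R * 100.0)
    return out


# ---------------------------------------------------------------------------
# Shrake-Rupley SAS
# ---------------------------------------------------------------------------

def _sphere_points(n: int) -> np.ndarray:
    """Deterministic golden-spiral covering of the unit sphere."""
    k = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (k + 0.5) / n
    r = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = np.pi * (1.0 + np.sqrt(5.0)) * (k + 0.5)
    return np.stack([r * np.cos(theta), r * np.sin(theta), z], axis=1)


def shrake_rupley_sas(ensemble: ConformationalEnsemble,
                      probe_radius: float = 0.14,
                      n_points: int = 960,
                      radii: dict[str, float] | None = None) -> SASProfile:
    """Shrake-Rupley solvent-accessible surface, per frame and per residue."""
    if probe_radius < 0:
        raise EnsembleError("probe_radius must be >= 0")
    table = dict(VDW_RADII)
    if radii:
        table.update(radii)
    top = ensemble.topology
    r_atom = np.empty(top.n_atoms)
    for a, elem in enumerate(top.elements):
        key = elem.capitalize()
        if key not in table:
            raise EnsembleError(f"no van der Waals radius configured for "
                                f"element {elem!r}")
        r_atom[a] = table[key]
    r_ext = r_atom + probe_radius
    points = _sphere_points(int(n_points))
    residues = sorted(set(int(r) for r in top.residue_ids))
    res_pos = {r: k for k, r in enumerate(residues)}
    atom_res = np.array([res_pos[int(r)] for r in top.residue_ids])
    F, A = ensemble.n_frames, top.n_atoms
    per_res = np.zeros((F, len(residues)))
    total = np.zeros(F)
    max_r = r_ext.max()
    for f in range(F):
        coords = ensemble.frames[f]
        tree = cKDTree(coords)
        neighbor_lists = tree.query_ball_point(coords, r=r_ext + max_r)
        areas = np.empty(A)
        for a in range(A):
            nbrs = [b for b in neighbor_lists[a] if b != a
                    and np.linalg.norm(coords[b] - coords[a]) < r_ext[a] + r_ext[b]]
            sphere = coords[a] + r_ext[a] * points
            if nbrs:
                nb = coords[nbrs]
                d2 = ((sphere[:, None, :] - nb[None, :, :]) ** 2).sum(axis=2)
                buried = (d2 < (r_ext[nbrs] ** 2)[None, :]).any(axis=1)
                frac = 1.0 - buried.mean()
            else:
                frac = 1.0
            areas[a] = 4.0 * np.pi * r_ext[a] ** 2 * frac
        total[f] = areas.sum()
        np.add.at(per_res[f], atom_res, areas)
    return SASProfile(total, per_res, residues, probe_radius, int(n_points))


# ---------------------------------------------------------------------------
# per-basin report
# ---------------------------------------------------------------------------

def basin_structure_report(basin_labels: list[str],
                           ss_profile: SecondaryStructureProfile,
                           sas_profile: SASProfile) -> pd.DataFrame:
    """Per-basin helical content and SAS statistics.

    ``basin_labels`` gives one label per frame; unassigned frames are
    skipped.  Empty basins are omitted.  Columns mirror a helicity/SAS
    summary table: mean and max counts per helix class, total helical %,
    SAS mean/min/max.
    """
    if len(basin_labels) != ss_profile.n_frames:
        raise EnsembleError("basin labels do not align with frames")
    if sas_profile.total_sas.shape[0] != ss_profile.n_frames:
        raise EnsembleError("SAS profile does not align with frames")
    rows = []
    labels = [l for l in sorted(set(basin_labels)) if l != "unassigned"]
    for label in labels:
        frames = np.array([i for i, b in enumerate(basin_labels) if b == label])
        summary = helical_content_summary(ss_profile, frames)
        sas = sas_profile.total_sas[frames]
        rows.append({
            "basin": label,
            "n_frames": len(frames),
            "mean_alpha": summary["mean_alpha"],
            "mean_310": summary["mean_310"],
            "mean_pi": summary["mean_pi"],
            "max_alpha": summary["max_alpha"],
            "max_310": summary["max_310"],
            "max_pi": summary["max_pi"],
            "total_helical_pct": summary["total_helical_pct"],
            "sas_mean": float(sas.mean()),
            "sas_min": float(sas.min()),
            "sas_max": float(sas.max()),
        })
    return pd.DataFrame(rows)
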