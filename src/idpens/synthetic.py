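"""Synthetic ensembles, contact schedules, and charge-state distributions.

Every downstream analysis stage in this package is exercised against data
with *known* ground truth.  This module emulates the statistical structure
of a disordered-protein ensemble — a ~70-residue chain with transiently
occupied helical segments, a mixture of compact and extended states, planted
residue-pair contacts with prescribed persistence, and bimodal electrospray
charge-state distributions — without pretending to be physically realistic
dynamics.

The backbone is built residue-by-residue from ideal internal coordinates
(NeRF construction), so hydrogen-bond based secondary-structure assignment
and side-chain contact typing both work on the output.  Each residue carries
N, H, CA, C, O plus one side-chain reference pseudo-atom (named CB) placed
along the CA->CB direction at a residue-type-specific distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .ensemble_io import ConformationalEnsemble, EnsembleError, Topology

__all__ = [
    "EnsembleSpec",
    "ContactSchedule",
    "ContactPair",
    "CsdSpec",
    "GroundTruth",
    "generate_ensemble",
    "plant_contacts",
    "generate_csd",
    "ideal_chain",
    "CHARGED_BASIC",
    "CHARGED_ACIDIC",
]

# ideal backbone geometry, nm / degrees
_B_N_CA = 0.1458
_B_CA_C = 0.1525
_B_C_N = 0.1329
_B_C_O = 0.1231
_B_N_H = 0.100
_ANG_C_N_CA = 121.7
_ANG_N_CA_C = 111.2
_ANG_CA_C_N = 116.2
_ANG_CA_C_O = 120.8

HELIX_PHI = -57.0
HELIX_PSI = -47.0

CHARGED_BASIC = frozenset({"LYS", "ARG"})
CHARGED_ACIDIC = frozenset({"ASP", "GLU"})

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}

# CA -> side-chain reference distance per residue type, nm
_SC_DISTANCE = {
    "ALA": 0.152, "ARG": 0.41, "ASN": 0.25, "ASP": 0.25, "CYS": 0.21,
    "GLN": 0.31, "GLU": 0.31, "GLY": 0.11, "HIS": 0.27, "ILE": 0.24,
    "LEU": 0.26, "LYS": 0.35, "MET": 0.29, "PHE": 0.29, "PRO": 0.19,
    "SER": 0.19, "THR": 0.19, "TRP": 0.32, "TYR": 0.32, "VAL": 0.20,
}

#: default sequence motif: charged (K/E/D/R), aromatic (F/Y) and
#: hydrophobic (L/A/V) residues so that every interaction class is testable
DEFAULT_SEQUENCE_PATTERN = "SKTEDLRAGVFNQY"


def _unit(v: np.ndarray) -> np.ndarray:
    n = np.linalg.norm(v)
    if n == 0.0:
        raise ValueError("zero-length vector")
    return v / n


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from atoms A-B-C, bond |CD|, angle BCD and dihedral ABCD."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = _unit(c - b)
    n = _unit(np.cross(b - a, bc))
    m = np.cross(n, bc)
    d_local = bond * np.array(
        [-np.cos(ang), np.sin(ang) * np.cos(dih), np.sin(ang) * np.sin(dih)]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


@dataclass
class EnsembleSpec:
    """Recipe for a synthetic conformational ensemble.

    ``helical_segments`` are ``(start_res, end_res, occupancy)`` triples in
    1-based inclusive residue numbering: in each frame the segment is either
    fully helical (ideal alpha dihedrals) with probability ``occupancy`` or
    coil.  ``states`` are ``(label, weight, compactness_scale)`` triples; the
    compactness scale controls how extension-biased the state's coil
    dihedral distribution is (larger = more extended chain, larger Rg).
    """

    n_residues: int = 70
    helical_segments: list[tuple[int, int, float]] = field(
        default_factory=lambda: [(12, 24, 0.7), (30, 34, 0.3)]
    )
    states: list[tuple[str, float, float]] = field(
        default_factory=lambda: [("compact", 0.5, 1.0), ("extended", 0.5, 2.5)]
    )
    n_frames: int = 100
    coordinate_noise_sigma: float = 0.01
    dihedral_jitter_deg: float = 3.0
    sequence: str | None = None
    first_residue_id: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise EnsembleError("n_frames must be >= 1")
        if self.n_residues < 2:
            raise EnsembleError("n_residues must be >= 2")
        weights = np.array([w for _, w, _ in self.states], dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-9):
            raise EnsembleError("state weights must be >= 0 and sum to 1")
        occupied = np.zeros(self.n_residues + 1, dtype=bool)
        for start, end, occ in self.helical_segments:
            if not (1 <= start <= end <= self.n_residues):
                raise EnsembleError(f"helical segment ({start}, {end}) out of range")
            if not (0.0 <= occ <= 1.0):
                raise EnsembleError("segment occupancy must be in [0, 1]")
            if occupied[start:end + 1].any():
                raise EnsembleError(f"helical segment ({start}, {end}) overlaps another")
            occupied[start:end + 1] = True
        if self.sequence is not None and len(self.sequence) != self.n_residues:
            raise EnsembleError("sequence length differs from n_residues")

    def resolved_sequence(self) -> str:
        if self.sequence is not None:
            return self.sequence
        reps = -(-self.n_residues // len(DEFAULT_SEQUENCE_PATTERN))
        return (DEFAULT_SEQUENCE_PATTERN * reps)[: self.n_residues]


@dataclass
class GroundTruth:
    """What the generator actually planted, frame by frame."""

    state_labels: list[str]
    helix_mask: np.ndarray  # (F, R) bool: residue helical in frame
    radius_of_gyration: np.ndarray  # (F,) nm, over CA atoms
    state_definitions: list[tuple[str, float, float]]

    def state_frames(self, label: str) -> np.ndarray:
        return np.array([i for i, s in enumerate(self.state_labels) if s == label])

    def helix_occupancy(self) -> np.ndarray:
        """Per-residue fraction of frames in which the residue is helical."""
        return self.helix_mask.mean(axis=0)


def _build_topology(sequence: str, first_residue_id: int) -> Topology:
    atom_names, res_names, res_ids, elements = [], [], [], []
    for r, one in enumerate(sequence):
        three = _ONE_TO_THREE[one.upper()]
        rid = first_residue_id + r
        for name, elem in (("N", "N"), ("H", "H"), ("CA", "C"),
                           ("C", "C"), ("O", "O"), ("CB", "C")):
            atom_names.append(name)
            res_names.append(three)
            res_ids.append(rid)
            elements.append(elem)
    return Topology(atom_names, res_names, res_ids, elements)


def ideal_chain(phi: np.ndarray, psi: np.ndarray, sequence: str) -> np.ndarray:
    """Build backbone coordinates (nm) from per-residue phi/psi dihedrals.

    Returns an ``(R*6, 3)`` array in the atom order N, H, CA, C, O, CB per
    residue.  Peptide bonds are trans (omega = 180 deg); the amide H sits
    0.1 nm from N along the anti-bisector of C(i-1)-N-CA; the side-chain
    reference atom sits off the backbone at a residue-type distance.
    """
    R = len(sequence)
    phi = np.asarray(phi, dtype=float)
    psi = np.asarray(psi, dtype=float)
    if phi.shape != (R,) or psi.shape != (R,):
        raise ValueError("phi/psi must have one value per residue")
    N = np.zeros((R, 3))
    CA = np.zeros((R, 3))
    C = np.zeros((R, 3))
    # first residue in a canonical pose
    N[0] = (0.0, 0.0, 0.0)
    CA[0] = (_B_N_CA, 0.0, 0.0)
    ang = np.deg2rad(_ANG_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, R):
        N[i] = _nerf(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _ANG_CA_C_N, psi[i - 1])
        CA[i] = _nerf(CA[i - 1], C[i - 1], N[i], _B_N_CA, _ANG_C_N_CA, 180.0)
        C[i] = _nerf(C[i - 1], N[i], CA[i], _B_CA_C, _ANG_N_CA_C, phi[i])
    coords = np.zeros((R * 6, 3))
    for i in range(R):
        # carbonyl O anti to the next amide N in the peptide plane
        O = _nerf(N[i], CA[i], C[i], _B_C_O, _ANG_CA_C_O, psi[i] + 180.0)
        if i == 0:
            h_dir = _unit(_unit(N[i] - CA[i]) + np.array([0.0, -1.0, 0.0]))
        else:
            h_dir = _unit(_unit(N[i] - C[i - 1]) + _unit(N[i] - CA[i]))
        H = N[i] + _B_N_H * h_dir
        u = _unit(_unit(CA[i] - N[i]) + _unit(CA[i] - C[i]))
        v = _unit(np.cross(C[i] - CA[i], N[i] - CA[i]))
        sc_dir = _unit(u + v)
        three = _ONE_TO_THREE[sequence[i].upper()]
        CB = CA[i] + _SC_DISTANCE[three] * sc_dir
        coords[i * 6:(i + 1) * 6] = (N[i], H, CA[i], C[i], O, CB)
    return coords


def _coil_dihedrals(rng: np.random.Generator, n: int, compactness: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Draw coil phi/psi: extension-biased fraction grows with compactness scale."""
    p_ext = float(np.clip((compactness - 0.5) / 2.5, 0.02, 0.98))
    phi = np.empty(n)
    psi = np.empty(n)
    ext = rng.random(n) < p_ext
    n_ext = int(ext.sum())
    phi[ext] = rng.normal(-120.0, 20.0, n_ext)
    psi[ext] = rng.normal(135.0, 20.0, n_ext)
    # compact coil: mixture of turn-like basins
    basins = np.array([[-75.0, -35.0, 15.0], [-90.0, 5.0, 20.0], [55.0, 50.0, 10.0]])
    pick = rng.choice(3, size=n - n_ext, p=[0.5, 0.3, 0.2])
    phi[~ext] = basins[pick, 0] + rng.normal(0.0, basins[pick, 2])
    psi[~ext] = basins[pick, 1] + rng.normal(0.0, basins[pick, 2])
    return phi, psi


def generate_ensemble(spec: EnsembleSpec) -> tuple[ConformationalEnsemble, GroundTruth]:
    """Generate a synthetic ensemble with a ground-truth report.

    Each frame is assigned to a state by the state weights; its coil
    dihedrals are the state's template angles plus a small von-Mises-like
    jitter, while residues inside an occupied helical segment get ideal
    alpha-helix dihedrals.  Gaussian coordinate noise is added to all atoms.
    Fixed seed => bit-reproducible output.
    """
    rng = np.random.default_rng(spec.seed)
    seq = spec.resolved_sequence()
    R, F = spec.n_residues, spec.n_frames
    topology = _build_topology(seq, spec.first_residue_id)

    # one template coil conformation per state, drawn once
    templates = {}
    for label, _w, compactness in spec.states:
        templates[label] = _coil_dihedrals(rng, R, compactness)
    labels = [s[0] for s in spec.states]
    weights = np.array([s[1] for s in spec.states], dtype=float)

    state_idx = rng.choice(len(labels), size=F, p=weights)
    helix_mask = np.zeros((F, R), dtype=bool)
    frames = np.zeros((F, R * 6, 3))
    ca_slice = np.arange(R) * 6 + 2
    rg = np.zeros(F)
    for f in range(F):
        label = labels[state_idx[f]]
        phi0, psi0 = templates[label]
        phi = phi0 + rng.normal(0.0, spec.dihedral_jitter_deg, R)
        psi = psi0 + rng.normal(0.0, spec.dihedral_jitter_deg, R)
        for start, end, occ in spec.helical_segments:
            if rng.random() < occ:
                sl = slice(start - 1, end)
                phi[sl] = HELIX_PHI
                psi[sl] = HELIX_PSI
                helix_mask[f, sl] = True
        coords = ideal_chain(phi, psi, seq)
        coords += rng.normal(0.0, spec.coordinate_noise_sigma, coords.shape)
        frames[f] = coords
        ca = coords[ca_slice]
        rg[f] = float(np.sqrt(((ca - ca.mean(axis=0)) ** 2).sum(axis=1).mean()))
    truth = GroundTruth(
        state_labels=[labels[i] for i in state_idx],
        helix_mask=helix_mask,
        radius_of_gyration=rg,
        state_definitions=list(spec.states),
    )
    ensemble = ConformationalEnsemble(topology, frames)
    return ensemble, truth


# ---------------------------------------------------------------------------
# contact planting
# ---------------------------------------------------------------------------

@dataclass
class ContactPair:
    """One scheduled residue-pair contact.

    If ``mask`` is given it is the deterministic frame mask; otherwise a
    Bernoulli(``persistence``) mask is drawn per frame.  With neither a mask
    nor ``probabilistic=True``, an evenly spaced deterministic mask with
    exactly ``round(persistence * F)`` active frames is constructed, so the
    realized persistence equals the target exactly.
    """

    res_i: int
    res_j: int
    persistence: float
    mask: np.ndarray | None = None
    probabilistic: bool = False

    def __post_init__(self) -> None:
        if self.res_i == self.res_j:
            raise EnsembleError("contact pair must join two distinct residues")
        if not (0.0 <= self.persistence <= 1.0):
            raise EnsembleError("persistence must be in [0, 1]")

    def resolve_mask(self, n_frames: int, rng: np.random.Generator) -> np.ndarray:
        if self.mask is not None:
            m = np.asarray(self.mask, dtype=bool)
            if m.shape != (n_frames,):
                raise EnsembleError("contact mask length differs from frame count")
            return m
        if self.probabilistic:
            return rng.random(n_frames) < self.persistence
        n_on = int(round(self.persistence * n_frames))
        m = np.zeros(n_frames, dtype=bool)
        if n_on > 0:
            m[np.linspace(0, n_frames - 1, n_on).round().astype(int)] = True
        return m


@dataclass
class ContactSchedule:
    pairs: list[ContactPair]
    seed: int = 0


def _fibonacci_directions(n: int) -> np.ndarray:
    """n well-spread unit vectors (golden-spiral sphere covering)."""
    k = np.arange(n, dtype=float)
    phi = np.arccos(1.0 - 2.0 * (k + 0.5) / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * (k + 0.5)
    return np.stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)],
        axis=1,
    )


def plant_contacts(
    ensemble: ConformationalEnsemble,
    schedule: ContactSchedule,
    contact_distance: float = 0.30,
    isolate_others: bool = True,
) -> tuple[ConformationalEnsemble, dict[tuple[int, int], np.ndarray]]:
    """Plant side-chain contacts with exactly known persistence.

    For each scheduled pair and each active frame, the two side-chain
    reference atoms (CB) are moved to a dedicated, well-separated contact
    site ``contact_distance`` apart (<= 0.35 nm); in all other frames the
    scheduled residues sit at per-residue parking sites > 0.7 nm from
    everything else.  With ``isolate_others`` (default) the CB atoms of all
    *unscheduled* charged residues (Lys/Arg/Asp/Glu) are parked too, so that
    off-schedule contacts are exactly zero.  This sacrifices side-chain
    realism for exact ground truth; the backbone is untouched.

    Returns the modified ensemble and the realized per-pair frame masks.
    A residue appearing in two pairs that are active in the same frame is
    rejected (one atom cannot satisfy two contact geometries).
    """
    if not schedule.pairs:
        return ensemble, {}
    rng = np.random.default_rng(schedule.seed)
    top = ensemble.topology
    F = ensemble.n_frames
    sc_index: dict[int, int] = {}
    for a, (name, rid) in enumerate(zip(top.atom_names, top.residue_ids)):
        if name == "CB":
            sc_index[int(rid)] = a
    res_names = {int(r): n for r, n in zip(top.residue_ids, top.residue_names)}

    masks: dict[tuple[int, int], np.ndarray] = {}
    active_by_res: dict[int, np.ndarray] = {}
    for pair in schedule.pairs:
        for rid in (pair.res_i, pair.res_j):
            if rid not in sc_index:
                raise EnsembleError(
                    f"residue {rid} absent or lacking a side-chain reference atom"
                )
        m = pair.resolve_mask(F, rng)
        key = (pair.res_i, pair.res_j)
        masks[key] = m
        for rid in (pair.res_i, pair.res_j):
            prev = active_by_res.get(rid)
            if prev is not None and np.any(prev & m):
                raise EnsembleError(
                    f"residue {rid} is scheduled in two pairs active in the same frame"
                )
            active_by_res[rid] = m if prev is None else (prev | m)

    scheduled_res = sorted(active_by_res)
    parked_res = list(scheduled_res)
    if isolate_others:
        charged = CHARGED_BASIC | CHARGED_ACIDIC
        for rid, rname in res_names.items():
            if rname in charged and rid not in active_by_res and rid in sc_index:
                parked_res.append(rid)
    dirs = _fibonacci_directions(len(masks) + len(parked_res))
    pair_dirs = dirs[: len(masks)]
    park_dirs = dirs[len(masks):]

    frames = ensemble.frames.copy()
    park_of = {rid: 14.0 * d for rid, d in zip(parked_res, park_dirs)}
    for rid in parked_res:
        frames[:, sc_index[rid], :] = park_of[rid]
    for p, (key, m) in enumerate(masks.items()):
        d = pair_dirs[p]
        t = _unit(np.cross(d, [0.0, 0.0, 1.0]) if abs(d[2]) < 0.9
                  else np.cross(d, [1.0, 0.0, 0.0]))
        site = 10.0 * d
        half = 0.5 * contact_distance
        frames[m, sc_index[key[0]], :] = site - half * t
        frames[m, sc_index[key[1]], :] = site + half * t
    labels = list(ensemble.frame_labels) if ensemble.frame_labels is not None else None
    return ConformationalEnsemble(top, frames, labels), masks


# ---------------------------------------------------------------------------
# charge-state distributions
# ---------------------------------------------------------------------------

@dataclass
class CsdSpec:
    """Recipe for a synthetic charge-state distribution.

    ``components`` are ``(mean_z, sigma_z, area)`` triples; the intensity at
    each integer charge is the sum of the component Gaussian densities times
    their areas, with multiplicative relative noise.
    """

    components: list[tuple[float, float, float]]
    charge_range: tuple[int, int] = (1, 20)
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.components:
            raise EnsembleError("CsdSpec needs at least one component")
        for mean, sigma, area in self.components:
            if sigma <= 0:
                raise EnsembleError("component sigma must be > 0")
            if area <= 0:
                raise EnsembleError("component area must be > 0")
        if self.charge_range[0] >= self.charge_range[1]:
            raise EnsembleError("charge_range must satisfy z_min < z_max")
        if self.noise_sigma < 0:
            raise EnsembleError("noise_sigma must be >= 0")


def generate_csd(spec: CsdSpec):
    """Synthesize a charge-state distribution plus its ground truth.

    Returns ``(ChargeStateDistribution, ground_truth)`` where the ground
    truth dict records the planted component parameters and area fractions.
    """
    from .csd_ms import ChargeStateDistribution

    rng = np.random.default_rng(spec.seed)
    z = np.arange(spec.charge_range[0], spec.charge_range[1] + 1)
    intensity = np.zeros(z.shape, dtype=float)
    for mean, sigma, area in spec.components:
        intensity += area / (sigma * np.sqrt(2 * np.pi)) * np.exp(
            -0.5 * ((z - mean) / sigma) ** 2
        )
    if spec.noise_sigma > 0:
        intensity = intensity * (1.0 + spec.noise_sigma * rng.standard_normal(z.shape))
    intensity = np.clip(intensity, 0.0, None)
    areas = np.array([c[2] for c in spec.components], dtype=float)
    truth = {
        "means": np.array([c[0] for c in spec.components], dtype=float),
        "sigmas": np.array([c[1] for c in spec.components], dtype=float),
        "areas": areas,
        "fractions": areas / areas.sum(),
    }
    return ChargeStateDistribution(list(z), list(intensity)), truth
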