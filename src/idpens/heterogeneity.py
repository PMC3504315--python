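"""Conformational heterogeneity: Gromos clustering and the order parameter O.

The Gromos algorithm greedily partitions an ensemble using the pairwise
RMSD matrix: the frame with the most neighbors within the cutoff becomes a
cluster center, it and its neighbors are removed, and the procedure repeats
until every frame is assigned.  Cluster weights are relative sizes
(members / total frames).

The ensemble-disorder order parameter over representative conformations
s_1..s_n with weights w_i is

    O = sum_i w_i * log2[ 1 + sum_j w_j * exp( -D^2(s_i, s_j) / (2 <D^2>) ) ]

where D^2 is the Calpha mean-square distance between two structures after
optimal superposition and <D^2> is the pairwise MSD expected from the
fluctuations of a typical folded protein (0.27 nm^2 by default; the scale
is exposed because the literature value is dimensionally ambiguous).
O = 1 for a single conformation and tends to 0 for an infinite number of
equally populated, mutually distant conformations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble_io import (
    ConformationalEnsemble,
    EnsembleError,
    StructuralModel,
    kabsch_fit,
    pairwise_rmsd_matrix,
)

__all__ = [
    "ClusterSet",
    "OrderParameterResult",
    "GromosClustering",
    "gromos_cluster",
    "gromos_partition_from_matrix",
    "order_parameter",
    "order_parameter_from_msd",
    "order_parameter_uniform",
    "disorder_profile",
    "DEFAULT_MSD_SCALE",
]

#: reference mean-square distance <D^2> (nm^2)
DEFAULT_MSD_SCALE = 0.27


@dataclass
class Cluster:
    members: np.ndarray  # frame indices
    center: int          # Gromos center (max-neighbor frame)
    medoid: int          # lowest mean RMSD to the other members
    weight: float


@dataclass
class ClusterSet:
    clusters: list[Cluster]
    rmsd_cutoff: float
    selection: str

    def __post_init__(self) -> None:
        w = sum(c.weight for c in self.clusters)
        if abs(w - 1.0) > 1e-9:
            raise EnsembleError(f"cluster weights sum to {w}, expected 1")

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    @property
    def weights(self) -> np.ndarray:
        return np.array([c.weight for c in self.clusters])

    @property
    def medoid_frames(self) -> list[int]:
        return [c.medoid for c in self.clusters]

    def labels(self, n_frames: int) -> np.ndarray:
        lab = np.full(n_frames, -1, dtype=int)
        for k, c in enumerate(self.clusters):
            lab[c.members] = k
        return lab


def gromos_partition_from_matrix(rmsd: np.ndarray, cutoff: float
                                 ) -> list[tuple[np.ndarray, int, int]]:
    """Greedy Gromos partition of a precomputed RMSD matrix.

    Returns (members, center, medoid) per cluster, in extraction order.
    Ties in neighbor count are broken by the lowest frame index.
    """
    if cutoff <= 0:
        raise EnsembleError("rmsd_cutoff must be > 0")
    F = rmsd.shape[0]
    remaining = np.ones(F, dtype=bool)
    within = rmsd <= cutoff
    out = []
    while remaining.any():
        counts = (within & remaining[None, :]).sum(axis=1)
        counts[~remaining] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        members = np.where(within[center] & remaining)[0]
        sub = rmsd[np.ix_(members, members)]
        if len(members) == 1:
            medoid = int(members[0])
        else:
            mean_to_others = sub.sum(axis=1) / (len(members) - 1)
            medoid = int(members[int(np.argmin(mean_to_others))])
        out.append((members, center, medoid))
        remaining[members] = False
    return out


class GromosClustering:
    """Gromos RMSD clustering, sklearn-estimator style.

    Parameters
    ----------
    cutoff : float
        RMSD neighbor cutoff in nm (0.4 nm is the conventional default).
    selection : str
        Atom selection for the RMSD ("mainchain", "ca", "all").
    fit_pairs : bool
        Re-superpose each frame pair before its RMSD (default True).

    Attributes (after ``fit``)
    --------------------------
    labels_ : (F,) cluster index per frame
    clusters_ : :class:`ClusterSet`
    rmsd_matrix_ : the F x F matrix used
    """

    def __init__(self, cutoff: float = 0.4, selection: str = "mainchain",
                 fit_pairs: bool = True):
        self.cutoff = cutoff
        self.selection = selection
        self.fit_pairs = fit_pairs

    def get_params(self, deep: bool = True) -> dict:
        return {"cutoff": self.cutoff, "selection": self.selection,
                "fit_pairs": self.fit_pairs}

    def set_params(self, **params) -> "GromosClustering":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, ensemble: ConformationalEnsemble) -> "GromosClustering":
        if self.cutoff <= 0:
            raise EnsembleError("rmsd_cutoff must be > 0")
        if ensemble.n_frames == 1:
            rmsd = np.zeros((1, 1))
        else:
            rmsd = pairwise_rmsd_matrix(ensemble, self.selection, fit=self.fit_pairs)
        parts = gromos_partition_from_matrix(rmsd, self.cutoff)
        F = ensemble.n_frames
        clusters = [Cluster(m, c, md, len(m) / F) for m, c, md in parts]
        sel = self.selection if isinstance(self.selection, str) else "custom"
        self.clusters_ = ClusterSet(clusters, self.cutoff, sel)
        self.labels_ = self.clusters_.labels(F)
        self.rmsd_matrix_ = rmsd
        return self

    def fit_predict(self, ensemble: ConformationalEnsemble) -> np.ndarray:
        return self.fit(ensemble).labels_


def gromos_cluster(ensemble: ConformationalEnsemble, rmsd_cutoff: float = 0.4,
                   selection: str = "mainchain", fit_pairs: bool = True) -> ClusterSet:
    """Cluster an ensemble with the Gromos algorithm (see class docs)."""
    est = GromosClustering(rmsd_cutoff, selection, fit_pairs)
    return est.fit(ensemble).clusters_


# ---------------------------------------------------------------------------
# order parameter
# ---------------------------------------------------------------------------

@dataclass
class OrderParameterResult:
    O: float
    msd_scale: float
    cutoff: float | None
    n_clusters: int
    weights: np.ndarray

    def __post_init__(self) -> None:
        if not (0.0 < self.O <= 1.0 + 1e-12):
            raise EnsembleError(f"order parameter {self.O} outside (0, 1]")


def order_parameter_from_msd(msd: np.ndarray, weights: np.ndarray,
                             msd_scale: float = DEFAULT_MSD_SCALE) -> float:
    """O from a precomputed pairwise mean-square-distance matrix (nm^2)."""
    msd = np.asarray(msd, dtype=float)
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise EnsembleError("weights must be non-negative")
    if abs(w.sum() - 1.0) > 1e-6:
        raise EnsembleError(f"weights sum to {w.sum()}, expected 1")
    if msd.shape != (w.size, w.size):
        raise EnsembleError("MSD matrix shape inconsistent with weights")
    inner = np.exp(-msd / (2.0 * msd_scale)) @ w
    return float(np.sum(w * np.log2(1.0 + inner)))


def order_parameter_uniform(n: int, d2_over_scale: float) -> float:
    """O for n equally weighted conformations with equal pairwise D^2.

    Closed-form evaluation (no n x n matrix): with uniform weights 1/n and
    all off-diagonal D^2/<D^2> = ``d2_over_scale``,

        O = log2[ 1 + 1/n + (1 - 1/n) * exp(-d2_over_scale / 2) ].

    For well-separated conformations this converges to log2(1 + 1/n) and
    hence to 0 as n grows without bound.
    """
    if n < 1:
        raise EnsembleError("n must be >= 1")
    w = 1.0 / n
    inner = w + (1.0 - w) * np.exp(-0.5 * d2_over_scale)
    return float(np.log2(1.0 + inner))


def _ca_coordinates(model: StructuralModel) -> np.ndarray:
    idx = [i for i, a in enumerate(model.atom_names) if a == "CA"]
    if not idx:
        raise EnsembleError("representative lacks CA atoms")
    return model.coordinates[idx]


def pairwise_ca_msd(representatives: list[StructuralModel],
                    fit_pairs: bool = True) -> np.ndarray:
    """Pairwise Calpha mean-square distances (nm^2) between representatives."""
    cas = [_ca_coordinates(m) for m in representatives]
    n_ca = {c.shape[0] for c in cas}
    if len(n_ca) != 1:
        raise EnsembleError("representatives have mismatched Calpha counts")
    n = len(cas)
    msd = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            if fit_pairs:
                _, _, rmsd = kabsch_fit(cas[j], cas[i])
                d2 = rmsd ** 2
            else:
                d2 = float(np.mean(np.sum((cas[i] - cas[j]) ** 2, axis=1)))
            msd[i, j] = msd[j, i] = d2
    return msd


def order_parameter(representatives: list[StructuralModel],
                    weights,
                    msd_scale: float = DEFAULT_MSD_SCALE,
                    fit_pairs: bool = True,
                    cutoff: float | None = None) -> OrderParameterResult:
    """Ensemble order parameter O over representative conformations.

    ``D^2(s_i, s_j)`` is the squared Calpha RMSD after pairwise optimal
    superposition (set ``fit_pairs=False`` to compare coordinates as
    stored).
    """
    w = np.asarray(weights, dtype=float)
    if len(representatives) != w.size:
        raise EnsembleError("one weight per representative required")
    msd = pairwise_ca_msd(representatives, fit_pairs=fit_pairs)
    O = order_parameter_from_msd(msd, w, msd_scale)
    return OrderParameterResult(O, msd_scale, cutoff, len(representatives), w)


def disorder_profile(ensemble: ConformationalEnsemble,
                     cutoffs=(0.4, 0.5, 0.6),
                     selection: str = "mainchain",
                     msd_scale: float = DEFAULT_MSD_SCALE) -> pd.DataFrame:
    """Cluster at each cutoff, then compute O over medoids and weights.

    Returns a table with columns (cutoff_nm, n_clusters, order_parameter) —
    the end-to-end workflow behind a cutoff/cluster-count/O summary.
    """
    rows = []
    for cutoff in cutoffs:
        cs = gromos_cluster(ensemble, cutoff, selection)
        reps = [ensemble.model(f) for f in cs.medoid_frames]
        res = order_parameter(reps, cs.weights, msd_scale, cutoff=cutoff)
        rows.append({"cutoff_nm": float(cutoff),
                     "n_clusters": cs.n_clusters,
                     "order_parameter": res.O})
    return pd.DataFrame(rows)
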