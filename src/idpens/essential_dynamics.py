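"""Essential dynamics: covariance PCA of positional fluctuations and RMSIP.

The essential-dynamics picture decomposes the (optionally mass-weighted)
covariance matrix C of atomic positional fluctuations about the ensemble
mean; the leading eigenvectors describe the dominant collective motions and
projections onto them serve as reaction coordinates for free-energy
landscapes.  Subspace convergence between independent trajectories is
measured by the root mean square inner product (RMSIP) of the leading
eigenvector sets:

    RMSIP = sqrt( (1/D) * sum_{i<=D} sum_{j<=D} (eta_i^A . eta_j^B)^2 )

which is 1 for identical subspaces and 0 for orthogonal ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ensemble_io import ConformationalEnsemble, EnsembleError, selection_indices

__all__ = [
    "EigenDecomposition",
    "ProjectionSet",
    "EssentialDynamicsPCA",
    "fit_pca",
    "project_frames",
    "cumulative_variance",
    "rmsip",
]

#: standard atomic masses (amu); pseudo-atoms fall back to carbon
ATOMIC_MASSES = {
    "H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06,
    "P": 30.974, "Se": 78.971,
}
DEFAULT_MASS = 12.011

# above this flattened dimension the F x F dual decomposition is used
_DUAL_THRESHOLD = 3000


@dataclass
class EigenDecomposition:
    """Eigenvectors/eigenvalues of the positional covariance.

    ``eigenvectors`` has shape (n_modes, 3*A_sel) with rows sorted by
    descending eigenvalue; eigenvalues are nm^2 (nm^2*amu if mass-weighted).
    """

    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    mean_structure: np.ndarray  # (A_sel, 3), nm
    selection: str
    mass_weighted: bool
    masses: np.ndarray  # (A_sel,), amu (ones if not mass-weighted)

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise EnsembleError("eigenvalues must be sorted descending")
        if np.any(self.eigenvalues < -1e-10):
            raise EnsembleError("eigenvalues must be non-negative")
        self.eigenvalues = np.clip(self.eigenvalues, 0.0, None)

    @property
    def n_modes(self) -> int:
        return self.eigenvectors.shape[0]


@dataclass
class ProjectionSet:
    """Per-frame projections onto the leading eigenvectors (F x K)."""

    values: np.ndarray
    eig: EigenDecomposition

    def coordinate(self, k: int) -> np.ndarray:
        """The k-th (1-based) principal-component reaction coordinate."""
        return self.values[:, k - 1]


class EssentialDynamicsPCA:
    """Covariance PCA over an ensemble, sklearn-estimator style.

    Parameters
    ----------
    selection : {"ca", "all", "mainchain"} or index array
        Atoms entering the covariance.  The ensemble is assumed to be
        superposed already (see :func:`idpens.superpose_ensemble`).
    mass_weighted : bool
        Weight coordinates by sqrt(atomic mass) before the covariance.
    n_components : int or None
        Number of eigenvectors to retain (None = all).

    Attributes (after ``fit``)
    --------------------------
    eigenvectors_ : (n_modes, 3*A_sel) array
    eigenvalues_ : (n_modes,) array, descending
    mean_ : (A_sel, 3) array
    """

    def __init__(self, selection="ca", mass_weighted: bool = False,
                 n_components: int | None = None):
        self.selection = selection
        self.mass_weighted = mass_weighted
        self.n_components = n_components

    # minimal sklearn plumbing -------------------------------------------------
    def get_params(self, deep: bool = True) -> dict:
        return {
            "selection": self.selection,
            "mass_weighted": self.mass_weighted,
            "n_components": self.n_components,
        }

    def set_params(self, **params) -> "EssentialDynamicsPCA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    # --------------------------------------------------------------------------
    def _weighted_displacements(self, ensemble: ConformationalEnsemble,
                                idx: np.ndarray, mean: np.ndarray,
                                sqrt_m: np.ndarray) -> np.ndarray:
        disp = ensemble.frames[:, idx, :] - mean[None]
        return (disp * sqrt_m[None, :, None]).reshape(ensemble.n_frames, -1)

    def fit(self, ensemble: ConformationalEnsemble) -> "EssentialDynamicsPCA":
        if ensemble.n_frames < 2:
            raise EnsembleError("PCA needs at least 2 frames (no fluctuations in 1)")
        idx = selection_indices(ensemble.topology, self.selection)
        if idx.size == 0:
            raise EnsembleError("empty atom selection")
        if self.mass_weighted:
            masses = np.array(
                [ATOMIC_MASSES.get(ensemble.topology.elements[i], DEFAULT_MASS)
                 for i in idx]
            )
        else:
            masses = np.ones(idx.size)
        sqrt_m = np.sqrt(masses)
        mean = ensemble.frames[:, idx, :].mean(axis=0)
        Y = self._weighted_displacements(ensemble, idx, mean, sqrt_m)
        F, D = Y.shape
        if D <= _DUAL_THRESHOLD:
            C = Y.T @ Y / F
            evals, evecs = np.linalg.eigh(C)
            order = np.argsort(evals)[::-1]
            evals = evals[order]
            evecs = evecs[:, order].T  # rows
        else:
            # dual trick: eigendecompose the F x F Gram matrix
            G = Y @ Y.T / F
            gvals, gvecs = np.linalg.eigh(G)
            order = np.argsort(gvals)[::-1]
            gvals = np.clip(gvals[order], 0.0, None)
            gvecs = gvecs[:, order]
            nz = gvals > 1e-14 * max(gvals[0], 1.0)
            vecs = (Y.T @ gvecs[:, nz]) / np.sqrt(F * gvals[nz])[None, :]
            evals = gvals[nz]  # only the resolvable (nonzero) modes
            evecs = vecs.T
        evals = np.clip(evals, 0.0, None)
        k = self.n_components or len(evals)
        self.eigenvalues_ = evals[:k]
        self.eigenvectors_ = np.ascontiguousarray(evecs[:k])
        self.mean_ = mean
        self.masses_ = masses
        self.atom_indices_ = idx
        self.total_variance_ = float(evals.sum())
        return self

    def transform(self, ensemble: ConformationalEnsemble,
                  k: int | None = None) -> np.ndarray:
        """Project frames onto the first ``k`` eigenvectors (F x k)."""
        if not hasattr(self, "eigenvectors_"):
            raise EnsembleError("PCA not fitted")
        k = k if k is not None else self.eigenvectors_.shape[0]
        if k > self.eigenvectors_.shape[0]:
            raise EnsembleError(f"requested {k} components, only "
                                f"{self.eigenvectors_.shape[0]} available")
        idx = self.atom_indices_
        if ensemble.topology.n_atoms <= int(idx.max()):
            raise EnsembleError("ensemble does not match the fitted selection")
        Y = self._weighted_displacements(ensemble, idx, self.mean_,
                                         np.sqrt(self.masses_))
        return Y @ self.eigenvectors_[:k].T

    def fit_transform(self, ensemble: ConformationalEnsemble,
                      k: int | None = None) -> np.ndarray:
        return self.fit(ensemble).transform(ensemble, k)

    def decomposition(self) -> EigenDecomposition:
        sel = self.selection if isinstance(self.selection, str) else "custom"
        return EigenDecomposition(
            eigenvectors=self.eigenvectors_,
            eigenvalues=self.eigenvalues_,
            mean_structure=self.mean_,
            selection=sel,
            mass_weighted=self.mass_weighted,
            masses=self.masses_,
        )


def fit_pca(ensemble: ConformationalEnsemble, selection="ca",
            mass_weighted: bool = False) -> EigenDecomposition:
    """PCA of the positional-fluctuation covariance (see class docs)."""
    est = EssentialDynamicsPCA(selection=selection, mass_weighted=mass_weighted)
    return est.fit(ensemble).decomposition()


def project_frames(ensemble: ConformationalEnsemble, eig: EigenDecomposition,
                   k: int) -> ProjectionSet:
    """Project each frame onto the first ``k`` eigenvectors."""
    if k > eig.n_modes:
        raise EnsembleError(f"k={k} exceeds available eigenvectors ({eig.n_modes})")
    sel = eig.selection if eig.selection != "custom" else "all"
    idx = selection_indices(ensemble.topology, sel)
    if idx.size != eig.mean_structure.shape[0]:
        raise EnsembleError("ensemble selection does not match the decomposition")
    disp = ensemble.frames[:, idx, :] - eig.mean_structure[None]
    Y = (disp * np.sqrt(eig.masses)[None, :, None]).reshape(ensemble.n_frames, -1)
    return ProjectionSet(Y @ eig.eigenvectors[:k].T, eig)


def cumulative_variance(eig: EigenDecomposition, k: int) -> float:
    """Fraction of total variance captured by the first ``k`` eigenvectors."""
    if k < 1:
        raise EnsembleError("k must be >= 1")
    total = float(eig.eigenvalues.sum())
    if total == 0.0:
        return 1.0
    return float(eig.eigenvalues[:min(k, len(eig.eigenvalues))].sum() / total)


def rmsip(eig_a, eig_b, d: int = 10) -> float:
    """Root mean square inner product of two leading-eigenvector sets.

    Accepts :class:`EigenDecomposition` objects or plain (n_modes, dim)
    arrays of orthonormal row vectors.
    """
    A = eig_a.eigenvectors if isinstance(eig_a, EigenDecomposition) else np.asarray(eig_a)
    B = eig_b.eigenvectors if isinstance(eig_b, EigenDecomposition) else np.asarray(eig_b)
    if A.shape[1] != B.shape[1]:
        raise EnsembleError("eigenvector dimensions differ between the two sets")
    if d > A.shape[0] or d > B.shape[0]:
        raise EnsembleError(f"d={d} exceeds the available eigenvectors")
    M = A[:d] @ B[:d].T
    return float(np.sqrt(np.sum(M * M) / d))
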