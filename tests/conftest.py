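import numpy as np
import pytest

from idpens.ensemble_io import ConformationalEnsemble, Topology
from idpens.synthetic import EnsembleSpec, generate_ensemble, ideal_chain, _build_topology


def make_point_ensemble(frames: np.ndarray, atom_name="CA", element="C",
                        residue_name="ALA") -> ConformationalEnsemble:
    """Ensemble of bare points, one residue per atom (for geometry tests)."""
    A = frames.shape[1]
    top = Topology([atom_name] * A, [residue_name] * A,
                   list(range(1, A + 1)), [element] * A)
    return ConformationalEnsemble(top, frames)


def make_chain_ensemble(phi_psi_list, sequence) -> ConformationalEnsemble:
    """Ensemble built from explicit per-frame (phi, psi) dihedral arrays."""
    frames = np.stack([ideal_chain(phi, psi, sequence)
                       for phi, psi in phi_psi_list])
    return ConformationalEnsemble(_build_topology(sequence, 1), frames)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_ensemble(rng):
    """20 frames of 5 free atoms with mild scatter."""
    base = rng.normal(size=(5, 3))
    frames = base[None] + 0.1 * rng.normal(size=(20, 5, 3))
    return make_point_ensemble(frames)


@pytest.fixture
def two_state_ensemble():
    spec = EnsembleSpec(
        n_residues=30,
        n_frames=60,
        helical_segments=[(5, 15, 0.5)],
        states=[("compact", 0.5, 1.0), ("extended", 0.5, 2.5)],
        seed=42,
    )
    return generate_ensemble(spec)
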