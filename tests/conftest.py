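import numpy as np
import pytest

from statescan import (StructureModel, Topology, Trajectory, TwoStateSpec,
                       build_toy_gtpase, simulate_two_state_trajectory)


@pytest.fixture(scope="session")
def base_model() -> StructureModel:
    """The default closed-state pseudo-GTPase."""
    return build_toy_gtpase()


@pytest.fixture(scope="session")
def two_state(base_model):
    """A medium two-state ensemble (p_active = 0.5) with ground truth."""
    spec = TwoStateSpec.from_base(base_model, p_active=0.5, n_frames=2000, seed=42)
    return simulate_two_state_trajectory(base_model, spec)


def make_topology(n_atoms: int, resseq_per_atom=None) -> Topology:
    """A generic all-carbon topology for geometric toy systems."""
    seqs = resseq_per_atom if resseq_per_atom is not None else np.arange(1, n_atoms + 1)
    return Topology(
        serials=np.arange(1, n_atoms + 1),
        names=["CA"] * n_atoms,
        residue_names=["GLY"] * n_atoms,
        chain_ids=["A"] * n_atoms,
        residue_seqs=seqs,
        elements=["C"] * n_atoms,
        is_hetero=[False] * n_atoms,
    )


def make_trajectory(coords: np.ndarray, resseq_per_atom=None) -> Trajectory:
    coords = np.asarray(coords, float)
    return Trajectory(make_topology(coords.shape[1], resseq_per_atom), coords)


def random_trajectory(rng: np.random.Generator, n_frames: int, n_atoms: int,
                      scale: float = 3.0) -> Trajectory:
    base = rng.uniform(-5, 5, size=(n_atoms, 3))
    coords = base[None] + rng.normal(0, scale / 3, size=(n_frames, n_atoms, 3))
    return make_trajectory(coords)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
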