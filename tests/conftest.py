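import numpy as np
import pytest

from pmmfep import (
    EnvironmentFrame,
    PerturbationSample,
    QCPoint,
    QCProfile,
    ReactionCoordinateSpec,
    ToySystemSpec,
    make_toy_qc,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_spec():
    """Fast toy-system spec for unit tests (full-size runs live in acceptance)."""
    return ToySystemSpec(n_points=7, n_frames=400, seed=11)


@pytest.fixture
def small_profile(small_spec):
    return make_toy_qc(small_spec)


@pytest.fixture
def two_state_point():
    """Minimal hand-built two-state, two-atom QC point."""
    return QCPoint(
        index=0,
        elements=["S", "O"],
        geometry=np.array([[0.0, 0.0, 0.0], [1.5, 0.0, 0.0]]),
        state_energies=np.array([-1.0, -0.9]),
        dipole_matrix=np.array(
            [
                [[0.1, 0.0, 0.0], [0.05, 0.02, 0.0]],
                [[0.05, 0.02, 0.0], [0.2, 0.0, 0.0]],
            ]
        ),
        atomic_charges=np.array([[0.3, -0.3], [0.1, -0.1]]),
        total_charge=0,
        xi=-1.0,
    )


def make_point(charges, total_charge=0, dipoles=None, energies=(-1.0, -0.5),
               geometry=None, elements=None, xi=0.0, index=0):
    charges = np.atleast_2d(np.asarray(charges, dtype=float))
    m = len(energies)
    if charges.shape[0] == 1:
        charges = np.tile(charges, (m, 1))
    n = charges.shape[1]
    if geometry is None:
        geometry = np.column_stack([np.arange(n, dtype=float), np.zeros(n), np.zeros(n)])
    if elements is None:
        elements = ["C"] * n
    if dipoles is None:
        dipoles = np.zeros((m, m, 3))
    return QCPoint(
        index=index, elements=elements, geometry=np.asarray(geometry, dtype=float),
        state_energies=np.asarray(energies, dtype=float),
        dipole_matrix=np.asarray(dipoles, dtype=float),
        atomic_charges=charges, total_charge=total_charge, xi=xi,
    )


def zero_sample(n_atoms):
    return PerturbationSample(
        potential_at_atoms=np.zeros(n_atoms),
        field_at_origin=np.zeros(3),
        potential_at_origin=0.0,
    )


def random_frame(rng, n=50, box=None, charge_scale=1.0):
    span = np.asarray(box) if box is not None else np.array([20.0, 20.0, 20.0])
    return EnvironmentFrame(
        charges=charge_scale * rng.uniform(-1, 1, n),
        positions=rng.uniform(0, 1, (n, 3)) * span,
        molecule_ids=np.arange(n),
        box=None if box is None else np.asarray(box, dtype=float),
    )
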