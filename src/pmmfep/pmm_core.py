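"""Perturbed electronic Hamiltonian construction and diagonalization.

The perturbed matrix method represents the quantum center (QC) in the
basis of its M unperturbed electronic eigenstates and adds, per classical
configuration, the electrostatic perturbation of the environment:

    H = H0 + V

Diagonal elements use the atom-based monopole expansion — each state's
ESP atomic charges times the environment potential at the corresponding
atomic center — plus the QC-level permanent-dipole coupling to the field
at the center of mass; off-diagonal elements use the QC-based dipolar
approximation (field at the center of mass dotted into the transition
dipoles):

    H_kk = E_k0 + Σ_N q_{N,k} V(R_N) − E(r0)·μ_kk
    H_kl = −E(r0)·μ_kl                      (k ≠ l)

Diagonalizing H per frame yields the perturbed ground-state energy that
feeds the free-energy estimators. Higher atom-based terms (local fields
times atomic dipoles) require per-atom, per-state dipole inputs that the
unperturbed data set does not carry; the field coupling is therefore kept
at the QC level. The ``include_permanent_dipole`` flag drops the
−E(r0)·μ_kk term from the diagonal for sensitivity checks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .environment import PerturbationSample
from .errors import ContractError, InvariantError
from .qc_model import QCPoint
from .units import HARTREE_TO_KCAL

SYMMETRY_TOL = 1e-12   # Hartree; asymmetry above this is an error
DEGENERACY_TOL = 1e-9  # Hartree; ground-state gap below this is flagged


@dataclass
class PerturbedResult:
    """Eigenvalues/ground state of one perturbed Hamiltonian (Hartree)."""

    eigenvalues: np.ndarray
    ground_energy: float
    ground_vector: np.ndarray
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.eigenvalues = np.asarray(self.eigenvalues, dtype=float)
        self.ground_vector = np.asarray(self.ground_vector, dtype=float)
        if np.any(np.diff(self.eigenvalues) < 0):
            raise InvariantError("eigenvalues must be ascending")
        if abs(np.linalg.norm(self.ground_vector) - 1.0) > 1e-10:
            raise InvariantError("ground_vector is not normalized")


@dataclass
class EnergyTrace:
    """Per-frame perturbed ground-state energies for one ensemble (Hartree)."""

    point_index: int
    energies: np.ndarray
    frame_stride_ps: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        if self.energies.size < 1:
            raise InvariantError("energy trace must have at least one frame")
        if not np.all(np.isfinite(self.energies)):
            raise InvariantError("energy trace contains non-finite values")

    @property
    def n_frames(self) -> int:
        return self.energies.size


def build_hamiltonian(
    point: QCPoint,
    sample: PerturbationSample,
    include_permanent_dipole: bool = True,
) -> np.ndarray:
    """Assemble the M×M perturbed Hamiltonian (Hartree) for one frame."""
    if sample.potential_at_atoms.shape != (point.n_atoms,):
        raise ContractError(
            f"sample has {sample.potential_at_atoms.shape[0]} atomic potentials, "
            f"QC point has {point.n_atoms} atoms"
        )
    m = point.n_states
    # field coupling: -E(r0)·μ_kl for every matrix element
    field_term = -np.einsum("i,kli->kl", sample.field_at_origin, point.dipole_matrix)
    if not include_permanent_dipole:
        np.fill_diagonal(field_term, 0.0)
    h = field_term
    diag = point.state_energies + point.atomic_charges @ sample.potential_at_atoms
    h[np.arange(m), np.arange(m)] = np.diag(field_term) + diag
    return 0.5 * (h + h.T)


def diagonalize(h: np.ndarray, degeneracy_tol: float = DEGENERACY_TOL) -> PerturbedResult:
    """Exact eigendecomposition of a symmetric perturbed Hamiltonian.

    Asymmetry above ``SYMMETRY_TOL`` Hartree is a contract error; smaller
    asymmetry is silently symmetrized. A ground-state gap below
    ``degeneracy_tol`` sets the ``degenerate`` flag (the energy is still
    the lowest eigenvalue).
    """
    h = np.asarray(h, dtype=float)
    if h.ndim != 2 or h.shape[0] != h.shape[1]:
        raise ContractError(f"Hamiltonian must be square, got shape {h.shape}")
    asym = np.max(np.abs(h - h.T)) if h.size else 0.0
    if asym > SYMMETRY_TOL:
        raise ContractError(f"Hamiltonian asymmetry {asym:.3e} Hartree exceeds {SYMMETRY_TOL}")
    h = 0.5 * (h + h.T)
    vals, vecs = np.linalg.eigh(h)
    degenerate = bool(len(vals) > 1 and (vals[1] - vals[0]) < degeneracy_tol)
    return PerturbedResult(
        eigenvalues=vals,
        ground_energy=float(vals[0]),
        ground_vector=vecs[:, 0],
        degenerate=degenerate,
    )


def _stack_samples(
    point: QCPoint, samples: Sequence[PerturbationSample]
) -> tuple[np.ndarray, np.ndarray]:
    pots = np.stack([s.potential_at_atoms for s in samples])
    fields = np.stack([s.field_at_origin for s in samples])
    if pots.shape[1] != point.n_atoms:
        raise ContractError(
            f"samples carry {pots.shape[1]} atomic potentials, QC point has {point.n_atoms} atoms"
        )
    return pots, fields


def ensemble_energies(
    point: QCPoint,
    samples: Sequence[PerturbationSample],
    include_permanent_dipole: bool = True,
    frame_stride_ps: float | None = None,
) -> EnergyTrace:
    """Perturbed ground-state energy for every frame of an ensemble.

    Vectorized over frames (one batched ``eigh`` call); frame order is
    preserved. Identical, frame by frame, to calling
    ``diagonalize(build_hamiltonian(point, s))`` in a loop.
    """
    if len(samples) == 0:
        raise InvariantError("need at least one perturbation sample")
    pots, fields = _stack_samples(point, samples)
    m = point.n_states
    f = len(samples)
    hs = -np.einsum("fi,kli->fkl", fields, point.dipole_matrix)
    if not include_permanent_dipole:
        hs[:, np.arange(m), np.arange(m)] = 0.0
    diag = point.state_energies[None, :] + pots @ point.atomic_charges.T  # (F, M)
    hs[:, np.arange(m), np.arange(m)] += diag
    hs = 0.5 * (hs + np.swapaxes(hs, 1, 2))
    vals = np.linalg.eigvalsh(hs)
    return EnergyTrace(
        point_index=point.index,
        energies=vals[:, 0],
        frame_stride_ps=frame_stride_ps,
    )


def write_energy_trace(trace: EnergyTrace, path) -> None:
    """Columnar text: frame index, energy in Hartree and in kcal/mol."""
    with open(path, "w") as fh:
        fh.write(f"# point_index {trace.point_index}\n")
        if trace.frame_stride_ps is not None:
            fh.write(f"# frame_stride_ps {trace.frame_stride_ps}\n")
        fh.write("# frame\tenergy_hartree\tenergy_kcal_mol\n")
        for i, e in enumerate(trace.energies):
            fh.write(f"{i}\t{float(e)!r}\t{float(e * HARTREE_TO_KCAL)!r}\n")


def read_energy_trace(path) -> EnergyTrace:
    point_index = 0
    stride = None
    energies = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("# point_index"):
                point_index = int(line.split()[-1])
            elif line.startswith("# frame_stride_ps"):
                stride = float(line.split()[-1])
            elif not line or line.startswith("#"):
                continue
            else:
                energies.append(float(line.split("\t")[1]))
    return EnergyTrace(point_index=point_index, energies=np.array(energies),
                       frame_stride_ps=stride)
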