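"""Data model and I/O for the unperturbed quantum-center (QC) profile.

A QC profile describes the quantum subsystem of a hybrid QM/MM free-energy
calculation at a set of points scanned along a chemical reaction coordinate.
Each point carries the gas-phase (unperturbed) electronic structure data that
the perturbed-matrix construction needs: geometry, electronic state energies,
the permanent/transition dipole matrix, and per-state ESP atomic charges.

The reaction coordinate ξ is the difference between the breaking and the
forming bond distances along the scanned path (e.g. d(O–O) − d(S–O) for a
sulfide oxidation, d(Sc–Slg) − d(Sc–Snu) for a thiolate/disulfide exchange).

File format
-----------
Profiles are stored as a versioned JSON document::

    {
      "schema_version": 1,
      "coordinate_spec": {"bond_break": [i, j], "bond_form": [k, l]},
      "metadata": {"...": "free-form provenance strings"},
      "points": [
        {
          "index": 0,
          "xi": -2.0,                      # Å
          "elements": ["S", "O", ...],
          "geometry": [[x, y, z], ...],    # Å
          "state_energies": [E0, E1, ...], # Hartree, ground first
          "dipole_matrix": [[[x,y,z], ...], ...],  # a.u., M x M x 3
          "total_charge": 0,               # e
          "atomic_charges": [[...], ...],  # e, M x N_atoms (per state), OR
          "ground_state_charges": [...],   # e, N_atoms
          "replicate_ground_charges": true # with ground_state_charges only
        }, ...
      ]
    }

Energies are in Hartree, geometries in Å, dipoles in atomic units and
charges in elementary charges. JSON floats round-trip exactly, so
``load_qc_profile(write_qc_profile(p))`` reproduces every numeric field
bit for bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import DegenerateGeometryError, InvariantError, SchemaError

SCHEMA_VERSION = 1

#: default tolerance (e) for the per-state charge-sum invariant
CHARGE_SUM_TOL = 1e-3


@dataclass
class ReactionCoordinateSpec:
    """Reaction coordinate ξ = d(bond_break) − d(bond_form).

    ``bond_break`` and ``bond_form`` are ordered atom-index pairs; they may
    share at most one atom (the central atom of the exchange).
    """

    bond_break: tuple[int, int]
    bond_form: tuple[int, int]

    def __post_init__(self) -> None:
        self.bond_break = tuple(int(i) for i in self.bond_break)  # type: ignore[assignment]
        self.bond_form = tuple(int(i) for i in self.bond_form)  # type: ignore[assignment]
        if len(self.bond_break) != 2 or len(self.bond_form) != 2:
            raise InvariantError("bond_break and bond_form must be atom-index pairs")
        for pair in (self.bond_break, self.bond_form):
            if pair[0] == pair[1]:
                raise InvariantError(f"bond pair {pair} repeats an atom index")
        shared = set(self.bond_break) & set(self.bond_form)
        if len(shared) > 1:
            raise InvariantError(
                f"bond_break {self.bond_break} and bond_form {self.bond_form} "
                "share more than one atom"
            )

    def validate_for(self, n_atoms: int) -> None:
        for idx in (*self.bond_break, *self.bond_form):
            if not 0 <= idx < n_atoms:
                raise InvariantError(f"atom index {idx} out of range for {n_atoms} atoms")


def compute_xi(geometry: np.ndarray, spec: ReactionCoordinateSpec) -> float:
    """Reaction-coordinate value (Å) for one geometry.

    Returns d(bond_break) − d(bond_form). Raises
    :class:`DegenerateGeometryError` if either bond has zero length.
    """
    geometry = np.asarray(geometry, dtype=float)
    spec.validate_for(len(geometry))
    d_break = float(np.linalg.norm(geometry[spec.bond_break[0]] - geometry[spec.bond_break[1]]))
    d_form = float(np.linalg.norm(geometry[spec.bond_form[0]] - geometry[spec.bond_form[1]]))
    if d_break == 0.0:
        raise DegenerateGeometryError(f"coincident atoms in bond_break {spec.bond_break}")
    if d_form == 0.0:
        raise DegenerateGeometryError(f"coincident atoms in bond_form {spec.bond_form}")
    return d_break - d_form


@dataclass
class QCPoint:
    """One reaction-coordinate point of the quantum center.

    Parameters
    ----------
    index
        Position along the scanned path.
    elements
        Element labels, length N_atoms.
    geometry
        (N_atoms, 3) Cartesian coordinates, Å.
    state_energies
        (M,) unperturbed electronic energies, Hartree, ground state first
        and non-decreasing.
    dipole_matrix
        (M, M, 3) permanent (diagonal) and transition (off-diagonal)
        dipoles, a.u.; symmetric component-wise.
    atomic_charges
        (M, N_atoms) per-state ESP charges, e. Each state's charges must
        sum to ``total_charge`` within ``charge_tol``.
    total_charge
        Net QC charge, e (integer).
    xi
        Reaction-coordinate value, Å.
    """

    index: int
    elements: list[str]
    geometry: np.ndarray
    state_energies: np.ndarray
    dipole_matrix: np.ndarray
    atomic_charges: np.ndarray
    total_charge: int
    xi: float
    charge_tol: float = CHARGE_SUM_TOL

    def __post_init__(self) -> None:
        self.geometry = np.asarray(self.geometry, dtype=float)
        self.state_energies = np.asarray(self.state_energies, dtype=float)
        self.dipole_matrix = np.asarray(self.dipole_matrix, dtype=float)
        self.atomic_charges = np.asarray(self.atomic_charges, dtype=float)
        self.validate()

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    @property
    def n_states(self) -> int:
        return len(self.state_energies)

    def validate(self) -> None:
        tag = f"point {self.index}"
        n, m = self.n_atoms, self.n_states
        if m < 2:
            raise InvariantError(f"{tag}: need at least 2 electronic states, got {m}")
        if self.geometry.shape != (n, 3):
            raise InvariantError(f"{tag}: geometry shape {self.geometry.shape} != ({n}, 3)")
        if np.any(np.diff(self.state_energies) < 0):
            raise InvariantError(f"{tag}: state_energies not non-decreasing")
        if self.dipole_matrix.shape != (m, m, 3):
            raise InvariantError(
                f"{tag}: dipole_matrix shape {self.dipole_matrix.shape} != ({m}, {m}, 3)"
            )
        if not np.allclose(self.dipole_matrix, np.swapaxes(self.dipole_matrix, 0, 1), atol=1e-10):
            raise InvariantError(f"{tag}: dipole_matrix is not symmetric (μ_kl != μ_lk)")
        if self.atomic_charges.shape != (m, n):
            raise InvariantError(
                f"{tag}: atomic_charges shape {self.atomic_charges.shape} != ({m}, {n})"
            )
        sums = self.atomic_charges.sum(axis=1)
        bad = np.nonzero(np.abs(sums - self.total_charge) > self.charge_tol)[0]
        if bad.size:
            k = int(bad[0])
            raise InvariantError(
                f"{tag}: state {k} charges sum to {sums[k]:.6f} e, expected "
                f"total_charge {self.total_charge} within {self.charge_tol} e"
            )


@dataclass
class QCProfile:
    """Ordered QC points along the reaction coordinate plus its definition."""

    points: list[QCPoint]
    coordinate_spec: ReactionCoordinateSpec
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def xi_values(self) -> np.ndarray:
        return np.array([p.xi for p in self.points], dtype=float)

    def validate(self) -> None:
        if not self.points:
            raise InvariantError("profile has no points")
        ref = self.points[0]
        self.coordinate_spec.validate_for(ref.n_atoms)
        for p in self.points:
            if p.elements != ref.elements:
                raise InvariantError(f"point {p.index}: element list differs from point {ref.index}")
            if p.total_charge != ref.total_charge:
                raise InvariantError(f"point {p.index}: total_charge differs")
            if p.n_states != ref.n_states:
                raise InvariantError(f"point {p.index}: state count differs")
        xi = self.xi_values
        dxi = np.diff(xi)
        if not (np.all(dxi > 0) or np.all(dxi < 0)):
            raise InvariantError("xi values are not strictly monotonic along the profile")


# ---------------------------------------------------------------------------
# serialization
# ---------------------------------------------------------------------------

def _point_to_dict(p: QCPoint) -> dict:
    return {
        "index": p.index,
        "xi": p.xi,
        "elements": list(p.elements),
        "geometry": p.geometry.tolist(),
        "state_energies": p.state_energies.tolist(),
        "dipole_matrix": p.dipole_matrix.tolist(),
        "total_charge": int(p.total_charge),
        "atomic_charges": p.atomic_charges.tolist(),
    }


def _point_from_dict(d: dict, charge_tol: float) -> QCPoint:
    required = ["index", "xi", "elements", "geometry", "state_energies",
                "dipole_matrix", "total_charge"]
    for key in required:
        if key not in d:
            raise SchemaError(f"point record missing required field {key!r}")
    if "atomic_charges" in d:
        charges = np.asarray(d["atomic_charges"], dtype=float)
    elif "ground_state_charges" in d:
        if not d.get("replicate_ground_charges", False):
            raise SchemaError(
                "field 'ground_state_charges' requires 'replicate_ground_charges': true"
            )
        ground = np.asarray(d["ground_state_charges"], dtype=float)
        charges = np.tile(ground, (len(d["state_energies"]), 1))
    else:
        raise SchemaError("point record needs 'atomic_charges' or 'ground_state_charges'")
    return QCPoint(
        index=int(d["index"]),
        elements=[str(e) for e in d["elements"]],
        geometry=np.asarray(d["geometry"], dtype=float),
        state_energies=np.asarray(d["state_energies"], dtype=float),
        dipole_matrix=np.asarray(d["dipole_matrix"], dtype=float),
        atomic_charges=charges,
        total_charge=int(d["total_charge"]),
        xi=float(d["xi"]),
        charge_tol=charge_tol,
    )


def write_qc_profile(profile: QCProfile, path) -> None:
    """Write a validated profile to the documented JSON schema."""
    profile.validate()
    doc = {
        "schema_version": SCHEMA_VERSION,
        "coordinate_spec": {
            "bond_break": list(profile.coordinate_spec.bond_break),
            "bond_form": list(profile.coordinate_spec.bond_form),
        },
        "metadata": dict(profile.metadata),
        "points": [_point_to_dict(p) for p in profile.points],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_qc_profile(path, charge_tol: float = CHARGE_SUM_TOL) -> QCProfile:
    """Load and validate a QC profile from the documented JSON schema.

    Raises :class:`SchemaError` naming the offending field on malformed
    input, :class:`InvariantError` naming the point index when a physical
    invariant (energy ordering, dipole symmetry, charge sums, ξ
    monotonicity) fails.
    """
    with open(path) as fh:
        try:
            doc = json.load(fh)
        except json.JSONDecodeError as exc:
            raise SchemaError(f"not valid JSON: {exc}") from exc
    if not isinstance(doc, dict):
        raise SchemaError("top-level document must be a JSON object")
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise SchemaError(f"unsupported schema_version {version!r} (expected {SCHEMA_VERSION})")
    for key in ("coordinate_spec", "points"):
        if key not in doc:
            raise SchemaError(f"document missing required field {key!r}")
    cs = doc["coordinate_spec"]
    if "bond_break" not in cs or "bond_form" not in cs:
        raise SchemaError("coordinate_spec needs 'bond_break' and 'bond_form'")
    spec = ReactionCoordinateSpec(tuple(cs["bond_break"]), tuple(cs["bond_form"]))
    points = [_point_from_dict(d, charge_tol) for d in doc["points"]]
    return QCProfile(points=points, coordinate_spec=spec, metadata=doc.get("metadata", {}))
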