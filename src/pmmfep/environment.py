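"""Perturbing environment: point-charge electrostatics, shells, g(r).

The environment of a quantum center (solvent plus any classical solute
atoms) is a set of point charges per trajectory frame. Its instantaneous
perturbation enters the matrix method as the electrostatic potential V at
each QC atomic center and the electric field E at the QC center of mass.
Both are direct Coulomb sums; when an orthorhombic box is present,
distances follow the minimum-image convention. No Ewald summation and no
distance cutoff are applied by default — the perturbation is the
instantaneous field of the nearest images.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import InvariantError, SingularGeometryError, UnsupportedBoxError
from .units import ANGSTROM_TO_BOHR, mass_of

DEFAULT_CLASH_DISTANCE = 0.1  # Å


@dataclass
class EnvironmentFrame:
    """One classical configuration: point charges in (optionally) a box.

    charges in e, positions in Å, molecule_ids group particles into whole
    molecules (shell filtering keeps or drops entire molecules), box is
    orthorhombic edge lengths in Å or ``None`` for a non-periodic cluster.
    """

    charges: np.ndarray
    positions: np.ndarray
    molecule_ids: np.ndarray
    box: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.charges = np.asarray(self.charges, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.molecule_ids = np.asarray(self.molecule_ids, dtype=int)
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise UnsupportedBoxError(f"box must be 3 orthorhombic lengths, got {self.box.shape}")
            if np.any(self.box <= 0):
                raise InvariantError("box lengths must be strictly positive")
        n = len(self.charges)
        if self.positions.shape != (n, 3) or len(self.molecule_ids) != n:
            raise InvariantError(
                f"charges ({n}), positions ({self.positions.shape}) and "
                f"molecule_ids ({len(self.molecule_ids)}) are not consistent"
            )

    @property
    def n_particles(self) -> int:
        return len(self.charges)

    def subset(self, mask: np.ndarray) -> "EnvironmentFrame":
        return EnvironmentFrame(
            charges=self.charges[mask],
            positions=self.positions[mask],
            molecule_ids=self.molecule_ids[mask],
            box=None if self.box is None else self.box.copy(),
        )


@dataclass
class PerturbationSample:
    """Electrostatic perturbation of one frame at the QC expansion centers.

    All entries are in atomic units: ``potential_at_atoms[N]`` is V(R_N)
    at the N-th QC atom, ``field_at_origin``/``potential_at_origin`` are
    E(r0) and V(r0) at the QC center of mass.
    """

    potential_at_atoms: np.ndarray
    field_at_origin: np.ndarray
    potential_at_origin: float

    def __post_init__(self) -> None:
        self.potential_at_atoms = np.asarray(self.potential_at_atoms, dtype=float)
        self.field_at_origin = np.asarray(self.field_at_origin, dtype=float)
        if self.field_at_origin.shape != (3,):
            raise InvariantError("field_at_origin must be a 3-vector")
        if not (
            np.all(np.isfinite(self.potential_at_atoms))
            and np.all(np.isfinite(self.field_at_origin))
            and np.isfinite(self.potential_at_origin)
        ):
            raise InvariantError("perturbation sample contains non-finite entries")


def _min_image(deltas: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return deltas
    return deltas - box * np.round(deltas / box)


def potential_and_field(
    frame: EnvironmentFrame,
    point: Sequence[float],
    clash_distance: float = DEFAULT_CLASH_DISTANCE,
) -> tuple[float, np.ndarray]:
    """Coulomb potential (a.u.) and field (a.u.) of a frame at one point (Å).

    V = Σ q_m / r_m and E = Σ q_m r̂_m / r_m², distances taken to the
    nearest periodic image when the frame has a box. A particle closer
    than ``clash_distance`` raises :class:`SingularGeometryError`.
    """
    point = np.asarray(point, dtype=float)
    if frame.n_particles == 0:
        return 0.0, np.zeros(3)
    deltas = _min_image(point[None, :] - frame.positions, frame.box)  # Å, charge -> point
    r_ang = np.linalg.norm(deltas, axis=1)
    clash = np.nonzero(r_ang < clash_distance)[0]
    if clash.size:
        m = int(clash[0])
        raise SingularGeometryError(
            f"particle {m} at {r_ang[m]:.4f} Å from the evaluation point "
            f"(clash distance {clash_distance} Å)"
        )
    r_b = r_ang * ANGSTROM_TO_BOHR
    v = float(np.sum(frame.charges / r_b))
    e = np.sum(
        (frame.charges / r_b**3)[:, None] * (deltas * ANGSTROM_TO_BOHR), axis=0
    )
    return v, e


def center_of_mass(geometry: np.ndarray, elements: Sequence[str]) -> np.ndarray:
    """Center of mass (Å) from element labels and standard atomic weights."""
    masses = np.array([mass_of(e) for e in elements])
    return np.asarray(geometry, dtype=float).T @ masses / masses.sum()


def sample_perturbation(
    frame: EnvironmentFrame,
    qc_geometry: np.ndarray,
    qc_elements: Sequence[str],
    clash_distance: float = DEFAULT_CLASH_DISTANCE,
) -> PerturbationSample:
    """Evaluate one frame's perturbation at the QC expansion centers.

    Returns V(R_N) at every QC atom plus V(r0) and E(r0) at the QC center
    of mass. The frame must not contain the QC particles themselves.
    """
    qc_geometry = np.asarray(qc_geometry, dtype=float)
    pots = np.empty(len(qc_geometry))
    for n, r in enumerate(qc_geometry):
        pots[n], _ = potential_and_field(frame, r, clash_distance)
    r0 = center_of_mass(qc_geometry, qc_elements)
    v0, e0 = potential_and_field(frame, r0, clash_distance)
    return PerturbationSample(potential_at_atoms=pots, field_at_origin=e0, potential_at_origin=v0)


def filter_shell(
    frame: EnvironmentFrame,
    center: Sequence[float],
    r_shell: float,
    complement: bool = False,
) -> EnvironmentFrame:
    """Keep the whole molecules whose nearest atom lies within ``r_shell`` Å.

    Membership is decided per molecule (``molecule_ids``) by the minimum
    atom distance to ``center`` (minimum image when periodic), so that no
    molecule's charges are ever split. ``complement=True`` returns the
    excluded molecules instead; kept ∪ complement = original frame.
    """
    if r_shell <= 0:
        raise InvariantError("r_shell must be positive")
    center = np.asarray(center, dtype=float)
    if frame.n_particles == 0:
        return frame.subset(np.zeros(0, dtype=bool))
    d = np.linalg.norm(_min_image(frame.positions - center[None, :], frame.box), axis=1)
    inside = np.zeros(frame.n_particles, dtype=bool)
    for mol in np.unique(frame.molecule_ids):
        sel = frame.molecule_ids == mol
        if d[sel].min() <= r_shell:
            inside[sel] = True
    return frame.subset(~inside if complement else inside)


@dataclass
class RDFResult:
    """Radial distribution function and running coordination number."""

    r: np.ndarray          # bin centers, Å
    g: np.ndarray          # number-density-normalized g(r)
    coordination: np.ndarray  # cumulative mean particle count n(r) at bin edges
    counts: np.ndarray     # raw mean counts per bin


def radial_distribution(
    frames: Sequence[EnvironmentFrame],
    centers: Sequence[Sequence[float]] | Sequence[float],
    selector: Callable[[EnvironmentFrame], np.ndarray] | None = None,
    bin_width: float = 0.1,
    r_max: float = 10.0,
) -> RDFResult:
    """g(r) of selected particles around a (per-frame) center.

    ``centers`` is either one 3-vector used for every frame or an
    (n_frames, 3) array. ``selector`` maps a frame to a boolean particle
    mask (default: all particles); to count molecules, select one tag atom
    per molecule. Normalization uses the selected-particle number density
    N_sel / V of each frame, so an ideal gas gives g(r) = 1. Requires a
    periodic box with r_max < half the smallest edge.
    """
    if len(frames) == 0:
        raise InvariantError("need at least one frame")
    centers = np.asarray(centers, dtype=float)
    if centers.ndim == 1:
        centers = np.tile(centers, (len(frames), 1))
    if centers.shape != (len(frames), 3):
        raise InvariantError("centers must be a 3-vector or an (n_frames, 3) array")
    n_bins = int(np.ceil(r_max / bin_width))
    edges = np.arange(n_bins + 1) * bin_width
    counts = np.zeros(n_bins)
    density_sum = 0.0
    for frame, center in zip(frames, centers):
        if frame.box is None:
            raise InvariantError("radial_distribution requires periodic frames")
        if r_max >= frame.box.min() / 2:
            raise InvariantError(
                f"r_max {r_max} Å must be below half the smallest box edge "
                f"({frame.box.min() / 2:.3f} Å)"
            )
        mask = np.ones(frame.n_particles, dtype=bool) if selector is None else selector(frame)
        d = np.linalg.norm(
            _min_image(frame.positions[mask] - center[None, :], frame.box), axis=1
        )
        counts += np.histogram(d, bins=edges)[0]
        density_sum += mask.sum() / np.prod(frame.box)
    counts /= len(frames)
    rho = density_sum / len(frames)
    shell_vol = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = counts / (rho * shell_vol)
    r_mid = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(r=r_mid, g=g, coordination=np.cumsum(counts), counts=counts)


# ---------------------------------------------------------------------------
# trajectory readers (XYZ / GRO via MDAnalysis + plain-text charge table)
# ---------------------------------------------------------------------------

def read_charge_table(path) -> tuple[np.ndarray, np.ndarray]:
    """Read the sidecar charge table: columns ``index charge molecule_id``.

    Plain text, whitespace-separated, ``#`` comments allowed; indices are
    0-based particle indices and must cover 0..P−1 exactly once.
    """
    data = np.loadtxt(path, comments="#", ndmin=2)
    if data.shape[1] != 3:
        raise InvariantError(f"charge table must have 3 columns, got {data.shape[1]}")
    order = np.argsort(data[:, 0].astype(int))
    data = data[order]
    idx = data[:, 0].astype(int)
    if not np.array_equal(idx, np.arange(len(idx))):
        raise InvariantError("charge table indices must cover 0..P-1 exactly once")
    return data[:, 1], data[:, 2].astype(int)


def _frames_from_universe(universe, charges, mol_ids, box) -> list[EnvironmentFrame]:
    frames = []
    for ts in universe.trajectory:
        frame_box = box
        if frame_box is None and ts.dimensions is not None and ts.dimensions[:3].any():
            dims = ts.dimensions
            if not np.allclose(dims[3:], 90.0):
                raise UnsupportedBoxError(
                    f"triclinic box angles {dims[3:]} — only orthorhombic boxes are supported"
                )
            frame_box = np.array(dims[:3], dtype=float)
        frames.append(
            EnvironmentFrame(
                charges=charges.copy(),
                positions=universe.atoms.positions.astype(float).copy(),
                molecule_ids=mol_ids.copy(),
                box=None if frame_box is None else np.asarray(frame_box, dtype=float),
            )
        )
    return frames


def read_xyz_frames(path, charge_table_path, box=None) -> list[EnvironmentFrame]:
    """Read a (multi-frame) XYZ trajectory with a sidecar charge table.

    XYZ carries no box information, so an orthorhombic ``box`` (Å) is
    supplied explicitly (``None`` for a non-periodic cluster).
    """
    import MDAnalysis as mda

    charges, mol_ids = read_charge_table(charge_table_path)
    u = mda.Universe(path, topology_format="XYZ", format="XYZ")
    if len(u.atoms) != len(charges):
        raise InvariantError(
            f"charge table has {len(charges)} rows but trajectory has {len(u.atoms)} atoms"
        )
    return _frames_from_universe(u, charges, mol_ids, None if box is None else np.asarray(box, float))


def read_gro_frames(path, charge_table_path) -> list[EnvironmentFrame]:
    """Read a GRO configuration (box line included) with a sidecar charge table."""
    import MDAnalysis as mda

    charges, mol_ids = read_charge_table(charge_table_path)
    u = mda.Universe(path)
    if len(u.atoms) != len(charges):
        raise InvariantError(
            f"charge table has {len(charges)} rows but configuration has {len(u.atoms)} atoms"
        )
    return _frames_from_universe(u, charges, mol_ids, None)
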