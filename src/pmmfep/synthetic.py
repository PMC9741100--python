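"""Toy reaction systems with an exactly solvable solvent response.

The generator emulates the statistical structure that the perturbed-matrix
free-energy machinery assumes for sulfur-chemistry reactions in polar
solvents, at desk scale:

* a four-atom linear quantum center (donor, central, acceptor, spectator)
  whose gas-phase ground-state energy follows a smooth single-maximum
  curve (barrier and product offset configurable), and whose ESP charges
  follow one of two schedules — ``oxidation-like`` (charge separation
  between donor and acceptor peaks at the transition state, as in sulfide
  oxidation by H2O2) or ``exchange-like`` (a net negative charge localized
  on a terminal atom at the endpoints and delocalized at the TS, as in
  thiolate/disulfide exchange);

* a solvent whose instantaneous electric field at the QC center of mass
  is Gaussian along a fixed axis (the molecular axis, x), with a mean that
  responds linearly to the solute charge separation and configurable
  fluctuations — a linearized reaction field. Atomic-center potentials are
  those of the same uniform field, V(R_N) = −E·(R_N − r0).

Because the toy dipole matrix has no component along the field axis, the
perturbed ground-state energy is exactly linear in the field, every
per-step ΔU is exactly Gaussian, and the chained free energy has the
closed form ΔA_step = μ_step − βσ_step²/2. :func:`analytic_reference`
evaluates that closed form and is the parameter-recovery target for the
full sampling pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .environment import PerturbationSample, center_of_mass
from .errors import InvariantError
from .free_energy import FreeEnergyProfile, StepEstimate, chain_profile
from .qc_model import QCPoint, QCProfile, ReactionCoordinateSpec
from .units import ANGSTROM_TO_BOHR, HARTREE_TO_KCAL, KB_HARTREE

SCHEDULES = ("oxidation-like", "exchange-like")


@dataclass
class ToySystemSpec:
    """Parameters of the synthetic reaction system.

    Defaults mimic a sulfide-oxidation-like path: a 25-point scan, four
    electronic states, a 28.2 kcal/mol gas-phase barrier with strongly
    stabilized products, a transferred charge of half an elementary charge
    at the TS, and a solvent response sized so the mean field roughly
    halves the barrier, with field fluctuations of 2×10⁻³ a.u.
    """

    n_points: int = 25
    n_states: int = 4
    gas_barrier: float = 28.2          # kcal/mol above the first point
    product_offset: float = -40.0      # kcal/mol of the last point
    charge_separation_peak: float = 0.5  # e transferred at the TS
    coupling: float = 0.02             # a.u. field per e of charge separation
    fluctuation_sd: float = 0.00145    # a.u.; default satisfies FDT at 300 K (see fdt_fluctuation_sd)
    n_frames: int = 10_000             # frames per ensemble
    seed: int = 0
    schedule: str = "oxidation-like"

    def __post_init__(self) -> None:
        if self.n_points < 3:
            raise InvariantError("n_points must be at least 3")
        if self.n_states < 2:
            raise InvariantError("n_states must be at least 2")
        if self.n_frames < 2:
            raise InvariantError("n_frames must be at least 2")
        if self.fluctuation_sd < 0:
            raise InvariantError("fluctuation_sd must be non-negative")
        if self.schedule not in SCHEDULES:
            raise InvariantError(f"schedule must be one of {SCHEDULES}")


def _ts_index(n_points: int) -> int:
    return (n_points - 1) // 2


def _energy_curve(s: np.ndarray, s_ts: float, barrier: float, offset: float) -> np.ndarray:
    """Smooth single-interior-maximum curve, kcal/mol relative to s=0.

    Two half-cosine arcs meeting with zero slope at the TS: exactly
    ``barrier`` at s_ts and exactly ``offset`` at s=1.
    """
    e = np.empty_like(s)
    left = s <= s_ts
    e[left] = barrier * 0.5 * (1.0 - np.cos(np.pi * s[left] / s_ts))
    rest = ~left
    e[rest] = offset + (barrier - offset) * 0.5 * (
        1.0 + np.cos(np.pi * (s[rest] - s_ts) / (1.0 - s_ts))
    )
    return e


def _ground_charges(s: float, s_ts: float, spec: ToySystemSpec) -> np.ndarray:
    """Per-atom ground-state charges [donor, central, acceptor, spectator]."""
    if spec.schedule == "oxidation-like":
        q = spec.charge_separation_peak * np.exp(-((s - s_ts) ** 2) / (2 * 0.15**2))
        return np.array([q, 0.0, -q, 0.0])
    # exchange-like: one negative charge migrating donor -> acceptor,
    # shared (delocalized) across the terminals near the TS
    f = s * s * (3.0 - 2.0 * s)  # smoothstep
    return np.array([-(1.0 - f), 0.0, -f, 0.0])


def _geometry(s: float) -> np.ndarray:
    d_form = 3.4 - 1.6 * s
    d_break = 1.4 + 1.6 * s
    return np.array(
        [
            [0.0, 0.0, 0.0],               # donor (attacking/forming partner)
            [d_form, 0.0, 0.0],            # central atom
            [d_form + d_break, 0.0, 0.0],  # acceptor (leaving/breaking partner)
            [-1.2, 1.1, 0.0],              # spectator substituent
        ]
    )


def make_toy_qc(spec: ToySystemSpec) -> QCProfile:
    """Deterministic toy QC profile for the given system parameters.

    ξ = d(central–acceptor) − d(donor–central) grows strictly monotonically
    along the scan; the interior ground-state maximum sits exactly
    ``gas_barrier`` above the first point and the last point exactly at
    ``product_offset``. Excited states ride at fixed gaps above the ground
    state with transition and permanent dipoles transverse to the
    molecular (solvent-field) axis; ESP charges are replicated across
    states.
    """
    n = spec.n_points
    m = spec.n_states
    s_values = np.linspace(0.0, 1.0, n)
    s_ts = s_values[_ts_index(n)]
    energies_kcal = _energy_curve(s_values, s_ts, spec.gas_barrier, spec.product_offset)

    elements = ["S", "O", "O", "C"] if spec.schedule == "oxidation-like" else ["S", "S", "S", "C"]
    total_charge = 0 if spec.schedule == "oxidation-like" else -1

    gaps = 0.10 + 0.03 * np.arange(m)  # Hartree offsets of excited states
    dipoles = np.zeros((m, m, 3))
    for k in range(m):
        dipoles[k, k] = (0.0, 0.4 + 0.1 * k, 0.0)
        for l in range(k + 1, m):
            mu = (0.0, 0.15 / (l - k), 0.08 / (l - k))
            dipoles[k, l] = mu
            dipoles[l, k] = mu

    points = []
    for i, s in enumerate(s_values):
        geom = _geometry(s)
        ground_q = _ground_charges(s, s_ts, spec)
        if total_charge == -1:  # keep exact charge sums
            ground_q[0] = -(1.0 + ground_q[2])
        e0 = energies_kcal[i] / HARTREE_TO_KCAL
        state_e = e0 + np.concatenate([[0.0], gaps[: m - 1]])
        points.append(
            QCPoint(
                index=i,
                elements=list(elements),
                geometry=geom,
                state_energies=state_e,
                dipole_matrix=dipoles.copy(),
                atomic_charges=np.tile(ground_q, (m, 1)),
                total_charge=total_charge,
                xi=float(3.2 * s - 2.0),
            )
        )
    return QCProfile(
        points=points,
        coordinate_spec=ReactionCoordinateSpec(bond_break=(1, 2), bond_form=(0, 1)),
        metadata={"generator": "pmmfep.synthetic", "schedule": spec.schedule},
    )


def charge_separation(point: QCPoint) -> float:
    """Donor/acceptor charge separation (e): (q_donor − q_acceptor)/2."""
    q = point.atomic_charges[0]
    return float((q[0] - q[2]) / 2.0)


def _coupling_strength(point_charges: QCPoint, point_geom: QCPoint) -> float:
    """Effective dipole D (a.u.) coupling a state to the x field.

    Energy response to a field E_x is −E_x·D with
    D = Σ_N q_N (x_N − x0) (in bohr, ground-state charges of
    ``point_charges`` at the expansion centers of ``point_geom``) plus the
    ground-state permanent dipole x-component of ``point_charges``.
    """
    x = point_geom.geometry[:, 0]
    x0 = center_of_mass(point_geom.geometry, point_geom.elements)[0]
    q = point_charges.atomic_charges[0]
    return float(
        q @ ((x - x0) * ANGSTROM_TO_BOHR) + point_charges.dipole_matrix[0, 0, 0]
    )


def fdt_fluctuation_sd(coupling: float, temperature: float = 300.0) -> float:
    """Field fluctuation (a.u.) consistent with fluctuation–dissipation.

    A bath in thermal equilibrium whose mean field responds linearly to
    the solute dipole with susceptibility χ must fluctuate with variance
    χ kB T. For the toy geometry the donor–acceptor separation is fixed
    at 4.8 Å, so the dipole susceptibility is coupling / (4.8 Å in bohr)
    and σ = √(coupling·kB·T / ℓ). Generators built with this value are
    Boltzmann ensembles of a harmonic bath, which is what makes
    forward/backward free-energy cycles close; the class default equals
    this value for the default coupling at 300 K.
    """
    ell = 4.8 * ANGSTROM_TO_BOHR
    return float(np.sqrt(coupling * KB_HARTREE * temperature / ell))


def mean_field(profile: QCProfile, spec: ToySystemSpec, point_index: int) -> float:
    """Mean solvent field E_x (a.u.) of the ensemble at one point."""
    return -spec.coupling * charge_separation(profile.points[point_index])


def sample_environment(
    profile: QCProfile,
    spec: ToySystemSpec,
    point_index: int,
    n_frames: int | None = None,
) -> list[PerturbationSample]:
    """Draw the Gaussian solvent-field ensemble for one ξ point.

    The field is (E_x, 0, 0) with E_x ~ N(−coupling × charge separation,
    fluctuation_sd²); atomic potentials are the uniform-field values
    V(R_N) = −E_x (x_N − x0) at this point's expansion centers, with
    V(r0) = 0. Deterministic under (seed, point_index): ensembles are
    independently reproducible.
    """
    if not 0 <= point_index < profile.n_points:
        raise InvariantError(f"point_index {point_index} out of range")
    n = spec.n_frames if n_frames is None else int(n_frames)
    point = profile.points[point_index]
    rng = np.random.default_rng([spec.seed, point_index])
    fields = mean_field(profile, spec, point_index) + spec.fluctuation_sd * rng.standard_normal(n)
    x = point.geometry[:, 0]
    x0 = center_of_mass(point.geometry, point.elements)[0]
    dx_bohr = (x - x0) * ANGSTROM_TO_BOHR
    return [
        PerturbationSample(
            potential_at_atoms=-ex * dx_bohr,
            field_at_origin=np.array([ex, 0.0, 0.0]),
            potential_at_origin=0.0,
        )
        for ex in fields
    ]


def _is_linear(profile: QCProfile) -> bool:
    """True when the perturbed ground energy is exactly linear in an x field."""
    for p in profile.points:
        if np.max(np.abs(p.dipole_matrix[..., 0])) > 1e-12:
            return False
        if not np.allclose(p.atomic_charges, p.atomic_charges[0][None, :], atol=1e-12):
            return False
    return True


def analytic_reference(
    profile: QCProfile,
    spec: ToySystemSpec,
    temperature: float = 300.0,
    direction: str = "forward",
) -> FreeEnergyProfile:
    """Closed-form free-energy profile for the linearly coupled toy system.

    Under linear coupling every per-step ΔU is Gaussian, so each forward
    step has exactly ΔA = μ_step − βσ_step²/2 with

        μ_step = ΔE⁰ − m_i (D_{i+1|i} − D_{i|i}),   σ_step = σ_f |D_{i+1|i} − D_{i|i}|,

    where m_i is the ensemble-i mean field and D_{j|i} the coupling dipole
    of point j's charges at point i's expansion centers. ΔU chains the
    exact ensemble means. If the profile violates the linearity conditions
    (dipole components along the field axis, state-dependent charges) the
    reference is still returned but flagged ``approximate`` in ``meta``.
    """
    if temperature <= 0:
        raise InvariantError("temperature must be positive")
    beta = 1.0 / (KB_HARTREE * temperature)
    n = profile.n_points
    steps = []
    for i in range(n - 1):
        p_i, p_j = profile.points[i], profile.points[i + 1]
        de0 = p_j.state_energies[0] - p_i.state_energies[0]
        m_i = mean_field(profile, spec, i)
        m_j = mean_field(profile, spec, i + 1)
        dd_fwd = _coupling_strength(p_j, p_i) - _coupling_strength(p_i, p_i)
        mu_f = de0 - m_i * dd_fwd
        sd_f = spec.fluctuation_sd * abs(dd_fwd)
        dA_f = mu_f - beta * sd_f**2 / 2.0
        if direction == "forward":
            dA = dA_f
        else:
            dd_bwd = _coupling_strength(p_j, p_j) - _coupling_strength(p_i, p_j)
            mu_b = de0 - m_j * dd_bwd
            sd_b = spec.fluctuation_sd * abs(dd_bwd)
            dA_b = mu_b + beta * sd_b**2 / 2.0
            if direction == "backward":
                dA = dA_b
            elif direction == "symmetric":
                dA = 0.5 * (dA_f + dA_b)
            else:
                raise InvariantError(f"unknown direction {direction!r}")
        du = (p_j.state_energies[0] - m_j * _coupling_strength(p_j, p_j)) - (
            p_i.state_energies[0] - m_i * _coupling_strength(p_i, p_i)
        )
        dA_kcal = dA * HARTREE_TO_KCAL
        du_kcal = du * HARTREE_TO_KCAL
        steps.append(
            StepEstimate(dA=dA_kcal, dU=du_kcal, TdS=du_kcal - dA_kcal,
                         err_dA=0.0, err_dU=0.0, direction=direction)
        )
    result = chain_profile(steps, profile.xi_values)
    result.meta["approximate"] = not _is_linear(profile)
    result.meta["analytic"] = True
    return result
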