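"""Run configuration and the end-to-end perturbation → profile pipeline.

A run takes a QC profile plus one environment ensemble per ξ point
(trajectory files or the synthetic generator), evaluates the perturbed
ground-state energy of adjacent QC points over each ensemble, chains the
exponential-average steps into ΔA/ΔU/TΔS profiles, and writes the profile
table, a machine-readable report and a log that records every setting in
force, so a run is fully reconstructible from its outputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from . import __version__
from .environment import (
    EnvironmentFrame,
    PerturbationSample,
    center_of_mass,
    filter_shell,
    read_gro_frames,
    read_xyz_frames,
    sample_perturbation,
)
from .errors import InvariantError, PMMError
from .free_energy import (
    DEFAULT_BLOCK_GRID,
    FreeEnergyProfile,
    chain_profile,
    fep_step,
    write_profile,
)
from .pmm_core import ensemble_energies
from .qc_model import SCHEMA_VERSION, QCProfile, load_qc_profile
from .synthetic import ToySystemSpec, make_toy_qc, sample_environment
from .units import HARTREE_TO_KCAL

logger = logging.getLogger("pmmfep")


@dataclass
class TrajectorySource:
    """One ξ point's environment ensemble on disk."""

    path: str
    charge_table: str
    format: str = "xyz"          # "xyz" or "gro"
    box: list[float] | None = None  # Å, required for periodic XYZ

    def load(self) -> list[EnvironmentFrame]:
        if self.format == "xyz":
            return read_xyz_frames(self.path, self.charge_table, box=self.box)
        if self.format == "gro":
            return read_gro_frames(self.path, self.charge_table)
        raise InvariantError(f"unknown trajectory format {self.format!r}")


@dataclass
class RunConfig:
    """Everything needed to reproduce a pipeline run.

    Either ``synthetic`` (a toy-system spec) or ``qc_profile_path`` plus
    one ``trajectories`` entry per ξ point must be set. Defaults: 300 K,
    forward estimator, no shell filter, 5.5 Å shell radius when enabled.
    """

    qc_profile_path: str | None = None
    trajectories: list[TrajectorySource] | None = None
    synthetic: ToySystemSpec | None = None
    temperature: float = 300.0
    direction: str = "forward"
    shell_filter: bool = False
    shell_radius: float = 5.5
    shell_center_atom: int | None = None  # None -> QC center of mass
    include_permanent_dipole: bool = True
    block_grid: Sequence[int] = DEFAULT_BLOCK_GRID
    output_dir: str = "pmm_run"
    seed: int = 0
    verbosity: str = "INFO"

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise InvariantError("temperature must be positive")
        if self.shell_filter and self.shell_radius <= 0:
            raise InvariantError("shell_radius must be positive when the filter is on")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            raw["synthetic"] = ToySystemSpec(**raw["synthetic"])
        if "trajectories" in raw and raw["trajectories"] is not None:
            raw["trajectories"] = [TrajectorySource(**t) for t in raw["trajectories"]]
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["block_grid"] = list(self.block_grid)
        return d


# ---------------------------------------------------------------------------
# perturbation sample files (one TSV per ensemble)
# ---------------------------------------------------------------------------

def write_samples(samples: Sequence[PerturbationSample], path) -> None:
    """TSV: frame, Ex, Ey, Ez, V(r0), V(R_1)..V(R_N) — all a.u."""
    n_atoms = samples[0].potential_at_atoms.size
    with open(path, "w") as fh:
        cols = "\t".join(f"V_atom{i}" for i in range(n_atoms))
        fh.write(f"# frame\tEx\tEy\tEz\tV_origin\t{cols}\n")
        for i, s in enumerate(samples):
            ex, ey, ez = (float(v) for v in s.field_at_origin)
            pots = "\t".join(repr(float(v)) for v in s.potential_at_atoms)
            fh.write(f"{i}\t{ex!r}\t{ey!r}\t{ez!r}\t{float(s.potential_at_origin)!r}\t{pots}\n")


def read_samples(path) -> list[PerturbationSample]:
    data = np.loadtxt(path, comments="#", ndmin=2)
    return [
        PerturbationSample(
            potential_at_atoms=row[5:],
            field_at_origin=row[1:4],
            potential_at_origin=float(row[4]),
        )
        for row in data
    ]


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def _setup_logging(outdir: Path, verbosity: str) -> None:
    logger.setLevel(getattr(logging, verbosity.upper(), logging.INFO))
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    fh = logging.FileHandler(outdir / "run.log", mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def _samples_from_trajectory(
    source: TrajectorySource, qc_geometry, qc_elements, config: RunConfig
) -> list[PerturbationSample]:
    frames = source.load()
    if config.shell_filter:
        if config.shell_center_atom is None:
            center = center_of_mass(qc_geometry, qc_elements)
        else:
            center = np.asarray(qc_geometry)[config.shell_center_atom]
        frames = [filter_shell(f, center, config.shell_radius) for f in frames]
    return [sample_perturbation(f, qc_geometry, qc_elements) for f in frames]


def _collect_samples(config: RunConfig, profile: QCProfile) -> list[list[PerturbationSample]]:
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        return [sample_environment(profile, spec, i) for i in range(profile.n_points)]
    if config.trajectories is None:
        raise InvariantError("config needs either 'synthetic' or 'trajectories'")
    if len(config.trajectories) != profile.n_points:
        raise InvariantError(
            f"{len(config.trajectories)} trajectories for {profile.n_points} QC points"
        )
    out = []
    for i, source in enumerate(config.trajectories):
        p = profile.points[i]
        out.append(_samples_from_trajectory(source, p.geometry, p.elements, config))
    return out


def run_pipeline(config: RunConfig) -> FreeEnergyProfile:
    """Execute the full perturbed-matrix free-energy pipeline.

    Stage failures are re-raised with the stage name and ξ-point index
    prepended. Writes ``profile.tsv``, ``report.json`` and ``run.log``
    into ``config.output_dir`` and returns the chained profile.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir, config.verbosity)
    logger.info("pmmfep %s; config: %s", __version__, json.dumps(config.to_dict(), default=str))

    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic, seed=config.seed)
        profile = make_toy_qc(spec)
        logger.info("synthetic QC profile: %d points, schedule %s", profile.n_points, spec.schedule)
    else:
        if config.qc_profile_path is None:
            raise InvariantError("config needs either 'synthetic' or 'qc_profile_path'")
        profile = load_qc_profile(config.qc_profile_path)
        logger.info("loaded QC profile %s (schema v%d, %d points)",
                    config.qc_profile_path, SCHEMA_VERSION, profile.n_points)

    try:
        ensembles = _collect_samples(config, profile)
    except PMMError as exc:
        raise type(exc)(f"[perturbation sampling] {exc}") from exc

    n = profile.n_points
    own_traces = []
    for i in range(n):
        try:
            own_traces.append(
                ensemble_energies(profile.points[i], ensembles[i],
                                  include_permanent_dipole=config.include_permanent_dipole)
            )
        except PMMError as exc:
            raise type(exc)(f"[diagonalization, point {i}] {exc}") from exc

    steps = []
    need_bwd = config.direction in ("backward", "symmetric")
    for i in range(n - 1):
        try:
            cross_fwd = ensemble_energies(
                profile.points[i + 1], ensembles[i],
                include_permanent_dipole=config.include_permanent_dipole,
            )
            forward_dU = (cross_fwd.energies - own_traces[i].energies) * HARTREE_TO_KCAL
            backward_dU = None
            if need_bwd:
                cross_bwd = ensemble_energies(
                    profile.points[i], ensembles[i + 1],
                    include_permanent_dipole=config.include_permanent_dipole,
                )
                backward_dU = (own_traces[i + 1].energies - cross_bwd.energies) * HARTREE_TO_KCAL
            step = fep_step(
                forward_dU=forward_dU,
                backward_dU=backward_dU,
                trace_i=own_traces[i],
                trace_j=own_traces[i + 1],
                temperature=config.temperature,
                direction=config.direction,
                n_blocks_grid=config.block_grid,
            )
        except PMMError as exc:
            raise type(exc)(f"[free-energy step {i}->{i + 1}] {exc}") from exc
        logger.debug("step %d->%d: dA=%.4f dU=%.4f kcal/mol", i, i + 1, step.dA, step.dU)
        steps.append(step)

    result = chain_profile(steps, profile.xi_values)
    result.meta.update(
        {
            "temperature_K": config.temperature,
            "direction": config.direction,
            "seed": config.seed,
            "n_points": n,
            "n_frames": [len(e) for e in ensembles],
        }
    )
    write_profile(result, outdir / "profile.tsv")
    report = {
        "pmmfep_version": __version__,
        "qc_schema_version": SCHEMA_VERSION,
        "config": config.to_dict(),
        "units": {"xi": "angstrom", "energies": "kcal/mol",
                  "hartree_to_kcal_mol": HARTREE_TO_KCAL},
        "barrier_kcal_mol": result.barrier,
        "barrier_xi_angstrom": result.barrier_xi,
        "barrier_err_kcal_mol": result.barrier_err,
        "steps": [dataclasses.asdict(s) for s in steps],
    }
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, default=str)
    logger.info("barrier %.4f ± %.4f kcal/mol at xi=%.4f Å",
                result.barrier, result.barrier_err, result.barrier_xi)
    return result


# ---------------------------------------------------------------------------
# run comparison
# ---------------------------------------------------------------------------

@dataclass
class ComparisonResult:
    """ΔΔA‡ between two runs, with per-ξ profile deltas when available."""

    barrier_difference: float
    xi: np.ndarray | None = None
    dA_deltas: np.ndarray | None = None


def _barrier_of(p) -> float:
    return p.barrier if isinstance(p, FreeEnergyProfile) else float(p)


def compare_runs(profile_a, profile_b, interpolate: bool = False) -> ComparisonResult:
    """Barrier difference barrier(a) − barrier(b) and pointwise ΔA deltas.

    Accepts :class:`FreeEnergyProfile` objects or bare barrier heights
    (kcal/mol). Profiles on different ξ grids require ``interpolate=True``
    (profile b is linearly interpolated onto a's grid); bare numbers give
    the barrier difference only.
    """
    diff = _barrier_of(profile_a) - _barrier_of(profile_b)
    if not (isinstance(profile_a, FreeEnergyProfile) and isinstance(profile_b, FreeEnergyProfile)):
        return ComparisonResult(barrier_difference=diff)
    if profile_a.xi.size == profile_b.xi.size and np.allclose(profile_a.xi, profile_b.xi):
        deltas = profile_a.dA_cum - profile_b.dA_cum
    elif interpolate:
        deltas = profile_a.dA_cum - np.interp(profile_a.xi, profile_b.xi, profile_b.dA_cum)
    else:
        raise InvariantError(
            "profiles have incompatible xi grids; pass interpolate=True to compare"
        )
    return ComparisonResult(barrier_difference=diff, xi=profile_a.xi.copy(), dA_deltas=deltas)
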