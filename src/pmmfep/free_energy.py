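"""Exponential-average free energy differences chained along ξ.

Each pair of adjacent reaction-coordinate points (i, i+1) is bridged by a
free energy perturbation step

    ΔA_{i→i+1} = −kB T ln ⟨ exp(−β ΔU) ⟩_i ,   ΔU = U_{i+1} − U_i,

with the average taken over the sampling ensemble (ensemble i for the
forward estimator; ensemble i+1, with the sign reversed, for the backward
one; the symmetric estimator averages the two). ΔU is the perturbed
ground-state electronic energy difference obtained by re-perturbing both
QC points with the same frame's environment. Summing the steps yields the
Helmholtz free energy profile ΔA(ξ); the internal-energy profile ΔU(ξ)
chains the ensemble-mean energies the same way, and TΔS = ΔU − ΔA.

Exponential averages are evaluated with a max-shift (log-sum-exp), so
finite inputs never overflow, and the Gibbs–Bogoliubov bound
ΔA ≤ ⟨ΔU⟩ holds for every input. Statistical errors come from block
averaging: the standard error of block means over a grid of block counts,
reporting the maximum over the grid as a plateau proxy for correlated
series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp

from .errors import InvariantError
from .pmm_core import EnergyTrace
from .units import HARTREE_TO_KCAL, KB_KCAL

DEFAULT_TEMPERATURE = 300.0  # K
DEFAULT_BLOCK_GRID = (5, 10, 20)


@dataclass
class BlockErrorResult:
    """Block-averaging standard error with per-block-count diagnostics."""

    error: float
    per_block_count: dict[int, float]


def block_average_error(
    series: np.ndarray, n_blocks_grid: Sequence[int] = DEFAULT_BLOCK_GRID
) -> BlockErrorResult:
    """Standard error of the mean of a (possibly correlated) series.

    For each block count b the series is cut into b contiguous blocks and
    the standard error of the block means, std/√b, is recorded; the
    reported error is the maximum over the grid (for correlated data the
    estimate grows with block size until blocks decorrelate, so the
    maximum is a plateau proxy). Requires len(series) ≥ 2 × max(grid).
    """
    series = np.asarray(series, dtype=float)
    grid = sorted(set(int(b) for b in n_blocks_grid))
    if any(b < 2 for b in grid):
        raise InvariantError("block counts must be at least 2")
    if series.size < 2 * max(grid):
        raise InvariantError(
            f"series of length {series.size} too short for {max(grid)} blocks "
            f"(need at least {2 * max(grid)})"
        )
    per: dict[int, float] = {}
    for b in grid:
        block_size = series.size // b
        means = series[: b * block_size].reshape(b, block_size).mean(axis=1)
        per[b] = float(np.std(means, ddof=1) / np.sqrt(b))
    return BlockErrorResult(error=max(per.values()), per_block_count=per)


@dataclass
class StepEstimate:
    """One FEP step: ΔA, ΔU and TΔS (kcal/mol) with block-averaging errors.

    TΔS is defined as ΔU − ΔA, so ΔA = ΔU − TΔS holds exactly by
    construction.
    """

    dA: float
    dU: float
    TdS: float
    err_dA: float
    err_dU: float
    direction: str = "forward"

    def __post_init__(self) -> None:
        if self.err_dA < 0 or self.err_dU < 0:
            raise InvariantError("errors must be non-negative")


def _exp_average_dA(dU: np.ndarray, kt: float, n_blocks_grid) -> tuple[float, float]:
    """−kT ln⟨e^{−ΔU/kT}⟩ with a max-shift, plus a block/delta-method error."""
    shift = float(dU.min())  # exponents ≤ 0 after shifting
    w = np.exp(-(dU - shift) / kt)
    dA = shift - kt * float(logsumexp(-(dU - shift) / kt) - np.log(dU.size))
    try:
        err_w = block_average_error(w, n_blocks_grid).error
        err = kt * err_w / float(np.mean(w))
    except InvariantError:  # series shorter than the block grid
        err = kt * float(np.std(w, ddof=1) / np.sqrt(w.size)) / float(np.mean(w)) if dU.size > 1 else 0.0
    return dA, err


def fep_step(
    forward_dU: np.ndarray | None = None,
    backward_dU: np.ndarray | None = None,
    trace_i: EnergyTrace | None = None,
    trace_j: EnergyTrace | None = None,
    temperature: float = DEFAULT_TEMPERATURE,
    direction: str = "forward",
    n_blocks_grid: Sequence[int] = DEFAULT_BLOCK_GRID,
) -> StepEstimate:
    """One exponential-average step between adjacent ξ points.

    Parameters
    ----------
    forward_dU
        Per-frame ΔU = U_{i+1} − U_i (kcal/mol) evaluated on ensemble-i
        frames. Required for ``direction`` "forward" and "symmetric".
    backward_dU
        Per-frame ΔU = U_{i+1} − U_i (kcal/mol) evaluated on ensemble-(i+1)
        frames. Required for "backward" and "symmetric".
    trace_i, trace_j
        Full ensemble energy traces (Hartree) for points i and i+1. When
        both are given, ΔU_internal = ⟨U_{i+1}⟩_{i+1} − ⟨U_i⟩_i (the mean
        energy in each point's own ensemble); otherwise the forward mean
        of ``forward_dU`` is used.
    temperature
        Kelvin; must be positive.
    direction
        "forward", "backward" or "symmetric" (mean of the two ΔA
        estimates).
    """
    if temperature <= 0:
        raise InvariantError(f"temperature must be positive, got {temperature}")
    if direction not in ("forward", "backward", "symmetric"):
        raise InvariantError(f"unknown direction {direction!r}")
    kt = KB_KCAL * temperature

    need_fwd = direction in ("forward", "symmetric")
    need_bwd = direction in ("backward", "symmetric")
    if need_fwd and forward_dU is None:
        raise InvariantError(f"direction {direction!r} requires forward_dU")
    if need_bwd and backward_dU is None:
        raise InvariantError(f"direction {direction!r} requires backward_dU")

    dA_parts, err_parts = [], []
    if need_fwd:
        fwd = np.asarray(forward_dU, dtype=float)
        dA_f, err_f = _exp_average_dA(fwd, kt, n_blocks_grid)
        dA_parts.append(dA_f)
        err_parts.append(err_f)
    if need_bwd:
        bwd = np.asarray(backward_dU, dtype=float)
        # backward: ΔA = +kT ln⟨e^{+βΔU}⟩_{i+1} = −(forward estimate of the reverse step)
        dA_b, err_b = _exp_average_dA(-bwd, kt, n_blocks_grid)
        dA_parts.append(-dA_b)
        err_parts.append(err_b)
    dA = float(np.mean(dA_parts))
    err_dA = float(np.sqrt(np.sum(np.square(err_parts))) / len(err_parts))

    if trace_i is not None and trace_j is not None:
        e_i = trace_i.energies * HARTREE_TO_KCAL
        e_j = trace_j.energies * HARTREE_TO_KCAL
        dU_val = float(e_j.mean() - e_i.mean())
        err_dU = float(np.sqrt(
            _series_error(e_i, n_blocks_grid) ** 2 + _series_error(e_j, n_blocks_grid) ** 2
        ))
    elif forward_dU is not None:
        fwd = np.asarray(forward_dU, dtype=float)
        dU_val = float(fwd.mean())
        err_dU = _series_error(fwd, n_blocks_grid)
    else:
        bwd = np.asarray(backward_dU, dtype=float)
        dU_val = float(bwd.mean())
        err_dU = _series_error(bwd, n_blocks_grid)

    return StepEstimate(
        dA=dA, dU=dU_val, TdS=dU_val - dA, err_dA=err_dA, err_dU=err_dU, direction=direction
    )


def _series_error(series: np.ndarray, n_blocks_grid) -> float:
    if series.size < 2:
        return 0.0
    try:
        return block_average_error(series, n_blocks_grid).error
    except InvariantError:
        return float(np.std(series, ddof=1) / np.sqrt(series.size))


def decompose(dA: float, dU: float) -> float:
    """Entropic term TΔS = ΔU − ΔA (kcal/mol) of a free-energy change."""
    if not (np.isfinite(dA) and np.isfinite(dU)):
        raise InvariantError("decompose requires finite inputs")
    return dU - dA


@dataclass
class FreeEnergyProfile:
    """Cumulative ΔA/ΔU/TΔS (kcal/mol) versus ξ, anchored at 0.

    ``barrier`` is max ΔA relative to the first (reactant) point — not the
    global minimum — and ``barrier_xi`` its location.
    """

    xi: np.ndarray
    dA_cum: np.ndarray
    dU_cum: np.ndarray
    TdS_cum: np.ndarray
    err_dA_steps: np.ndarray
    err_dU_steps: np.ndarray
    barrier: float
    barrier_xi: float
    barrier_err: float = 0.0
    meta: dict = field(default_factory=dict)

    @property
    def err_dA_cum(self) -> np.ndarray:
        """Quadrature-propagated cumulative ΔA error (independent steps)."""
        return np.sqrt(np.concatenate([[0.0], np.cumsum(self.err_dA_steps**2)]))

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "xi_angstrom": self.xi,
                "dA_kcal_mol": self.dA_cum,
                "dU_kcal_mol": self.dU_cum,
                "TdS_kcal_mol": self.TdS_cum,
                "err_dA_kcal_mol": self.err_dA_cum,
            }
        )


def chain_profile(
    step_estimates: Sequence[StepEstimate], xi_values: Sequence[float]
) -> FreeEnergyProfile:
    """Chain ordered per-step estimates into cumulative profiles.

    ``xi_values`` has one more entry than ``step_estimates``; the first
    point anchors all profiles at zero. Step errors are propagated in
    quadrature (steps treated as independent).
    """
    steps = list(step_estimates)
    xi = np.asarray(xi_values, dtype=float)
    if not steps:
        raise InvariantError("need at least one step estimate")
    if xi.size != len(steps) + 1:
        raise InvariantError(
            f"{len(steps)} steps require {len(steps) + 1} xi values, got {xi.size}"
        )
    dA = np.concatenate([[0.0], np.cumsum([s.dA for s in steps])])
    dU = np.concatenate([[0.0], np.cumsum([s.dU for s in steps])])
    tds = np.concatenate([[0.0], np.cumsum([s.TdS for s in steps])])
    err_dA = np.array([s.err_dA for s in steps])
    err_dU = np.array([s.err_dU for s in steps])
    i_max = int(np.argmax(dA))
    barrier = float(dA[i_max] - dA[0])
    barrier_err = float(np.sqrt(np.sum(err_dA[:i_max] ** 2)))
    return FreeEnergyProfile(
        xi=xi,
        dA_cum=dA,
        dU_cum=dU,
        TdS_cum=tds,
        err_dA_steps=err_dA,
        err_dU_steps=err_dU,
        barrier=barrier,
        barrier_xi=float(xi[i_max]),
        barrier_err=barrier_err,
    )


def write_profile(profile: FreeEnergyProfile, path) -> None:
    """Tab-separated profile: xi, ΔA, ΔU, TΔS, cumulative/step errors."""
    n = profile.xi.size
    err_cum = profile.err_dA_cum
    step_a = np.concatenate([[0.0], profile.err_dA_steps])
    step_u = np.concatenate([[0.0], profile.err_dU_steps])
    with open(path, "w") as fh:
        fh.write(
            "# xi_angstrom\tdA_kcal_mol\tdU_kcal_mol\tTdS_kcal_mol\t"
            "err_dA_cum_kcal_mol\terr_dA_step_kcal_mol\terr_dU_step_kcal_mol\n"
        )
        for i in range(n):
            row = (profile.xi[i], profile.dA_cum[i], profile.dU_cum[i],
                   profile.TdS_cum[i], err_cum[i], step_a[i], step_u[i])
            fh.write("\t".join(repr(float(x)) for x in row) + "\n")


def read_profile(path) -> FreeEnergyProfile:
    data = np.loadtxt(path, comments="#", ndmin=2)
    xi, dA, dU, tds = data[:, 0], data[:, 1], data[:, 2], data[:, 3]
    err_steps_a = data[1:, 5]
    err_steps_u = data[1:, 6]
    i_max = int(np.argmax(dA))
    return FreeEnergyProfile(
        xi=xi, dA_cum=dA, dU_cum=dU, TdS_cum=tds,
        err_dA_steps=err_steps_a, err_dU_steps=err_steps_u,
        barrier=float(dA[i_max] - dA[0]), barrier_xi=float(xi[i_max]),
        barrier_err=float(np.sqrt(np.sum(err_steps_a[:i_max] ** 2))),
    )
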