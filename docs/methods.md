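# Methods

## Scope and model

`pmmfep` computes Helmholtz free-energy, internal-energy and entropy
profiles along a chemical reaction coordinate for a quantum center (QC)
embedded in a classical point-charge environment, in the perturbed-matrix
style of QM/MM: the QC electronic structure is precomputed once per
reaction-coordinate point in the gas phase, and the environment of each
trajectory frame enters as an electrostatic perturbation of the QC
Hamiltonian written in the basis of the M unperturbed eigenstates.

Per frame the perturbed Hamiltonian is

    H_kk = E_k⁰ + Σ_N q_{N,k} V(R_N) − E(r0)·μ_kk
    H_kl = −E(r0)·μ_kl                          (k ≠ l)

with `E_k⁰` the unperturbed state energies, `q_{N,k}` per-state ESP
atomic charges, `V(R_N)` the environment potential at each QC atomic
center, and `E(r0)`, `μ` the field at the QC center of mass and the
permanent/transition dipole matrix. The diagonal therefore carries an
atom-based monopole re-expansion of the perturbation; the off-diagonal
couplings use the QC-level dipolar approximation. Higher atom-based terms
(local fields against atomic transition densities) would need per-atom,
per-state dipoles that the unperturbed data set (energies, dipoles, ESP
charges) does not contain, so the field coupling is kept at the QC level;
`include_permanent_dipole=False` drops the −E·μ_kk diagonal term for
sensitivity analysis, since whether that term belongs on the diagonal
alongside the monopole sum is a genuinely open modeling choice. The matrix
is symmetrized as (H+Hᵀ)/2; asymmetry above 1e−12 Hartree is an error.
Eigendecomposition is exact (`numpy.linalg.eigh`, batched over frames);
near-degenerate ground states (gap < 1e−9 Hartree) are flagged but the
energy is simply the lowest eigenvalue, because only eigenvalues feed the
estimators downstream.

The reaction coordinate is ξ = d(breaking bond) − d(forming bond),
computed from the point geometries; it is antisymmetric under exchanging
the two bonds and invariant under rigid motions.

## Electrostatics of the environment

The perturbation is an instantaneous direct Coulomb sum over point
charges, V = Σ q/r and E = Σ q r̂/r², with minimum-image distances for
orthorhombic boxes and a plain sum otherwise. No Ewald/PME and no cutoff
are applied: the package evaluates the field of a configuration, it never
propagates dynamics, and how the original MD handled long-range
electrostatics is a property of the trajectory, not of this analysis.
Triclinic boxes are rejected explicitly. A particle within 0.1 Å of an
expansion center raises a singular-geometry error naming the particle.

Solvation-shell analysis removes or keeps **whole molecules** (by
`molecule_ids`, minimum atom distance to the center), never single atoms,
so a water molecule's charges are never split; the default shell radius
is 5.5 Å, the first-shell extent around a thioether sulfur in water.
`radial_distribution` returns the number-density-normalized g(r) plus the
running coordination number n(r).

## Free-energy estimators

Each pair of adjacent ξ points is bridged by exponential averaging,
ΔA = −kBT ln⟨e^{−βΔU}⟩, where ΔU is the difference of the perturbed
ground-state energies of the two QC points evaluated **on the same
frame** (the frame's potentials at the sampling geometry's expansion
centers are applied to both points). Forward (ensemble i), backward
(ensemble i+1) and symmetric (mean of both ΔA estimates) directions are
exposed; the internal-energy step uses each point's own ensemble mean,
ΔU = ⟨U_{i+1}⟩_{i+1} − ⟨U_i⟩_i, whenever both traces are available. The
entropic term is defined as TΔS = ΔU − ΔA, so the decomposition identity
holds to machine precision wherever the three numbers appear together.
Exponential averages are computed with a max-shift (log-sum-exp), so
finite inputs can never overflow, and the Gibbs–Bogoliubov inequality
ΔA ≤ ⟨ΔU⟩ is preserved exactly.

Profiles chain the steps cumulatively, anchored at zero at the first
(reactant) point; the barrier is reported relative to that anchor, not to
the global minimum. Statistical errors per step come from block
averaging: the standard error of block means over a grid of block counts
(default 5/10/20), reporting the maximum over the grid as a plateau proxy
for correlated series; the ΔA error uses the delta method on the
max-shifted exponential weights. Step errors are propagated across the
profile in quadrature; correlation between adjacent steps (they share
ensembles) is not modeled, which tends to make the propagated profile
error conservative for anticorrelated and optimistic for correlated
steps — a documented limitation. Temperature defaults to 300 K
(kB·300 K = 0.59616 kcal/mol); all conversions go through a single
constants table (1 Hartree = 627.509 kcal/mol, 1 Å = 1.889726 bohr,
kB = 3.166812e−6 Hartree/K).

## Synthetic systems and what they do (and do not) show

The generator builds a four-atom linear QC (donor, central atom,
acceptor, spectator) scanned over n points. The gas-phase ground state
follows two half-cosine arcs: exactly `gas_barrier` above the reactant at
the interior maximum and exactly `product_offset` at the product.
Two charge schedules cover the two sulfur-reaction topologies:
`oxidation-like` (±q between donor and acceptor, peaking at the TS — the
charge-separating S–O–O oxidation) and `exchange-like` (one negative
charge localized on a terminal atom at the endpoints, shared between the
terminals at the TS — the trisulfide-anion exchange). Excited states ride
at fixed gaps with ESP charges replicated from the ground state, because
whether excited-state ESP charges are state-specific in practice is an
open question; the file schema accepts either.

The solvent is a linearized reaction field: the field at the QC center of
mass is Gaussian along the molecular axis with mean −coupling × charge
separation (sign convention such that positive coupling stabilizes
charge-separated states) and standard deviation `fluctuation_sd`; atomic
potentials are the uniform-field values −E·(R_N − r0). The toy dipole
matrix deliberately has no component along the field axis, so the
perturbed ground energy is **exactly linear** in the field, every
per-step ΔU is exactly Gaussian, and the chained profile has the closed
form ΔA_step = μ_step − βσ_step²/2 evaluated by `analytic_reference`.
Profiles that violate the linearity conditions are flagged
`approximate`.

Default study conditions: 25 points, 4 states, 28.2 kcal/mol gas barrier
with −40 kcal/mol products, 0.5 e transferred at the TS, 10⁴ frames per
ensemble. The coupling default (0.02 a.u. field per e) is sized so the
mean-field response removes roughly half the gas barrier, the magnitude
of solvent stabilization seen for charge-separating sulfur oxidations in
water. The fluctuation default (0.00145 a.u.) is the
fluctuation–dissipation value σ = √(χ kBT) for that coupling at 300 K
(susceptibility χ = coupling/ℓ with ℓ the fixed 4.8 Å donor–acceptor
separation; see `fdt_fluctuation_sd`): a bath violating this relation is
not a Boltzmann ensemble of any potential, forward and backward
estimators then target different quantities, and thermodynamic cycles do
not close. With the FDT-consistent default, cycles close and the
forward/backward/symmetric estimators agree in expectation.

What passing the synthetic tests shows: the Hamiltonian assembly,
diagonalization, ensemble evaluation, exponential averaging, chaining and
error estimation are each correct, and their composition recovers a known
closed-form free energy from sampled data. What it does not show:
fidelity of any particular force field or electronic-structure input,
convergence of real MD sampling, validity of the monopole truncation for
strongly inhomogeneous fields, or non-Gaussian solvent statistics
(hydrogen-bond switching, dielectric saturation). The published solvated
barriers themselves (14.9/19.0/12.2 kcal/mol) require DFT/TDDFT inputs
and 150 ns of MD and are outside desk scale; the package validates the
machinery, and reproduces the printed thermodynamic arithmetic
(decomposition and solvent comparisons) exactly.

## Numerical choices and problem sizes

- Internal units are Hartree atomic units; Å and kcal/mol at every user
  interface. Profile/trace/sample files store full `repr` precision so
  round trips are bit-exact.
- Degenerate inputs: zero-length bonds, clashing particles, empty frames
  and empty traces raise typed errors naming the offender; an empty
  environment frame is a valid zero perturbation.
- Tie-breaks: the barrier location is the first ξ at the maximum of the
  cumulative ΔA (numpy argmax convention).
- Test problem sizes are chosen to make statistical assertions sharp but
  cheap: unit tests use a 7-point/400-frame toy; the end-to-end recovery
  check uses the full default conditions (25 points × 10⁴ frames), which
  completes in seconds thanks to batched diagonalization; the Gaussian
  closed-form check uses 10⁶ samples; cycle closure uses 13 points ×
  2×10⁴ frames so per-step exponents stay in the well-sampled regime.
- Random streams: `numpy.random.default_rng([seed, point_index])`, so
  each ensemble is independently reproducible and adding points does not
  shift other ensembles' streams.

## Known limitations

- No self-consistent polarization between QC and environment; the
  environment is frozen point charges per frame.
- Atom-based expansion truncated at monopoles on the diagonal (inputs
  carry no atomic dipoles).
- Independent-step error propagation (see above).
- Orthorhombic periodicity only; minimum-image direct sums, no Ewald.
- The convenience reader for quantum-chemistry log files is not
  provided; profiles enter through the documented JSON schema.
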