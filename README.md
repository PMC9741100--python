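# pmmfep

Perturbed-matrix QM/MM free-energy profiles along chemical reaction
coordinates, with sulfur chemistry (thioether oxidation by H2O2,
thiolate/disulfide exchange) as the motivating application.

## The problem

Reactions of sulfur-containing amino acids — methionine oxidation to the
sulfoxide, cysteine thiol/disulfide interchange — sit at the heart of
cellular antioxidant defense. Their barriers are strongly
solvent-dependent: the charge separation that develops near the
transition state of an oxidation is stabilized by polar solvent, while
the delocalized trisulfide anion of an SN2 exchange is stabilized *less*
than its localized endpoints, so the same environment can lower one
barrier and raise another. Capturing this requires both a quantum
description of the reacting center and ensemble averaging over the
fluctuating environment.

`pmmfep` implements the perturbed-matrix route to that combination. The
quantum center (QC) is characterized once per point ξ of a scanned
reaction path (ξ = d(breaking bond) − d(forming bond)) by its gas-phase
state energies E_k⁰, dipole matrix μ and per-state ESP atomic charges
q_{N,k}. Each classical configuration of the environment (point charges)
then perturbs the M×M Hamiltonian in the unperturbed eigenbasis,

    H_kk = E_k⁰ + Σ_N q_{N,k} V(R_N) − E(r0)·μ_kk,
    H_kl = −E(r0)·μ_kl   (k ≠ l),

which is diagonalized per frame to give the perturbed ground-state energy
U. Adjacent points are bridged by exponential averaging (free energy
perturbation),

    ΔA_{i→i+1} = −kB T ln ⟨ e^{−βΔU} ⟩_i,     ΔA(ξ) = Σ_i ΔA_{i→i+1},

with internal energy ΔU(ξ) from ensemble means and TΔS = ΔU − ΔA.
Statistical errors come from block averaging. The package also provides
solvation-shell filtering (whole-molecule, 5.5 Å default radius), radial
distribution functions with coordination numbers, and a synthetic
toy-system generator with an exact closed-form reference for validating
the entire chain.

## Worked example

Run the default oxidation-like toy system — 25 points, 4 states, a
28.2 kcal/mol gas-phase barrier, 0.5 e of charge separation at the TS,
10⁴ solvent-field frames per point — and compare the sampled pipeline
against the closed-form reference:

```python
import pmmfep as pf

spec = pf.ToySystemSpec()                     # defaults described above
profile = pf.make_toy_qc(spec)
ref = pf.analytic_reference(profile, spec)    # exact Gaussian work identity
res = pf.run_pipeline(pf.RunConfig(synthetic=spec, seed=1, output_dir="run"))

print(f"analytic barrier : {ref.barrier:.3f} kcal/mol at xi = {ref.barrier_xi:.3f} A")
print(f"sampled barrier  : {res.barrier:.3f} +/- {res.barrier_err:.3f} kcal/mol")
```

prints

```
analytic barrier : 17.007 kcal/mol at xi = -0.933 A
sampled barrier  : 17.011 +/- 0.013 kcal/mol
```

The solvent response removes about 11 kcal/mol of the 28.2 kcal/mol gas
barrier and shifts its maximum toward the reactant side (the gas maximum
sits at ξ = −0.4 Å), exactly the phenomenology of a charge-separating
oxidation in water; the sampled estimate agrees with the closed form
within its block-averaging error. The run directory contains
`profile.tsv` (ξ, ΔA, ΔU, TΔS and errors in kcal/mol), `report.json`
(every setting needed to reconstruct the run) and `run.log`.

The same machinery handles real inputs: a QC profile in the documented
JSON schema (see `pmmfep.qc_model`) plus one XYZ/GRO trajectory with a
plain-text charge table per ξ point, configured in YAML and driven by
`run_pipeline` or the CLI:

```
pmmfep synth --out-dir toy                 # toy profile + samples + reference
pmmfep profile --config run.yaml           # full pipeline
pmmfep rdf --traj traj.xyz --charges q.txt --box 30,30,30 --center 0,0,0 --out rdf.tsv
pmmfep compare run/profile.tsv toy/analytic_reference.tsv
```

Worked-example arithmetic on published thermodynamic tables is exposed
directly: `pf.decompose(dA=14.9, dU=16.1)` returns the entropic term
1.2 kcal/mol, and `pf.compare_runs(19.0, 12.2)` the 6.8 kcal/mol
water-vs-DMF barrier difference of the exchange reaction.

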