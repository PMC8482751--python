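# fiberex

Monomer-exchange pathways in dynamic supramolecular fibers: do monomers leave
from the fiber **tips**, or through **backbone defects**?

One-dimensional supramolecular polymers constantly exchange monomers with the
surrounding solution. Two microscopic routes compete: detachment from the two
fiber ends, and a two-step backbone route in which an interior monomer first
pops out of stacking registry (a *defect*) and then escapes from that
defective state. `fiberex` implements a minimal coarse-grained particle model
of such fibers, a stochastic surrogate of the per-monomer state kinetics, two
independent defect-classification pipelines (supervised collective variables
and agnostic SOAP-style descriptors), rare-event rate estimation by
infrequent well-tempered metadynamics, and the kinetic model that turns the
measured rates into a pathway verdict.

The central statistic is the flux ratio

```
alpha = N_def * k_def->sol / (2 * k_tip->sol),
N_def = (N_tot - 2) * k_bulk->def / (k_bulk->def + k_def->bulk)
```

— the ratio of the total backbone escape flux to the total tip escape flux,
with the stationary defect number `N_def` from the creation/annihilation
balance. `alpha > 1` means backbone exchange dominates; solving `alpha = 1`
for `N_tot` gives the crossover fiber length at which the backbone route
takes over.

## Package layout

| module | contents |
|---|---|
| `fiberex.monomer` | coarse-grained monomer variants (triangle core, center dipole, solvophobic arms), pair energies, dimerization free energy |
| `fiberex.engine` | numba Langevin-dynamics engine (BAOAB, Verlet lists, truncated-shifted LJ + shifted-force Coulomb) |
| `fiberex.surrogate` | exact Gillespie surrogate of per-monomer BULK/DEFECT/TIP/SOLVENT kinetics |
| `fiberex.kinetics` | infrequent WT-MetaD, rescaled escape times, Poisson/KS reliability analysis |
| `fiberex.supervised` | four per-monomer CVs, spectral clustering, motif naming, defect counts |
| `fiberex.unsupervised` | SOAP-style descriptors, PCA, PAMM-style density clustering, rate matrices |
| `fiberex.pathway` | the alpha statistic, crossover length, pathway verdict |
| `fiberex.config` / `io` / `cli` | seeded run configurations, trajectory formats, staged pipeline |

See `docs/methods.md` for the model, the calibration rationale and all
numerical choices.

## Worked example

Generate a fiber-2-like stochastic trajectory (40 monomers, defect creation
0.3 /µs, annihilation 14 /µs), recover the rates from the observed state
sequence, and run the pathway analysis:

```python
from fiberex.surrogate import SurrogateRates, gillespie_stack, BULK, DEFECT
from fiberex.unsupervised import rate_matrix, stride_corrected_rates
from fiberex.pathway import RateSet, pathway_report

st = gillespie_stack(40, SurrogateRates(k_bulk_def=0.3, k_def_bulk=14.0),
                     t_end=500.0, seed=7, t_stride=0.01)
print("mean defects counted:", round(st.counts(DEFECT).mean(), 3))

rm = rate_matrix(st.states[:, 1:-1], t_stride=0.01, states=[BULK, DEFECT])
k_bd, se_bd, k_db, se_db = stride_corrected_rates(rm, BULK, DEFECT)
print(f"k_bulk->def = {k_bd:.3f} +/- {se_bd:.3f}   (truth 0.3)")
print(f"k_def->bulk = {k_db:.2f} +/- {se_db:.2f}   (truth 14)")

rs = RateSet(k_tip_sol=1.0, k_def_sol=1.0, k_bulk_def=k_bd, k_def_bulk=k_db,
             sigma_bulk_def=se_bd, sigma_def_bulk=se_db, n_tot=40)
rep = pathway_report(rs, measured_n_def=float(st.counts(DEFECT).mean()))
print(f"alpha = {rep.alpha:.3f} | verdict: {rep.verdict} "
      f"| crossover N = {rep.crossover_n:.0f}")
print(f"consistency ratio = {rep.consistency_ratio:.4f}")
```

Output:

```
mean defects counted: 0.784
k_bulk->def = 0.295 +/- 0.004   (truth 0.3)
k_def->bulk = 13.99 +/- 0.18   (truth 14)
alpha = 0.392 | verdict: TIPS | crossover N = 99
consistency ratio = 1.0002
```

A 40-monomer fiber with these kinetics exchanges through its **tips** (the
defect flux is ~0.4 of the tip flux); fibers of ~99 monomers or more would
flip to the backbone route. The equilibrium-balance prediction agrees with
the counted defect number to 0.02 %.

The same chain runs from the command line:

```sh
fiberex --out run all        # surrogate -> rates -> pathway
cat run/pathway_report.json
```

```json
{
  "alpha": 0.40203195936081276,
  "alpha_sigma": 0.0,
  "consistency_ratio": 1.0001888187553756,
  "crossover_n": 97.0,
  "n_bulk": 37.195936081278376,
  "n_def": 0.8040639187216255,
  "n_tot": 40,
  "provenance": { "n_def_source": "measured_n_def" },
  "verdict": "TIPS"
}
```

Every stage takes its seed from the run configuration, and repeated runs are
byte-identical.

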