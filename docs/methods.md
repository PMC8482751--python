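# Methods

This note records the scientific and numerical choices behind `fiberex`: the
coarse-grained model, the stochastic surrogate, the rare-event machinery, the
two defect-classification pipelines, and the kinetic pathway model that ties
them together. Units, defaults and calibration rationale are collected here so
that none of them have to be reverse-engineered from the code.

## 1. The question

One-dimensional supramolecular fibers exchange monomers with the surrounding
solution. Two microscopic routes compete:

* **tip exchange** — a monomer detaches from one of the two fiber ends;
* **backbone exchange** — an interior monomer first pops out of stacking
  registry (a *defect*), remains loosely attached, and then escapes to the
  solution from that defective state.

Which route dominates is a property of the monomer chemistry (how directional
its interactions are) and of the fiber length. The package quantifies the
competition with the flux ratio

```
alpha = N_def * k_def->sol / (2 * k_tip->sol)
```

where `N_def` is the stationary number of backbone defects and the two rate
constants are the per-monomer escape rates from a defect site and from a tip.
`alpha > 1` means backbone exchange dominates.

## 2. Coarse-grained monomer model (`fiberex.monomer`)

Each monomer is a rigid-bonded bead cluster in implicit solvent:

* a **core** of three beads on an equilateral triangle (side 1.33 σ) that
  provides the flat stacking face;
* a **center bead** carrying a point dipole, realized as two opposite charges
  (±q, default q = 1.45 e) at 0.2 σ separation along the core normal — the
  directional (out-of-plane) interaction;
* three radial **arms** of four beads each; the inner two beads are the
  variable solvophobic tier, the outer two are solvophilic (the corona that
  keeps fibers dispersed).

The three monomer *variants* differ only in the inner-arm bead class:

| variant | inner-arm class | character |
|---|---|---|
| 1 | C1 | weak lateral attraction — directional stacking dominates |
| 2 | C5 | intermediate |
| 3 | N0 | strong nondirectional attraction — defect-prone |

Solvent quality is folded into an effective Lennard-Jones ε table
(`monomer.eps_lookup`). The solvophobicity ordering is encoded as strictly
decreasing cross-ε with the solvophilic C1 class (C1–C1 0.08 > C1–C5 0.07 >
C1–N0 0.06) while the like-like attractions grow (C5–C5 0.30, N0–N0 0.55).

**Calibration.** The ε table, the thermostat temperature (k_BT = 0.35 ε) and
the dipole-site LJ shielding (DIP σ = 0.92, ε = 0.20) were calibrated together
so that the model sits in the physically meaningful regime: a variant-1
16-monomer fiber stays defect-free and exchanges only from its tips; a
variant-3 fiber is visibly defect-rich; and scaling the dipole charge upward
(1.2×, 1.4×) monotonically suppresses defects. This is calibration of a
minimal model into a target phenomenology, not a fit of any single number.
Two numerical pitfalls fixed the remaining constants:

* adjacent monomers can fuse their opposite dipole charge sites (runaway
  polarization); a stiffer dipole-cage bond (K = 2000 ε/σ², vs 400 for all
  other bonds) plus the DIP–DIP LJ shielding removes it;
* with the shielded dipole the equilibrium stacking distance comes out at
  c ≈ 1.12 σ, where the arm-bead LJ minimum sits — defects then cost lateral
  contact energy, as they should.

`dimerization_free_energy` integrates the mean restraint force over a ladder
of distance-restrained windows (thermodynamic integration over the
center-center distance) and is used to verify the variant ordering of binding
strengths.

## 3. Particle engine (`fiberex.engine`)

A Langevin-dynamics engine in reduced units (σ, ε, m = 1):

* **integrator** — BAOAB splitting, timestep 0.004 τ, friction 1 τ⁻¹;
* **nonbonded** — truncated-and-shifted LJ at r_c = 2.5 σ_ij and shifted-force
  Coulomb at r_c = 2.34 σ with relative dielectric ε_r = 15 (the charges only
  decorate the dipole sites, so the short cutoff is adequate);
* **bonded** — harmonic bonds on a triangulated scaffold (core triangle, arm
  chains plus next-nearest braces, dipole cage);
* **neighbor list** — Verlet list with 0.6 σ skin, rebuilt every 20 steps;
* all force loops are `numba`-compiled; a given seed reproduces trajectories
  bit-for-bit, and force blow-ups (|F| > 10⁶ or NaN) abort with a status flag
  rather than propagating garbage.

The double-charge dipole makes each monomer 2 beads larger than its
structural bead count (core + center + arms).

## 4. Stochastic surrogate (`fiberex.surrogate`)

System-scale statistics (stationary defect numbers, creation/annihilation
rates, escape-flux ratios) need far more sampling than the particle engine
can deliver in a test suite. The surrogate is an *exact* continuous-time
Markov emulation of the per-monomer state kinetics: each monomer is BULK,
DEFECT, TIP or SOLVENT; the two end monomers are pinned as tips; interior
monomers interconvert BULK ↔ DEFECT with rates `k_bulk_def`, `k_def_bulk`;
optional escape/re-adsorption channels connect to SOLVENT. Trajectories are
generated with the Gillespie stochastic simulation algorithm and sampled on a
regular stride, so every downstream estimator can be validated against known
generator parameters.

What the surrogate does **not** emulate: geometry, energetics, or any
coupling between monomers beyond tip bookkeeping. Two *renderers*
(`fiberex.fixtures`) bridge its exactly-known states into the inputs the
classification pipelines consume — canonical CV-space signatures with
Gaussian noise, and 3D center configurations in which defects are displaced
laterally by one stacking distance (fully out of registry) and solvent
monomers are scattered several c away from the axis.

## 5. Rare-event kinetics (`fiberex.kinetics`)

Escape events are rare at the particle level, so rates come from
**infrequent well-tempered metadynamics**: Gaussian hills of tempered height
`w0 * exp(-V/((gamma-1) kT))` are deposited sparsely on a slow collective
variable, and the physical escape time is recovered by exponential
reweighting of the elapsed time, `t* = sum_i dt * exp(V(s_i)/kT)`. An
ensemble of rescaled escape times is fit by the exponential MLE (τ = mean,
censoring-aware) and checked for Poissonian behaviour with a
Kolmogorov–Smirnov test — the standard reliability criterion for infrequent
metadynamics.

The machinery is validated on a 1D double well `V = barrier * (x² - 1)²`
(barrier 6 kT) where brute-force escape is still affordable: the reweighted
mean first-passage time must agree with the unbiased one within a factor of
two and pass the KS test.

`fiber_escape_wtmetad` applies the same scheme to the particle engine: the
bias acts on the target monomer's core-core coordination number (rational
switching function), with chain-rule bias forces on the monomer centers. For
simplicity the biased kernel evaluates forces once per step (a plain
velocity-Verlet-with-friction splitting rather than the main engine's full
BAOAB); this is acceptable for escape-time estimates, where the bias
potential dominates the error budget. A run commits to "escaped" when the
coordination stays below 0.2 for several consecutive deposition intervals
*and* the nearest core lies beyond two stacking distances.

`pathway_gap` expresses tip/backbone timescale separations in decades
(log₁₀ of the escape-time ratio).

## 6. Supervised classification (`fiberex.supervised`)

Four per-monomer collective variables are computed per frame:

1. **coordination** — switching-function contact count over center-center
   distances (R0 = 1.43 c, D_MAX = 4.47 c);
2. **min_core_distance** — nearest other center, in units of c;
3. **core_contacts** — core-bead contact count (R0 = 1.17 c);
4. **dipole_contacts** — dipole-site contact count (R0 = 0.81 c).

All switching functions are the stretched rational form (n = 6, m = 12),
shifted and rescaled to reach exactly zero at D_MAX (the PLUMED D_MAX
convention). The length ratios mirror a 0.47 nm bead mapping.

The standardized table is clustered by spectral clustering with a
nearest-neighbours affinity. The `lobpcg` eigensolver is forced: the default
ARPACK shift-invert path can stall indefinitely inside the sparse LU solve
when the kNN graph is disconnected (which defect/solvent configurations
routinely produce).

Clusters are *named* by centroid rules (`assign_motifs`): coordination ≥ 1.5
→ BULK; coordination in [0.5, 1.5) with min-distance ≤ 1.5 c → an edge motif,
split into TIP vs DEFECT by whether the monomer sits at an end of the
connected stack (degree-1 node of the largest connected component at link
distance 1.6 c); min-distance > 2 c → EXCHANGED; anything else UNASSIGNED.
Defect counts are block-averaged before feeding the pathway model.

## 7. Unsupervised classification (`fiberex.unsupervised`)

The agnostic route starts from a rotation/permutation-invariant SOAP-style
power-spectrum descriptor of each monomer-center environment: Gaussian radial
shells times spherical harmonics, contracted as
`p(n, n', l) = sum_m c_nlm conj(c_n'lm)` (324 features at n_max = l_max = 8).
It is implemented in-package (SciPy spherical harmonics) and verified by
exact invariance tests; environments with no neighbour map to the all-zero
fingerprint. PCA (deterministic sign convention) reduces the features to a
few scores.

Clustering is PAMM-style probabilistic analysis of molecular motifs:

1. farthest-point-sampling grid over the score space;
2. Gaussian KDE on the grid (bandwidth = fspread × mean feature std);
3. quick-shift uphill linking into micro-clusters, with an *adaptive*
   per-point link range (1.5× the local 10th-neighbour grid spacing, floored
   at the bandwidth) so sparse grid periphery does not fragment;
4. bootstrap stability analysis (73 resamples): micro-clusters whose modes
   coalesce in more than half the resamples are merged;
5. population-based merging: macro-clusters lighter than `merger_threshold`
   are absorbed into their nearest-mode neighbour, iterated — a threshold
   near 1 collapses everything into a single macro-cluster.

Macro populations give the free-energy surface `F_i = -kT ln(p_i/p_max)`, and
frame-to-frame macro transitions give the rate matrix
`R[a→b] = N_events / t_tot`. Because states are observed on a stride, fast
two-state flipping is undercounted; per-monomer rates are corrected by
inverting `lambda_naive = lambda * g(lambda * tau)` with
`g(u) = (1 - e^(-u))/u` (Brent's method), where τ is the stride.

The descriptor cannot know *absolute* position along the fiber, so TIP vs
DEFECT — positional by definition — is decided by the same motif-naming layer
as the supervised route: `assign_motifs` accepts any cluster labelling. The
cross-pipeline agreement check therefore compares *named motifs* from both
pipelines on a shared geometric rendering.

## 8. Kinetic pathway model (`fiberex.pathway`)

With the defect creation/annihilation balance at stationarity,

```
N_def = (N_tot - 2) * k_bulk_def / (k_bulk_def + k_def_bulk)
```

substituting into alpha gives the rates-only combined form, and setting
alpha = 1 yields the crossover length — the smallest fiber for which backbone
exchange wins. `pathway_report` prefers a *measured* defect number when one
is available and then reports the equilibrium prediction as a consistency
ratio; uncertainties are propagated to first order (delta method), and the
verdict is TIPS / BACKBONE / COMPETING depending on whether the 1-sigma band
of alpha clears, misses or straddles 1.

## 9. Problem sizes, determinism, limitations

* Test-suite problem sizes (10–40 monomers, 10⁵–10⁶ engine steps, 500 time
  units of surrogate) are chosen so the whole suite runs in minutes on one
  CPU while every estimator still resolves its target at 3-sigma.
* Every stochastic stage takes an explicit seed (`RunConfig.seeds`); the CLI
  pipeline is byte-deterministic for a fixed configuration.
* Limitations: implicit solvent (no hydrodynamics), short-cutoff
  shifted-force electrostatics (adequate only because charges are confined to
  compact dipoles), a fixed-topology fiber in the surrogate (no
  fragmentation/fusion), and a single-CV metadynamics bias (sufficient for
  escape, not for re-adsorption kinetics).
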