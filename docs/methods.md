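# Methods

## The common-core / serial-atom-insertion approach

`ccsai` computes relative free energy differences between small molecules
without ever transforming one molecule directly into another.  Instead, each
physical end-state is mutated into a shared *common core* (CC): the maximum
common substructure of the pair, extended by a single junction LJ particle X.
For two molecules A and B sharing a core, the relative solvation free energy
difference is assembled from four legs of a thermodynamic cycle,

    ddG(A -> B) = (dG_vac,B->CC - dG_solv,B->CC)
                - (dG_vac,A->CC - dG_solv,A->CC),

which is antisymmetric under exchange of A and B.  (The verbal convention —
"the second step is computed as the negative of the B-to-CC difference" —
and the antisymmetry invariant fix the sign; printed forms of this equation
in the literature sometimes order the two double differences differently,
so the package pins the convention above and tests it.)

Dummy atoms — atoms whose charge and LJ well depth are exactly zero — retain
their bonded terms along the whole path.  Because a dummy region attached
through a single junction contributes an *additive* term to the partition
function that is identical in both environments, it cancels from the double
difference.  Everything in the mutation machinery exists to keep that
cancellation exact:

* **Charge conservation.** Non-core charges (including X's) are scaled
  linearly to zero over equally spaced multipliers.  At every stage the
  compensating charge is recomputed *from scratch* (never accumulated) and
  placed on the physical core atom bonded to X, so the total charge of every
  intermediate equals the end-state total to machine precision.
* **Binary LJ turn-off (serial atom insertion).** LJ parameters are only
  ever fully on or exactly zero; no fractional LJ scaling exists anywhere in
  the code path, which is what makes soft-core potentials unnecessary and
  thermodynamic integration inapplicable.  All dummy-region hydrogens are
  turned off in one stage, then heavy atoms at one or two per stage, peeled
  farthest-from-the-core first (the ordering is a package choice; peeling
  from the outside keeps the remaining fragment bonded to interacting
  atoms).  The retyping of the junction atom to the X parameters is the last
  vdw-stage action.
* **Core adjustment.** After the turn-off stages the two molecules' cores
  may still differ in the bonded terms involving X; these are interpolated
  linearly to the target values taken from a template atom (the
  "corresponding hydrogen" rule).  Stages that would be no-ops are omitted:
  a methane-like end-state yields exactly one elec stage, one vdw stage
  (the single H -> X retype) and no core adjustment.

### Junction particle and templates

The junction particle X is the dummy-region atom bonded to the core.  Its
default parameters (epsilon 0.15 kcal/mol stored as a magnitude, sigma
1.5 A, zero charge) are configuration, not constants.  Keeping X interacting
converts a *triple junction* (an attachment atom with three core
neighbours, the hard case for dummy-atom decoupling) into a *terminal
junction* (one core neighbour, the benign case); the classifier defines the
kind by the attachment atom's number of core neighbours.

Bonded parameters involving X in the target core come from a designated
template atom, by default the smallest-index core hydrogen on the
attachment atom.  Substituting X -> template can produce a degenerate tuple
(e.g. the angle H-C-X when the attachment carbon carries a single
hydrogen); the lookup then falls back first to another equivalent core
hydrogen and finally to any all-core term with the same kind and element
pattern.  For the built-in fixtures, whose parameters are uniform per
element class, this reproduces exactly the parameters of the corresponding
hydrogen in the reference core molecule.

Supported topology: exactly one dummy region per molecule, attached to the
core through exactly one atom.  Ring-spanning mutations, multiple regions,
and pairs where only one side has a dummy region are refused with explicit
errors.  One deliberate extension: a junction with *no* bonded core
neighbour is accepted when the scaled region carries no charge — this is
the degenerate "annihilate a free LJ particle" case used by the quadrature
validation, where a bond would remove the very interaction being
annihilated through the 1-2 exclusion.

### Common-core search

The search is an exact McGregor-style branch and bound over *induced*
connected common subgraph mappings, with an upper bound pruning subtrees
that cannot beat the incumbent.  Ring preservation (every smallest-set-of-
smallest-rings ring matched completely or not at all) is enforced as a
validity filter on candidates, not as a pruning rule, so a partially
matched ring can still be completed deeper in the tree.  Ties between
equally large solutions are broken by the lexicographically smallest sorted
index list in A, then in B — output is fully deterministic, and the
identity pair maps every molecule onto itself.  Exactness is affordable
because the tool targets desk-scale systems (about 30 atoms); the test
suite verifies maximality against exhaustive subset enumeration on all
pairs with a side of at most 12 atoms.

Matching criteria: `element` (chemical element only), `element_and_degree`,
and `full_type` (element, degree and LJ parameters — a force-field-type
level match).

## The toy sampling engine

The engine exists so every alchemical state can be sampled on a desk, with
no external MD program.  It is a real, tested implementation — not a mock —
but deliberately minimal:

* Potential: harmonic bonds `k (b - b0)^2` and angles `k (th - th0)^2`
  (force constants include the conventional factor, i.e. no extra 1/2),
  periodic dihedrals `k (1 + cos(n phi - d))`, Coulomb `332.0637 q_i q_j /
  r` with no cutoff, and Lennard-Jones `4 eps [(sig/r)^12 - (sig/r)^6]`
  with Lorentz-Berthelot combination (arithmetic sigma, geometric epsilon)
  and a selectable taper.  1-2 and 1-3 pairs are excluded; 1-4 and beyond
  interact fully.
* Tapering options for LJ only: `vswitch` (the classic cubic-in-r^2
  potential switch, `S(r) = (roff^2 - r^2)^2 (roff^2 + 2 r^2 - 3 ron^2) /
  (roff^2 - ron^2)^3`), `vfswitch` (this package's convention: a C2
  quintic polynomial taper in r standing in for force-switched truncation —
  the genuine force-switch form shifts the potential by a constant below
  r_on, which would break the unit boundary value the switching-factor
  contract requires), `hard_cutoff`, and `none`.  Both smooth options are
  exactly 1 at r_on and exactly 0 at r_off with continuous first
  derivatives.
* Integrators: BAOAB-splitting Langevin dynamics (kB = 0.0019872041
  kcal/mol/K; units A, fs, amu, kcal/mol) and a Metropolis Monte Carlo
  sampler with single-atom uniform displacements.  Both are exactly
  reproducible from the recorded seed.  Defaults follow the production
  protocol (303.15 K, 1 fs, friction 1/ps, frames every 100 steps); toy
  runs use far fewer steps.  The Langevin thermostat is validated by
  equipartition and Boltzmann-variance tests; the MC sampler against the
  same closed forms.
* Minimisation: gradient descent with backtracking line search to a
  force-norm tolerance, used before production sampling of each state.
* Environments: no periodic boundaries, no Ewald sum, no barostat.  The
  "solvated" leg at desk scale is the `lj_bath` fixture — the solute
  embedded among neutral LJ particles inside an isotropic harmonic trap.
  This is a *scale substitution*, loudly not water: it exercises every code
  path (switching functions, solute-environment overlap, cycle assembly)
  but reproduces no aqueous solvation physics.  Reduced potentials carry no
  pressure-volume term because all toy sampling is at constant volume.

### What the fixtures emulate — and what they do not

`make_fixture` builds deterministic analogues of common small solutes
(methane-, ethane-, methanol-, toluene-, cyclopentane-like graphs, plus two
cyclopentyl-aryl regioisomers) with invented but physically plausible
parameters.  Charges are constructed so every molecule is neutral and so
that molecules sharing a core end with *identical* core parameters after
mutation — e.g. the methane-like carbon at -0.36 e absorbs its departing
hydrogen's +0.09 e to land at the -0.27 e of an ethane-like methyl carbon.
Passing tests therefore demonstrate the correctness of the machinery
(matching, path generation, estimators, cycle algebra) under controlled
conditions; they say nothing about force-field accuracy, water, or
conformational sampling of real solutes.

## Free energy estimation

Frames are selected by the fixed production rule — drop the first quarter,
keep every third of the remainder — and evaluated under all K parameter
sets to form the K x N dimensionless reduced-potential matrix
`u_kn = U(x_n; lambda_k) / kB T`.  A merged-trajectory evaluation mode
(one concatenated frame array) is provided and proven identical to
per-trajectory evaluation.

The MBAR estimator is implemented in the package (no external estimator
library): self-consistent iteration on the log-sum-exp form with an
adaptive switch to Newton-Raphson steps once the iterate is close, falling
back to self-consistent iteration whenever a Newton step fails to reduce
the residual (pure Newton can oscillate at machine precision on small
matrices).  Defaults: relative tolerance 1e-8, at most 10 000 iterations;
non-convergence raises an error carrying the residual.  Free energies are
dimensionless and anchored at f_0 = 0; conversion to kcal/mol happens only
at reporting.  Uncertainties come from the asymptotic covariance in its
truncated-SVD form (uncorrelated-sample approximation) — correlated frames
therefore understate errors, which is why validation sampling favours
exactly drawn or strongly thinned samples.  A two-state BAR solver
(bisection on the implicit equation) provides an internal cross-check; the
test suite additionally verifies the estimator against an independent
scipy minimisation of the convex MBAR objective to 1e-6.

The row-stochastic K x K overlap matrix is the standard MBAR diagnostic;
nearest-neighbour entries below 0.03 (a package choice — "sufficient
overlap" is not a number anywhere) produce a warning, never a failure.

Replicates differ only in their derived seeds (`base_seed + 7919 r +
104729 k`, recorded per state in the leg log); per-leg means and standard
deviations over replicates feed the cycle, and the final uncertainty is
the root-sum-square of the four leg deviations (Gaussian propagation).

## Validation problem sizes

The self-checks in `scripts/acceptance.py` use: 5 000 exactly drawn frames
per state for the two-state harmonic MBAR reference (spring ratio 4, exact
answer ln 2); 240 000 Metropolis moves per state (1 000 retained frames)
for the trap-pair annihilation against 3-D Gauss-Legendre quadrature of
both configuration integrals (240 radial x 120 angular points, converged
to ~1e-13); and a four-leg methane-like -> ethane-like toy cycle with two
replicates at desk-scale sampling budgets.  These sizes are the package's
validation choices: large enough for the three-standard-error bands of the
stochastic checks, small enough to run on one CPU in minutes.

## Known limitations

* Exact MCS is exponential in the worst case; it is intended for (and
  tested at) desk scale, not for ligands with many symmetric branches.
* Dihedral interpolation between differing multiplicities is refused
  rather than guessed; impropers, Urey-Bradley terms and CMAP are not
  modelled at all.
* One dummy region per molecule; no ring-spanning mutations; no
  charge-interpolation stage for cores whose *charges* differ between the
  two molecules beyond what the compensation rule absorbs.
* The LJ bath is not a solvent model, and the toy engine's error bars
  assume uncorrelated frames.
* CHARMM-format output is export-only (PSF X-PLOR EXT, RTF, PRM); imports
  are out of scope.
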