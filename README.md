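# ccsai — common-core / serial-atom-insertion free energy calculations

`ccsai` computes **relative alchemical free energy differences** between
small molecules.  Instead of transforming molecule A directly into molecule
B, each physical end-state is mutated into a shared **common core** (CC):
the maximum common substructure of the pair plus one junction LJ particle X.
Because every mutation only *turns interactions off* — charges first, then
Lennard-Jones parameters in discrete, binary steps (**serial atom
insertion**, SAI) — the intermediate states are plain, fully parameterized
systems that any sampling engine can simulate, with no soft-core potentials
and no alchemy-aware code in the sampling loop.

For two molecules sharing a core, the relative solvation free energy
difference comes from a thermodynamic cycle,

```
ddG(A -> B) = (dG_vac,B->CC - dG_solv,B->CC) - (dG_vac,A->CC - dG_solv,A->CC)
```

where each leg is estimated with the multistate Bennett acceptance ratio
(MBAR) from the K x N matrix of reduced potentials u(x, lambda) =
U(x; lambda) / kB T, and dummy atoms (zero charge, zero LJ) contribute an
additive partition-function term that cancels exactly from the double
difference.

The package is aimed at method development and teaching at desk scale: it
ships a deterministic fixture generator (methane-, ethane-, methanol-,
toluene-, cyclopentane-like molecules and an LJ-bath "solution" stand-in),
a self-contained toy engine (Langevin dynamics and Metropolis Monte Carlo
with vswitch / vfswitch / hard-cutoff LJ tapering), and its own MBAR/BAR
implementation with overlap diagnostics — everything needed to run a
complete relative free energy cycle on one CPU in minutes.

## Worked example

Discover the common core between a methane-like and a toluene-like
molecule, insert the junction particle, and plan the alchemical path for
the toluene side:

```python
from ccsai import (make_fixture, find_common_core, insert_junction_particle,
                   plan_path, ScheduleConfig)

methane = make_fixture("methane_like")
toluene = make_fixture("toluene_like")
ccmap = find_common_core(methane, toluene)
print("common core:", len(ccmap.pairs), "atom pairs:", ccmap.pairs)
ccmap, target_a, target_b = insert_junction_particle(ccmap, methane, toluene)
print("junction atoms:  methane ->", ccmap.junction_a,
      " toluene ->", ccmap.junction_b)
path = plan_path(toluene, ccmap, ScheduleConfig(
    n_elec_stages=3, heavy_atoms_per_vdw_stage=2, n_cc_adjust_stages=4))
for st in path.states:
    print(f"state {st.state_index:2d}  {st.stage:9s} scale={st.scale:5.3f}  "
          f"altered={sorted(st.altered_atoms)}")
```

prints

```
common core: 4 atom pairs: ((0, 0), (1, 7), (2, 8), (3, 9))
junction atoms:  methane -> 4  toluene -> 1
state  0  endpoint  scale=1.000  altered=[]
state  1  elec      scale=0.667  altered=[2, 3, 4, 5, 6, 10, 11, 12, 13, 14]
state  2  elec      scale=0.333  altered=[2, 3, 4, 5, 6, 10, 11, 12, 13, 14]
state  3  elec      scale=0.000  altered=[2, 3, 4, 5, 6, 10, 11, 12, 13, 14]
state  4  vdw       scale=0.250  altered=[10, 11, 12, 13, 14]
state  5  vdw       scale=0.500  altered=[3, 4]
state  6  vdw       scale=0.750  altered=[2, 5]
state  7  vdw       scale=1.000  altered=[1, 6]
state  8  cc_adjust scale=0.250  altered=[0, 1, 7, 8, 9]
state  9  cc_adjust scale=0.500  altered=[0, 1, 7, 8, 9]
state 10  cc_adjust scale=0.750  altered=[0, 1, 7, 8, 9]
state 11  cc_target scale=1.000  altered=[0, 1, 7, 8, 9]
```

Reading the trace: the common core is the methyl group (the four matched
atom pairs); in methane the fourth hydrogen becomes the junction X, in
toluene the ring carbon bound to the methyl group does.  The path then
switches off the ring charges in three equal steps (the five ring carbons,
five ring hydrogens, and X), turns off all five ring hydrogens' LJ
parameters in a single step followed by the ring carbons two at a time
(outermost first, ending with the C -> X retype), and finally interpolates
the bonded parameters involving X to those of a methyl hydrogen.

Estimating a free energy difference with the built-in MBAR against a case
with a closed-form answer — two harmonic wells with a spring-constant
ratio of 4, whose exact dimensionless free energy difference is ln 2:

```python
import math, numpy as np
from ccsai import make_analytic, solve_mbar
from ccsai.free_energy import ReducedPotentialMatrix

T = 303.15
soft, stiff = make_analytic([25.0]), make_analytic([100.0])
rng = np.random.default_rng(1)
n = 5000
x = np.vstack([soft.sample(n, T, rng), stiff.sample(n, T, rng)])
u = np.vstack([soft.reduced_potential(x, T), stiff.reduced_potential(x, T)])
result = solve_mbar(ReducedPotentialMatrix(u=u, counts=[n, n], temperature=T))
print(f"MBAR delta f = {result.f_k[1]:.4f} +- {result.uncertainties[0, 1]:.4f} kT")
print(f"exact answer = ln 2 = {math.log(2):.4f} kT")
```

prints

```
MBAR delta f = 0.6875 +- 0.0087 kT
exact answer = ln 2 = 0.6931 kT
```

i.e. the estimate lands within one standard error of the exact value.

## Command line

A thin CLI wraps the library:

```sh
ccsai fixtures                       # list built-in systems
ccsai plan    --config run.yaml --molecule toluene_like --out states/
ccsai sample  --config run.yaml --molecule toluene_like --out traj/
ccsai analyze --config run.yaml --molecule toluene_like \
              --trajectories traj/ --out report/
ccsai run     --config run.yaml --out results/
```

`run.yaml` is a declarative run configuration (molecule pair, matching
criterion, stage schedules, sampler settings per environment, replicate
count, base seed); CLI flags override file values.  Intermediate states are
written as portable text state files, optionally alongside CHARMM-format
PSF/RTF/PRM exports.

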