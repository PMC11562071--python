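# pipchain

Permutationally invariant polynomial (PIP) potential energy surfaces for
flexible alkane chains — two linear constructions over one fitting, dynamics
and analysis stack, exercised end to end on a built-in synthetic alkane
force field.

## Who this is for

Researchers building machine-learned potentials for large, floppy
hydrocarbons from quantum-chemistry data: the package implements the basis
construction, linear regression, analytic gradients, normal-mode analysis,
microcanonical dynamics and torsional analysis needed to go from a labeled
set of geometries to a usable surface, at desk scale.

## The two constructions

Both express the energy as a linear expansion in PIPs — orbit sums of
monomials in Morse variables y_ij = exp(−r_ij/a) under a declared like-atom
permutation group — fitted by SVD least squares:

**Fragmented basis (F-PES).** For a large molecule the full PIP basis over
all N(N−1)/2 pair variables is intractable, so the basis (not the energy)
is assembled as the deduplicated union of PIP bases on a few overlapping
atom subsets:

    V(x) = c0 + Σ_n Σ_i c_i^(n) p_i^(n)(τ_n)

where τ_n are the Morse variables of fragment n. Fragments are chosen
greedily from the data set's per-pair maximum Morse values, under the rule
that a fragment containing a permuting atom contains its whole permutation
class. For n-tetradecane (C14H30) the canonical three-fragment partition
(24/23/23 atoms) gives 661 distinct Morse variables of the 946 pairs and a
14,739-term basis at polynomial order 2.

**Many-body expansion (MB-PES).** A unified fit of

    V = V_1b + V_2b + V_3b + V_4b

with typed blocks: power series in the pair Morse variable for CC/CH/HH;
purified PIP bases of A3/A2B symmetry for CCC/CCH/CHH/HHH (order 8) and
A4/A3B/A2B2 symmetry for the five quadruple types (order 7); per-order
Morse ranges (2.5/1.8/1.2 bohr) and distance cutoffs (10/8/6 Å) with a C²
quintic switch on the tuple's largest internal distance. Purification
removes every polynomial that fails to vanish in any dissociation channel,
making the expansion size consistent; the assembled basis has
1 + 30 + 220 + 976 = 1227 coefficients and is manifestly invariant under
all like-atom permutations.

Around the models: weighted SVD fitting with energy ceilings and
train/test splits, analytic gradients (with the eRMSE/eWRMSE/eMAE/R²/gRMSE
metric set), finite-difference Hessians and harmonic normal modes, a
velocity-Verlet NVE engine with the equal-atomic-kinetic-energy /
zero-angular-momentum initialization protocol and exploding-trajectory
guards, rigid torsional scans with threefold-sine and even-polynomial fits,
periodic 1D DVR for torsional levels, and distribution observables
(end-to-end distance, cos θ of all backbone dihedrals).

The `synthetic_data` module supplies the test bed: a smooth valence force
field for alkanes (harmonic bonds/angles, cosine torsions, Lennard-Jones
with 1-4 exclusion, analytic gradients) plus thermal-Langevin,
normal-mode-displacement and head-to-tail-grid samplers that emit labeled
extended-XYZ datasets.

## Worked example

```bash
python examples/05_torsion_scan_dvr.py
```

prints (toy butane, bonded terms only):

```
methyl torsion  A sin(3 phi - phi0) + a:
  amplitude 600.0 cm^-1, phi0 4.712 rad, offset -600.0 cm^-1, residual RMS 7.72e-13
  barrier (2A) = 1200 cm^-1
  rotational constant B = 5.514 cm^-1
  lowest torsional levels (cm^-1): 118.2 118.2 118.2 349.0 349.0 349.0

backbone torsion, even-polynomial fit, stationary points (angle rad, energy cm^-1):
  GM  at 3.142:      5.5
  LM  at 1.098:    367.3
  ...
  TS2 at 0.059:   1591.7
```

The methyl scan is exactly threefold (residual at rounding level), the
1200 cm⁻¹ barrier holds near-degenerate torsional triplets below it, and
the backbone curve shows the anti global minimum (θ = π), gauche local
minima, the anti/gauche saddle (TS1) and the cis barrier (TS2) — the
textbook alkane torsional landscape. `examples/02_fragmented_fit.py` and
`examples/04_nve_dynamics.py` continue the pipeline: a fragmented fit of
toy butane reaches a train eRMSE of ~170 cm⁻¹ on 1,754 frames, and NVE
trajectories on that surface (10,000 steps at dt = 5 au) conserve total
energy to within about a wavenumber.

There is also a thin CLI (`pipchain basis|fragments|mbbuild|synth|fit|eval|
opt|freq|md|scan|convert|inspect`) over the same library calls.

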