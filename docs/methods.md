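# Methods

This note records the models, conventions, parameter choices and known
limitations of the package, in the spirit of a reference manual section.

## PIP bases over Morse variables

Internal units are bohr and hartree throughout; Å and cm⁻¹ are converted
once at I/O boundaries (1 bohr = 0.529177210903 Å, 1 hartree =
219474.6313632 cm⁻¹). Pair variables follow one canonical order everywhere:
lexicographic (i, j) with i < j over 0-based atom indices — the same order
`scipy.spatial.distance.pdist` emits.

A monomial is a product of positive powers of pair Morse variables
y = exp(−r/a); a PIP is the plain (unnormalized) sum of one orbit of
monomials under the group generated by within-class atom transpositions.
Bases contain every orbit with total degree 1..M and never a constant term;
models carry a single separate constant coefficient. Enumeration is
deterministic (by degree, then the lexicographically smallest orbit member)
so coefficient vectors are portable; a monomial-count ceiling guards
against accidentally requesting an intractable basis.

**Purification.** A purified basis keeps only polynomials that vanish in
*every dissociation channel*: for every bipartition of the atoms into two
non-empty groups, every orbit member must contain at least one cross-group
pair variable. For two and three atoms this coincides with the familiar
one-atom-limit rule; for four atoms the 2+2 channels remove additional
polynomials (A4 order 7: 119 → 77; the single-atom rule alone would leave
89). Purification is algebraic, on monomial supports; a numerical
cross-check (displace one atom to 10⁴ bohr, all purified PIP values below
10⁻¹²) is kept in the tests.

## Fragmented basis

Fragment selection is greedy closure on the data set's per-pair maximum
Morse values: start from the center's whole permutation class, repeatedly
add the candidate class with the strongest contact to any included atom,
and stop at the first candidate whose class would overflow the atom cap.
Ties break to the lowest atom index. The stop-at-first-overflow rule and
the tie-break are conventions this package fixes and pins in tests; other
reasonable greedy variants exist and can produce fragments differing by one
class near the cap.

Union assembly deduplicates identical polynomials by their global monomial
sets (sorted ((i, j), power) tuples — robust to fragment-local ordering).
Two scopes are provided:

* `dedup="all"` (default): a polynomial is dropped if it appeared in any
  earlier fragment. The surviving set is independent of fragment order.
* `dedup="chain"`: each incoming fragment is deduplicated only against the
  surviving entries of the immediately preceding fragment, as sequential
  fragment-assembly pipelines do. For the canonical tetradecane fragments
  at order 2 this yields 14,739 terms versus 14,694 for full
  deduplication; the 45-term difference is exactly the accidental overlap
  of fragments 1 and 3 through the two terminal-methyl hydrogen classes
  plus one methylene pair. The chain count is the one quoted for the
  reference partition.

The canonical three-fragment tetradecane partition (centers C1/C7/C13,
cap 24, sizes 24/23/23, under the permutation scheme with the two
terminal-methyl H triples and twelve methylene H pairs) ships as
`TETRADECANE_FRAGMENTS`. Duplicate-free coverage of the two chain ends in
one fragment matters: pairs not covered by any fragment are invisible to
the model, which can therefore not repel the corresponding atoms —
trajectories and optimizations exploit exactly such blind spots (see
Limitations).

## Many-body model

Defaults: Morse ranges a = (2.5, 1.8, 1.2) bohr, polynomial orders
M = (10, 8, 7), and switching windows (9–10, 7–8, 5–6) Å for 2-, 3- and
4-body terms, encoding the expectation that higher-order interactions are
shorter ranged. The switch argument is the tuple's largest internal
distance (the pair distance itself for n = 2); the switch multiplies the
whole tuple contribution. Its form, s = 1 − (10t³ − 15t⁴ + 6t⁵), is C² at
both ends, so energies and analytic gradients are continuous through the
cutoff seams (asserted to 10⁻¹⁰/10⁻⁶ in tests). CCH and CHH share the A2B
basis *structure* but own independent coefficient blocks, and likewise for
every type pair related by relabeling. Within a tuple, atoms order
canonically C-before-H, each sub-block ascending by global index.

The coefficient layout is [constant, CC, CH, HH, CCC, CCH, CHH, HHH, CCCC,
CCCH, CCHH, CHHH, HHHH] = 1 + 30 + 220 + 976 = 1227 terms at the defaults.
Because tuples are enumerated over all atoms, the model is invariant under
every like-atom permutation (including C↔C) to rounding, is size
consistent by construction, and evaluates any CnH2n+2 molecule with one
coefficient vector. Serialization stores only the configuration and
coefficients; bases are regenerated deterministically on load.

Evaluation compiles each typed basis into flat (variable, power) slot
arrays grouped by slot count, evaluated with a power-table gather and one
`reduceat` per batch of tuples; gradients form partial products directly
(never by division), so exact zeros in Morse variables are safe.

## Fitting

The weighted least-squares problem min Σ w_i (V(x_i) − E_i)² is solved by
row-scaling features and targets by √w and truncated-SVD `lstsq` with a
relative singular-value floor (default rcond 10⁻¹⁰, exposed). Overdetermined
systems are required; inverse-energy weights w = ε/(ε + ΔE) with ε = 0.02
hartree default on for fragmented models and off for many-body models.
Energy ceilings filter frames by E − E_min; splits are uniform random
without replacement, seeded. Gradients are never fit targets; gradient
metrics compare analytic model gradients with stored reference gradients on
a seeded subsample.

A practical caveat this package measures rather than hides: the many-body
feature columns span ~10 orders of magnitude (high powers of small 4-body
Morse variables), so a relative rcond keeps an effective rank well below
the nominal term count on desk-scale data. Column equilibration would raise
the rank and the training fit at the cost of held-out error when rows per
coefficient are few; the default solver is the plain relative-rcond SVD.

## Geometry machinery

Hessians are central differences of analytic gradients (default step
5×10⁻³ bohr), symmetrized. Normal modes solve the mass-weighted
eigenproblem with standard atomic weights (H 1.008, C 12.011 amu); the six
smallest-magnitude eigenvalues (five for a linear molecule, via
`n_remove`) are discarded and imaginary frequencies report as negative
wavenumbers. The optimizer is L-BFGS-B on the analytic gradient with a
max-norm gradient tolerance (default 10⁻⁶ hartree/bohr) and an optional
energy floor that raises a hole-detection error. `find_minimum` adds
mode-following: when the converged stationary point retains imaginary
modes, it displaces along the most negative mode (±0.25 bohr, both signs)
and re-optimizes — low-order fitted surfaces routinely place their true
minima at slightly rotated methyls relative to an idealized start.

## NVE dynamics

Velocity Verlet, default time step 5 au (≈ 0.121 fs). Initialization gives
every atom the same kinetic energy in a seeded random direction, projects
out center-of-mass momentum and (via the inertia tensor) total angular
momentum, then rescales speeds so KE equals the requested total energy
above the starting minimum. Explosion guards — the symptom is an
"exploding" molecule — fail a trajectory when the potential drops more
than 5,000 cm⁻¹ below the start (a hole), when any initially bonded pair
(pairs under 4 bohr at step 0) stretches beyond 6 Å, or on non-finite
forces; failures are flagged, never raised, and ensemble statistics pool
recorded frames of completed trajectories only. Runs are bitwise
reproducible for a fixed seed, model and configuration.

## Torsional analysis

Dihedrals use the signed convention in which the reference quadruple
(0,0,0)/(1,0,0)/(1,1,0)/(1,1,1) measures 3π/2, mapped to [0, 2π); the anti
backbone sits at θ = π (cos θ = −1) and planar cis at cos θ = +1. Scans
are rigid: the rotating side of a C–C bond (the far carbon's substituents
and everything beyond — `chain_rotating_set`) turns about the bond axis by
Rodrigues rotation, preserving all within-side internals exactly. Fits:
A sin(3φ − φ₀) + a, linearized over (A cos φ₀, A sin φ₀, a) — an amplitude
is fitted because torsional curves in cm⁻¹ require one, and unit-amplitude
inputs recover (φ₀, a) exactly — and even polynomials in (θ − π) up to
degree 12. Stationary points of the *fitted* curve are located by
derivative sign changes on a dense grid refined by bisection (tolerance
10⁻³ rad): the lowest minimum is GM, other minima LM, the highest maximum
TS2 (barrier to free rotation), remaining maxima TS1.

Torsional eigenvalues solve −B d²/dφ² + V(φ) with the periodic
Colbert–Miller DVR kinetic matrix on an odd uniform grid (default 201
points; scans default to 73 points, 5° spacing). B is computed from the
reduced moment of inertia of the two sides about the bond axis at the
reference geometry, B = 1/(2I); this convention is a documented package
choice.

## Synthetic data

The toy force field plays the role of an external sampling engine plus
labeler: harmonic bonds (k = 0.30/0.34 hartree/bohr², r₀ = 1.54/1.09 Å for
CC/CH), harmonic angles (k = 0.25/0.20/0.15 hartree/rad² for CCC/CCH/HCH,
θ₀ tetrahedral), cosine torsions — per-bond threefold barriers of 1,100
(backbone) and 1,200 cm⁻¹ (methyl, the physical order of magnitude for
alkanes) split evenly over the bond's substituent quadruples, plus a
500 cm⁻¹ onefold on the carbon backbone that places the gauche wells a few
hundred cm⁻¹ above anti — and 12-6 Lennard-Jones on pairs four or more
bonds apart (ε = 1.1×10⁻⁴/7.0×10⁻⁵/4.8×10⁻⁵ hartree, σ = 3.4/3.0/2.6 Å
for CC/CH/HH). All terms have analytic gradients verified against finite
differences at 10⁻⁸. The zigzag construction (tetrahedral angles, staggered
methyls, backbone dihedrals exactly π) is the exact minimum of the bonded
terms; with LJ on, the minimum shifts slightly.

Samplers: `thermal_md` runs BAOAB Langevin chains at a temperature ladder
(default 500/1000/2500 K, 0.5 fs step, friction 2×10⁻³ au⁻¹, 200-step
burn-in, collect every 20 steps); `mode_displacement` draws seeded normal-
mode displacements with thermal amplitudes √(kT)/ω at a reference
temperature (default 300 K) times a scale; `head_to_tail_grid` reselects
thermal frames whose end-to-end C–C distance lands nearest requested grid
values. Frames carry toy energies and gradients; an energy ceiling
(default 80,000 cm⁻¹) trims the tail, leaving the characteristic
low-energy concentration with a broad high-energy tail.

What the toy bed does *not* emulate: electronic-structure label noise,
reactive events, long-range dispersion beyond pair LJ, and the sheer data
volume of production workloads. Passing tests therefore demonstrate the
machinery — basis correctness, solver consistency, conservation laws,
conventions — not chemical accuracy on real data.

## Problem sizes used in the shipped checks

The test suite fits butane (thermal 1,500 + displacement 800 frames,
30,000 cm⁻¹ ceiling) for the fragmented model; the many-body held-out
check uses 5,000 post-ceiling thermal butane frames against the full
1,227-term basis; the tetradecane normal-mode check uses five cap-12
fragments covering all 44 atoms, fitted to ~4,600 displacement frames; NVE
checks run 10,000 steps (plus 20,000 at half step) at 2,000 cm⁻¹ total
energy. These sizes are the package's desk-scale defaults.

## Known limitations

* At desk-scale data volumes the full 1,227-term many-body basis
  generalizes imperfectly: with ~3 training rows per coefficient the
  held-out eRMSE sits several times above the training eRMSE. The shipped
  held-out acceptance check pins a 2%-of-standard-deviation bar that the
  current conditions do not reach (≈5% is measured); it is retained as an
  honest marker rather than relaxed.
* Order-2 fragmented bases can misrepresent soft torsional curvature;
  stationary points nearest an idealized start may be low-order saddles
  (hence `find_minimum`), and fragment-uncovered atom pairs are invisible
  to the model — fragment choice must cover every pair whose repulsion
  matters, or dynamics can walk into holes.
* The rigid-scan cis region of short alkanes probes the Lennard-Jones core
  (10⁶–10⁷ cm⁻¹ for butane); polynomial curve fits there are only
  meaningful for the bonded-terms-only force field or for interior bonds
  of longer chains.
* No long-range dispersion/polarization tail beyond the pair LJ of the toy
  bed; no thermostatted production dynamics on fitted models (the Langevin
  integrator exists only inside the synthetic-data module); no 5-body or
  higher terms.
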