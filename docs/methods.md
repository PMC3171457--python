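# Methods

This note records the model conventions, numerical choices and study
conditions behind `flexcon`, and what the bundled synthetic systems do and
do not establish about real molecular calculations.

## Coordinates and frame

Molecules are coordinated incrementally (Z-matrix style): atom `k` is
positioned by a bond length `b_k` to `a(k)`, a bond angle `theta_k`
measured at the vertex `a(k)` against an angle-reference atom, and a
dihedral `phi_k` against a third reference.  Following `a(·)` from any atom
gives its positioning chain `C(k) = [k, a(k), …, 1]`; `a(·)` must form a
tree rooted at atom 1.

The body-fixed ("primed") frame removes overall translation and rotation:
atom 1 at the origin, atom 2 on the positive z semi-axis, atom 3 in the
xz-plane with x > 0.  The frame is configurable (`FrameConvention`) but only
as signed permutations of the axes, so the gauge-zero components are exact
binary zeros rather than rounded ones; every derivative routine reads the
convention from this single place.

Angle convention: `theta_k` is the geometric angle at the vertex `a(k)`
between the two outgoing bond vectors, strictly inside (0, π).  Dihedral
convention: the standard IUPAC signed torsion
`atan2((n1×n2)·b̂2, n1·n2)` with a cis arrangement measuring 0; the
placement basis `(x_loc, y_loc = z_loc × x_loc, z_loc = unit(A−B))` was
derived so that measurement inverts construction identically.  The
build/measure round trip is exact to ~1e−15 over randomized molecules, and
a rigid rotation + translation of the Cartesian coordinates leaves all
measured internals unchanged.

Reference-atom protocol.  Default references follow the chain (angle
reference `a(a(k))`, dihedral reference `a(a(a(k)))`).  Exactly two
deviations are accepted, both SASMIC-style:

* **Root protocol** ("case a"): atoms bonded to atom 2 take atom 3 as angle
  reference and atom 1 as dihedral reference — near the root no chain
  default exists.  Validation additionally requires `a(3) = 2` and treats
  root-protocol atoms as *terminal*.  Both restrictions are load-bearing:
  if atom 3 hung off atom 1, or if another atom were coordinated *from* a
  root-protocol atom, that atom's dihedral would reference the off-axis
  atom 1 and its motion under `theta_3` would no longer be the rigid
  rotation the closed-form derivative assumes.  In chemically sensible
  coordinations, root-protocol atoms are terminal hydrogens, so nothing of
  practical value is excluded.
* **Branch phase dihedrals** ("case b"): when two branches leave the same
  atom, only one may carry the *principal* dihedral on the oriented bond
  `(a(k), a²(k))`; the other branch start is held by a *phase* dihedral
  referencing the principal atom.  The principal/phase kind is declared in
  the topology, never inferred; validation enforces one principal per
  oriented bond.

## Geometric derivatives

Changing one internal coordinate while holding the rest fixed moves a
definite atom set rigidly:

* `b_k`: every atom with `k ∈ C(β)` translates along the unit bond vector.
* `theta_k`: the same chain set — plus, for `theta_3`, the root-protocol
  atoms — rotates about `n = unit((x_B − x_A) × (x_k − x_A))` through
  `x_A`, where `A = a(k)`, `B` is the angle reference.  The axis sign is
  fixed by a self-consistency requirement (a finite rotation of atom `k`
  about `n` must increase the measured angle), not transcribed from a
  figure.
* `phi_k`: the chain set — plus phase-held branches referencing `k` and
  their subtrees — rotates about the bond axis `unit(x_A − x_B)` through
  `x_A`.

The derivative of each mover is the first-order Rodrigues term, a cross
product evaluated at the current geometry; non-movers are structural zeros
that are never stored.  I verified the rigid-motion property analytically
for every accepted reference pattern (the rotating set's internal
coordinates are invariant because each reference atom is either in the
rotating set or on the rotation axis / in the invariant plane) and
numerically against central finite differences of the Cartesian build over
hundreds of randomized topologies; agreement is at the FD-noise level
(≲2e−9 absolute).  In the sparsity check the oracle uses a 1e−5 step: at
1e−6 the oracle's own rounding floor (~|x|·ε/Δ) reaches the 1e−9 scale on
analytically cancelling paths, i.e. the limit is the oracle's, not the
implementation's — the declared zeros are exact.

## Constraint engine

`f(u)` is defined by *local* minimization of `V` over `d` at fixed `u`;
basins are selected by the warm start, and no global search is attempted
(for high-dimensional energy landscapes the local choice is the only
practical one).  The minimizer is a damped Newton iteration on the `d`
block — the analytic Hessian is needed anyway for the linear system, so
Newton costs nothing extra — with Levenberg shifts when `H_dd` is not
positive at an iterate and Armijo backtracking.  Convergence requires the
∞-norm of `∂V/∂d` below 1e−10 (1e−8 for numeric-fallback Hessians), with a
500-iteration cap; all configurable.

At the converged point the order of the stationary point is certified:
`H_dd` must admit a Cholesky factorization (strict positive definiteness);
otherwise a saddle-point error is raised with the smallest eigenvalue.  The
Jacobian solves `H_dd J = −H_du` through the same SPD factorization with L
right-hand sides; a condition estimate above 1e12 emits a warning.  A
numeric-fallback Hessian (central differences of the analytic gradient,
step 1e−5) is available for models without closed-form second derivatives;
it degrades the exactness guarantee to gradient-FD accuracy and is cross
checked against the analytic route in the tests.

The module is deterministic by construction: no random numbers anywhere.

## Finite-difference comparator

The comparator reproduces the displaced re-minimization protocol: displace
`u_i` by Δ (forward) or ±Δ/2 (central), re-minimize `d` warm-started from
the base minimizer, difference the target quantity.  Defaults: forward
scheme (the protocol's plain form), Δ list 1e−3…10 degrees log-spaced-ish,
basin-hop threshold 0.5 (rad or Å) per coordinate.  A hop warning flags
endpoint minimizers that moved beyond the threshold — the mechanism behind
anomalously large FD errors when the identity of a local minimum changes
under displacement.

`truncate_precision` rounds target values to fixed decimals (half-to-even)
before differencing, emulating the printed output precision of production
codes (six decimals for bond lengths, three for angles is typical).  With
truncation on, a stiff coordinate's error-vs-Δ curve is U-shaped: at the
smallest Δ the coordinate's true motion (≈ |c·Δ| for coupling amplitude c)
falls below the last printed digit and the estimate collapses, while at
large Δ the O(Δ) forward truncation error grows.

The normalized error metric averages |FD − exact| over a conformation set
and divides by a per-coordinate normalizer `N_μ`.  The normalizer is the
maximum magnitude of the exact derivative over the set — one transcription
point (`finite_diff.normalizer`) holds this choice, which makes the metric
invariant under uniform rescaling of the observable.

## Study systems

**2D toy.**  `V(x, y) = a·x²/2 + k·(y−y0)²/2 + c·x²y²` with defaults
`k = 100`, `y0 = 1`, `c = 2`, `a = 1`, `x ∈ [−2, 2]`: a stiff harmonic well
in `y` around `y0` whose position is dragged by a weak coupling as the soft
coordinate moves.  The constrained minimizer is closed-form,
`f(x) = k·y0/(k + 2c·x²)`, giving an independent oracle for the whole
pipeline; the demonstration observable is the distance to the origin.  The
scan uses 11 evenly spaced `x` values.

**Synthetic force field.**  Defined directly over internal coordinates so
that value, gradient and Hessian are closed-form: harmonic wells on every
constrained coordinate, cosine rotor series on the unconstrained dihedrals,
optional bilinear cross terms between constrained coordinates (these make
`H_dd` non-diagonal without moving the minimizer), and equilibrium-value
couplings `q0(u) = q00 + c·cos u`.  With couplings as the only
u-dependence, `f(u) = q0(u)` exactly and `J = ∂q0/∂u = −c·sin u` — the
parameter-recovery oracle.  Coupling amplitudes are small (0.006–0.06) so
`H_dd` stays positive definite over full scans (validated by sampling at
construction).  Force constants default to 300 (bonds), 80 (angles), 30
(dihedrals) in energy/Å² or energy/rad²: stiff enough that the truncation
pathology appears exactly where it should (a bond moving ~1e−7 Å per
millidegree is invisible at six printed decimals).  An optional engineered
double-well term on one constrained dihedral, with a tilt driven by one
unconstrained coordinate, produces a genuine basin migration for the
hop-detection tests.

**Molecule fixtures.**  Three bundled topologies emulate a small alcohol
(6 atoms, 1 unconstrained rotor), a capped amide (12 atoms, 3 unconstrained
dihedrals — both methyl rotors and the central amide rotation are scanned),
and a capped tri-peptide (30 atoms, 7 unconstrained backbone/rotor
dihedrals, with the peptide-bond dihedrals constrained).  Together they
exercise both branching special cases.  They are *topological emulations*:
atom counts, reference patterns and split structure mirror those systems,
but geometries are idealized (tetrahedral/trigonal angles, standard bond
lengths) and the energetics are the synthetic force field — no claim is
made of matching any production force field's minimized structures or the
derivatives thereof.  Conformation scans enumerate grids lexicographically
(the one-rotor full-turn scan at 20° steps has 19 points); where a
molecular-sampling procedure would be used for larger systems, a seeded
uniform sampler stands in, and determinism is part of its contract.

What passing tests show — and what they do not.  The synthetic systems
certify the *machinery*: exactness of the linear-system route on models
whose `f` is known in closed form, agreement of the kinematic derivatives
with numerical differentiation of the coordinate build, and the qualitative
failure modes of the FD protocol.  They do not reproduce any published
force-field numbers; real potentials have nonbonded Cartesian terms whose
internal-coordinate Hessians are far denser than the synthetic ones, and
error magnitudes there depend on the Hessian's accuracy and conditioning.

## An 8-atom branched example

The chain/special-case tests use this topology (atom: bond, angle, dihedral
references; kind):

| atom | a(k) | angle ref | dihedral ref | kind |
|-----:|-----:|----------:|-------------:|:-----|
| 2 | 1 | – | – | – |
| 3 | 2 | 1 | – | – |
| 4 | 3 | 2 | 1 | principal |
| 5 | 3 | 2 | 4 | phase |
| 6 | 2 | 3 | 1 | phase (root protocol) |
| 7 | 5 | 3 | 2 | principal |
| 8 | 4 | 3 | 2 | principal |

Chains: `C(7) = [7, 5, 3, 2, 1]`, `C(8) = [8, 4, 3, 2, 1]`.  Atom 5 (and
its subtree, atom 7) co-rotates with `phi_4`; atom 6 co-rotates with
`theta_3`.

## Problem sizes and determinism

Default verification sizes: 100 randomized molecules with N ≤ 10 for the
geometric-derivative sweep, 100 random quadratic models, 11 toy-grid
points, 19 methanol-scan points, 25 seeded starting conformations for the
tri-peptide minimization battery.  These sizes give FD-oracle noise floors
well below the asserted tolerances while keeping the whole suite in
seconds.  All stochastic inputs flow from explicit seeds; reports embed the
seed and a hash of the run configuration so every number is recomputable.

## Known limitations

* Ring-closure and redundant internal-coordinate sets are out of scope;
  topologies must be declared trees with the reference patterns above.
* Degenerate geometries (collinear reference triplets, coincident atoms)
  raise errors rather than returning limits; the collinearity tolerance is
  1e−10 on the relevant cross-product norm.
* Second geometric derivatives `∂²x′/∂q∂q` and derivatives with respect to
  the external (rigid-body) coordinates are not implemented; nothing in the
  constrained-derivative chain requires them.
* The basin-hop detector is a displacement heuristic: it cannot distinguish
  a genuine basin change from a legitimately large smooth response, and a
  hop that returns the coordinate near its original value would evade it.
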