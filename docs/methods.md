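# Methods

This note records the models implemented in `tcrforge`, their assumptions,
the defaults that matter, and the design choices made where the design was
genuinely open. It states no empirical number that the test suite or
`scripts/acceptance.py` does not itself compute.

## Energy model

The effective energy of a solute is the molecular-mechanics interaction
energy plus an implicit-solvent solvation free energy:

* **Coulomb**: `k_C Σ q_i q_j / (ε_in r_ij)` with
  `k_C = 332.0637 kcal·Å/(mol·e²)`; interior dielectric `ε_in = 1` by
  default.
* **Lennard-Jones**: `ε_ij[(r_min,ij/r)¹² − 2(r_min,ij/r)⁶]` with
  `r_min,ij = r_i + r_j` and `ε_ij = √(ε_i ε_j)`.
* **GB electrostatic solvation**:
  `−½ k_C (1/ε_in − 1/ε_out) Σ_ij q_i q_j / f_GB(r, a_i, a_j)` over all
  ordered pairs including `i = j`, with the standard smooth interpolation
  `f_GB = √(r² + a_i a_j e^(−r²/4a_i a_j))`. Effective radii `a_i` come
  from Hawkins–Cramer–Truhlar pairwise descreening of the per-atom
  intrinsic Born radii (neighbour radii scaled by 0.8; no self term, no
  contribution from a neighbour buried inside the atom's own radius; the
  inverse radius is floored at 1e-3 Å⁻¹). An isolated ion reduces exactly
  to the Born formula, which is the unit test anchor. `ε_out = 78.5`.
* **Nonpolar solvation**: `γ·SASA + b` with `γ = 0.00542 kcal/mol/Å²`,
  `b = 0.92 kcal/mol`, probe 1.4 Å. SASA is a deterministic Shrake–Rupley
  quadrature (960 golden-spiral points per atom by default). The additive
  constant `b` enters absolute single-state values only: in binding
  *differences* the offset is treated as a state-independent reference and
  cancels, so `Δ(np) = γ·ΔSASA`. A per-state constant would leave a
  spurious −b in every thermodynamic cycle (a complex at infinite
  separation would appear to "bind" by −b) and would break the locality of
  the per-residue decomposition.

All terms are arithmetic means over the structure's frames; a single frame
is a valid one-frame ensemble. Binding energies use the single-trajectory
convention — isolated-partner terms evaluated on the same frames after
deleting the other partner — so the gas-phase deltas reduce exactly to the
inter-partner pair sums and the conformational term is zero by
construction. Entropy is never computed; an externally supplied −TΔS can be
attached through the `entropy_term` hook. No Poisson–Boltzmann solver is
provided: GB is the model, not an approximation of one implemented here.

**Numerical notes.** Atom pairs closer than 1e-6 Å raise an error in the
pair sums. The SASA point grid is aligned to the principal axes of the
atom subset, with axis signs fixed by the third moment of the coordinate
distribution (falling back to a largest-component rule for symmetric
clouds); this makes the numerical SASA — and everything built on it —
exactly covariant under rigid transforms of the input, which the test suite
asserts at 1e-6 kcal/mol on whole binding energies.

## Structure handling

PDB I/O goes through Biopython. Residue identity is the author-assigned
(chain, residue number, insertion code); nothing is renumbered. Altloc
conflicts resolve to the highest occupancy, ties to 'A'. Waters are
dropped; multi-MODEL files become frames over one shared topology and any
topology mismatch between models is an error.

The bundled parameter set is a self-consistent united-atom style table
written for this toolkit: heavy atoms plus explicit polar hydrogens, with
per-residue charges summing exactly to the formal charge (ASP/GLU −1,
LYS/ARG +1, HIS neutral in the Nε-H tautomer). It is intentionally simple —
any table in the same TSV format can be swapped in, and the toolkit's
invariants (charge sums, conservation, closed forms) hold for any
consistent table. Missing polar hydrogens are constructed at
parameterization time by ideal geometry (amide H on the backbone bisector;
side-chain H from the residue's internal-coordinate template); nonpolar
hydrogens present in the input are dropped with a warning. Structures are
re-emitted in template atom order, which makes parameterization idempotent.

Mutants: alanine truncation keeps backbone + Cβ untouched in every frame
and retypes the residue. General point mutations keep the backbone and the
shared side-chain prefix at wild-type coordinates and grow the remaining
atoms from ideal internal coordinates, choosing among ≤ 9 canonical
rotamers (gauche−/trans/gauche+ over the first two torsions, trans beyond)
the one with the least steric overlap; if every rotamer has an atom closer
than 0.6 × the vdW-radius sum to the environment, the builder fails with
the clash list. This is a deterministic minimal scheme, not a reconstruction
of any published mutant-building protocol, and no re-simulation is
performed: wild type and mutant share frames, so conformational relaxation
upon mutation is deliberately outside the model (the known accuracy
limitation of single-structure ΔΔG estimates).

## Decomposition, scanning, and design scoring

BFED assigns each inter-partner pair energy half to each pair member's
residue; GB self terms and per-atom SASA changes go to the owning residue.
Conservation — contributions summing to the binding total within 1e-6
kcal/mol — is asserted on every fixture and frame count.

CAS reports `ΔΔG_CAS = ΔG_bind(Ala mutant) − ΔG_bind(wild type)`; positive
means the residue favours binding. GLY (no Cβ), PRO (ring spans the
backbone) and ALA targets are skipped with a warning. When CAS and BFED are
compared, BFED totals are negated first so both series are on the
"favours binding is positive" convention; `compare_cas_bfed` itself
correlates exactly what it is given.

The design score for one replacement sums per-residue contribution changes
over the mutated residue and all residues (either partner, either
structure) with a heavy atom within 4.5 Å of it. The cutoff default is a
toolkit choice, config-exposed, and audited by the identity that an
infinite cutoff equals the full sum over all residues. Negative
`ΔΔG_bind` = improved binding, stated in every output header. Measured
affinities convert as `fold = K_D^wt/K_D^mut`,
`ΔΔG_exp = RT ln(fold)` with `R = 1.9872e-3 kcal/(mol·K)`, 298 K default.

## Orientation scan

The receptor's axis is the principal gyration axis of its scored atoms
most aligned with the receptor→ligand centre-of-mass direction, oriented
toward the ligand (an explicit axis can be supplied; a near-spherical
receptor is an error). The receptor is translated 6–12 Å away along this
axis and rotated full circle in 5° steps about the axis through its
translated centroid; the ligand stays fixed. Angle 0° is the input pose.
Polar-only mode (Coulomb + GB) is the default energy; grid points with an
inter-partner heavy-atom pair closer than 0.5 × the vdW-radius sum are
flagged and excluded from the minimum search. Ties resolve to the smallest
angle, then distance; the reported margin is the gap to the lowest distinct
local basin.

Sub-group profiles are the Coulomb + GB cross energy between a
region-tagged receptor group and the whole ligand, so groups covering the
receptor sum to the total inter-partner polar profile. A group's *share*
of the orientation signal is the variance of its profile divided by the
variance of the total profile; because groups can be anticorrelated, a
dominant group's share can exceed 1 — it is a signal-attribution ratio,
not a partition of unity.

On the locked fixtures the continuous landscape minimum sits within a few
degrees of the construction angle; the small systematic offset comes from
the pose-dependent desolvation (GB self) term, which is not part of the
cross-interaction lock. This is the desk-scale analog of the angular shifts
a rigid scan shows on real structures, and it stays within one 5° grid step
on the bundled fixtures.

## Free-energy estimators

**TI.** Input is ⟨∂U/∂λ⟩ on a strictly increasing grid inside (0, 1); the
conventional 11-point grid 0.02, 0.1, …, 0.9, 0.98 is bundled as a preset.
The interior is integrated by the trapezoidal rule. The two end segments —
where the integrand may be singular — are integrated under a fitted form:
linear (2 nearest points), quadratic (3 points), or `a + b·λ^(−3/4)`
(resp. `a + b·(1−λ)^(−3/4)`; 2 points). The fitted form spans through the
second grid point when the grid has ≥ 4 points, so the near-singular first
segment is not trapezoid-approximated; all three schemes are then exact
for constant integrands, the polynomial schemes for linear ones, and the
pow34 scheme recovers ∫₀¹λ^(−3/4)dλ = 4 within 2% on the 11-point grid —
the behaviour the two-parameter endpoint form was chosen for (a
one-parameter `c·λ^(−3/4)` fit cannot be exact for constants). The error
estimate combines propagated per-λ standard errors with the cross-scheme
spread in quadrature. TI values are kcal/mol.

**Jarzynski.** Work is kJ/mol, β = 1/(R T) in mol/kJ, T = 300 K default;
the explicit unit split between the TI (kcal) and work (kJ) paths follows
the conventions of the two literatures and prevents silent mixing. The
direct estimator is −β⁻¹ ln⟨e^(−βW)⟩ via log-sum-exp (finite for |βW| up
to ~1e4); the cumulant estimator is W̄ − (β/2)s² with the unbiased (n−1)
variance. By Jensen's inequality the direct estimate never exceeds W̄,
asserted property-style.

**PMF from work profiles.** Under the stiff-spring approximation the work
of each trajectory is attributed at the guide position, and the chosen
estimator is applied column-wise over the shared ξ grid, anchored at
G(ξ₀) = 0. The full reweighting of time-dependent guiding potentials
(histogram-based unbiasing) is an extension point, not silently
approximated: this module assumes stiff guides.

**Toy simulator.** Overdamped Langevin dynamics on
`U(x) + ½k_g(x − (x₀+vt))²` with Euler–Maruyama steps (rejected as
unstable when `k_g·dt/friction ≥ 0.5`), equilibrated in the static guide
before pulling, vectorised over trajectories and bit-reproducible per
seed. Work accumulates as the explicit time-dependence of the guide,
`dW = −k_g(x − guide)·v·dt`, so a lagging particle yields positive work.
The exact free energy of the guided system,
`G(g) = −β⁻¹ ln ∫ e^(−β(U+½k_g(x−g)²)) dx`, is computed by quadrature and
serves as the independent ground truth in all simulator tests.

**Bias phenomenology.** The qualitative finding that finite-sample direct
averaging over-estimates ΔG while the cumulant expansion under-estimates
it requires a strongly dissipative ensemble whose work distribution has a
*short lower tail* (bounded below, positively skewed). The bundled
demonstration draws 150 work values — the trajectory count a realistic
steered campaign affords — from a shifted-gamma distribution
(shift 5, shape 36, scale 8 kJ/mol) whose Jarzynski average is available in
closed form: `ΔG = shift + (shape/β)·ln(1 + β·scale)`. The parameters were
chosen so the dominant region of the exponential average lies far below
the reachable sample minimum at n = 150: mean work exceeds the true ΔG by
>100 kJ/mol and the Gaussian surrogate's variance term overshoots the true
lower tail. The 1-D Langevin toy is kept for the dissipation and
quasi-static properties it does exhibit; its barrier-crossing work
distributions have a long lower tail (early thermal hops dissipate less),
which is the opposite regime, so it is not used for the bias
demonstration.

## Interface maps

H-bonds are geometric: donor–acceptor distance ≤ 3.5 Å and donor–H⋯acceptor
angle ≥ 120°, with donor/acceptor roles taken from the residue templates;
both thresholds are config-exposed because no standard exists. Nonpolar
contacts are carbon/sulfur heavy-atom pairs across the partner split within
4.5 Å. Occurrence maps take a per-frame ξ label from metadata (never
recomputed), bin frames by ξ, and report for each partner atom the fraction
of frames in which the interaction exists; empty bins are dropped with a
warning, and loosening a criterion can only add detections (monotonicity is
asserted).

## Synthetic fixtures

The toy complex is a geometric caricature, not a physical protein: a
12-residue "MHC rim" ring (radius 10 Å) plus a 3-residue central "peptide"
with side chains pointing up; a receptor with matching CDR-tagged ring
residues pointing down, two central CDR3 residues, and an 8-residue-per-
chain framework column that elongates the receptor along the approach axis
(as a real TCR is elongated toward its ligand). Engineered interactions —
by default two salt bridges (Lys/Glu at 0°, Arg/Asp at 270°), an amide
H-bond pair at 180° and a nonpolar patch at 90°, all on CDR1/2-tagged
residues — provide the electrostatic lock. Construction is made exact in
two steps: the receptor is rotated so its computed principal axis coincides
with the approach axis, and each engineered residue is swung azimuthally so
its functional tip (e.g. the lysine NZ, the carboxylate midpoint) sits at
its interaction angle. A requested native angle is then realised by rigidly
rotating the receptor about the approach axis — the same transform the scan
applies — so the landscape minimum is at the construction angle by design.
Placement jitter (0.05 Å, seed-dependent) varies fixtures across seeds;
frames beyond the first add independent coordinate jitter of the same
amplitude. Infeasible placements (any inter-residue atom pair < 1.6 Å)
retry with larger jitter up to 10 times.

What the fixtures do *not* emulate: real backbone connectivity (residues
are disconnected perches), side-chain flexibility, realistic packing
density, solvent structure, or conformational change on binding. Passing
tests therefore demonstrate the correctness and internal consistency of the
algorithms — conservation, locality, orientation recovery, estimator
behaviour — not predictive accuracy on real TCR–pMHC complexes, which
additionally depends on force-field quality and conformational sampling
outside this package's scope.

Work ensembles (Gaussian and shifted-gamma) and λ series (constant, linear,
λ^(−3/4), polynomial) carry their analytic truths in JSON sidecars.
Everything is bit-reproducible per seed.

## Problem sizes

The bundled verification runs use desk-scale sizes chosen as sufficient for
their statistical claims: 20-seed fixture batches for conservation (smaller
8-residue-rim complexes; conservation is size-independent) and orientation
recovery; 3 pooled fixtures (~87 residue pairs) for the CAS/BFED
correlation, with the SASA quadrature at 240 points per atom where only
conservation/correlation (not absolute areas) is at stake; 10⁵ draws for
the Gaussian Jarzynski check; 150 trajectories for the bias demonstration.

## Known limitations

* No entropy, no PB solver, no explicit solvent, no kinetics.
* Single-structure ΔΔG ignores relaxation upon mutation; outliers with
  large conformational rearrangement are expected.
* The rotamer builder is minimal (≤ 9 rotamers, hard-sphere screening).
* GB flavour is one pairwise-descreening variant; the flavour is a config
  surface so alternatives can be added.
* The united-atom parameter table is a consistent stand-in, not a
  published force field; absolute energies are not comparable across
  tables.
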