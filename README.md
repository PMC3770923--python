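# tcrforge

Structure-based energetics and free-energy estimators for engineering
T-cell receptor (TCR) affinity for peptide–MHC (pMHC) targets.

TCRs recognise peptides presented by MHC molecules through six
complementarity-determining region (CDR) loops. Adoptive T-cell therapies
benefit from receptors whose affinity has been nudged — not maximised — by a
small number of rational point mutations, because specificity must survive
the redesign. `tcrforge` implements the computational machinery such a
design campaign rests on:

* **MM-GBSA binding energies.** The binding free energy (entropy excluded)
  is assembled as
  `ΔG_bind = ΔH_elec + ΔG_vdW + ΔG_elec,solv + ΔG_np,solv`,
  with Generalized Born electrostatic solvation (Hawkins–Cramer–Truhlar
  pairwise descreening radii) and a SASA-proportional nonpolar term
  `ΔG_np,solv = γ·SASA + b` (Shrake–Rupley quadrature). The
  single-trajectory convention is used: isolated-partner terms are
  evaluated on the complex's frames after deleting the other partner, so
  `ΔH_intra = 0` by construction.
* **Per-residue decomposition (BFED) and alanine scanning (CAS).** BFED
  splits each inter-partner pair term half/half between the two residues
  (self and surface terms go to the owner) and conserves the total exactly;
  CAS truncates one side chain at a time to alanine and recomputes
  `ΔG_bind`. Their agreement is the toolkit's internal consistency check.
* **Rational design by local ΔΔG summation.** For a candidate mutation,
  `ΔΔG_bind = Σ_res (ΔG_bind^res,mut − ΔG_bind^res)` summed over the
  mutated residue and every residue in heavy-atom contact with it —
  suppressing noise from remote residues. Negative ΔΔG_bind = improved
  binding. Measured K_D tables convert to fold changes and
  `ΔΔG_exp = RT·ln(K_D^wt/K_D^mut)` for comparison.
* **Docking-orientation prediction.** A rigid scan translates the TCR
  6–12 Å along its principal axis and rotates it through 360° in 5° steps;
  the polar part of the effective energy (Coulomb + GB) alone identifies
  the native orientation as the landscape minimum, and a region-tagged
  decomposition attributes the orientation signal to CDR1/2-vs-MHC
  contacts.
* **Free-energy estimators.** Thermodynamic integration (trapezoid over a
  λ grid with linear / quadratic / λ^(−3/4) endpoint extrapolation) and the
  Jarzynski identity `exp(−βΔG) = ⟨exp(−βW)⟩` with both direct exponential
  averaging and the second-order cumulant expansion `ΔG = W̄ − (β/2)σ²`,
  plus PMF reconstruction from steered-work profiles and a 1-D overdamped
  toy simulator that generates such profiles.
* **Interface maps.** Geometric H-bond and nonpolar-contact detection over
  multi-frame ensembles, aggregated into occurrence maps binned by a
  separation coordinate ξ.

Everything is testable offline: a fixtures module generates toy TCR–pMHC
complexes with an engineered electrostatic lock at a known native angle,
plus synthetic work ensembles and λ series with analytic ground truth.

## Worked example

```python
import tcrforge as tf

# a toy complex: chains D/E = TCR alpha/beta, A/C = peptide/MHC
s, truth = tf.make_toy_complex(seed=7)

e = tf.binding_energy(s)
print({k: round(v, 2) for k, v in e.as_dict().items()})
# {'elec': -178.77, 'vdw': -1.67, 'gb': 179.74, 'np': -0.57,
#  'intra': 0.0, 'entropy': 0.0, 'total': -1.27}

records, skipped = tf.alanine_scan(s)
best = max(records, key=lambda t: t[1])
print(best[0].label, round(best[1], 2))
# D:LYS26 2.58
```

The breakdown shows the classic implicit-solvent picture: a large
favourable Coulomb term (engineered salt bridges) almost cancelled by the
GB desolvation penalty, leaving a modest net binding energy. The alanine
scan identifies the lysine of the engineered salt bridge as the top
hotspot — truncating it costs ~2.6 kcal/mol of binding.

```python
from tcrforge.orientation import rigid_scan, find_minimum
d, angle, energy, margin = find_minimum(rigid_scan(s, energy_mode="polar"))
print(angle)   # 0.0  — the native orientation of the bound input pose
```

A command-line interface mirrors the library
(`tcrforge energy|bfed|alascan|ddg|affinity|orient|ti|jarzynski|steer-sim|hbond-map|fixtures`).

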