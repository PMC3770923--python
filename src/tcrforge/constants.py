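"""Physical constants and toolkit-wide defaults.

Energies are kcal/mol on the structural side (MM-GBSA, TI) and kJ/mol on the
steered-work side, matching the conventional units of each literature.
"""

# Coulomb constant in kcal*Angstrom/(mol*e^2)
COULOMB_KCAL = 332.0637

# Gas constant
R_KCAL = 1.9872e-3   # kcal/(mol*K)
R_KJ = 8.3145e-3     # kJ/(mol*K)

# Dielectric defaults (conventional MM-GBSA values; config-exposed everywhere)
EPS_IN_DEFAULT = 1.0
EPS_OUT_DEFAULT = 78.5

# Nonpolar solvation: dG_np = gamma * SASA + b (absolute, single state).
# In binding differences the constant offset cancels by convention; see docs.
GAMMA_DEFAULT = 0.00542   # kcal/mol/A^2
B_DEFAULT = 0.92          # kcal/mol
PROBE_RADIUS_DEFAULT = 1.4  # A

# Heavy-atom contact cutoff for the local ddG summation (A)
CONTACT_CUTOFF_DEFAULT = 4.5

# Hard-sphere clash threshold for rotamer placement: fraction of vdW radius sum
CLASH_FRACTION = 0.6

# Steric flag threshold for rigid-scan grid points
SCAN_CLASH_FRACTION = 0.5

# H-bond geometric criteria (toolkit defaults; config-exposed)
HBOND_DA_CUTOFF = 3.5     # donor-acceptor distance, A
HBOND_ANGLE_CUTOFF = 120.0  # donor-H...acceptor angle, degrees

# Nonpolar contact cutoff (carbon/sulfur heavy atoms), A
NP_CONTACT_CUTOFF = 4.5

# The 11-point lambda grid commonly used for TI on this system
LAMBDA_GRID_11 = (0.02, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 0.98)
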