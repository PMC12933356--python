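"""Physical constants and unit conversions (CODATA 2018, thermochemical kcal).

Internal unit system:

* free energies  kcal/mol
* concentrations mol/L
* time           s (kinetics) / fs (molecular dynamics)
* length         Angstrom
* mass           amu
"""

#: Gas constant, kcal mol^-1 K^-1 (k_B * N_A / 4184 J/kcal).
R_KCAL = 1.987204e-3

#: k_B / h, s^-1 K^-1 — prefactor of the Eyring equation is KB_OVER_H * T.
KB_OVER_H = 2.083661e10

#: Boltzmann constant, kcal mol^-1 K^-1 (identical to R_KCAL per mole).
KB_KCAL = R_KCAL

# --- molecular-dynamics unit glue -----------------------------------------
# 1 kcal/mol/Angstrom of force on 1 amu gives this acceleration in A/fs^2.
_J_PER_KCAL = 4184.0
_NA = 6.02214076e23
_AMU_KG = 1.66053906892e-27
#: acceleration (A/fs^2) per (kcal/mol/A)/amu
# F per molecule = 4184/(NA*1e-10) N per kcal/mol/A; a = F/(m*amu_kg) m/s^2;
# 1 m/s^2 = 1e-20 A/fs^2, net factor 4.1840e-4.
KCAL_PER_MOL_A_TO_A_FS2 = _J_PER_KCAL / _NA / _AMU_KG * 1e-10

#: kinetic energy in kcal/mol of 1 amu moving at 1 A/fs (0.5*m*v^2 / this)
A_FS_SQ_AMU_TO_KCAL = 1.0 / KCAL_PER_MOL_A_TO_A_FS2

#: default water concentration held fixed in the formose runs, mol/L
WATER_CONC = 55.3

#: thermochemistry temperature of the packaged free energies, K (55 C)
T_THERMO = 328.15

#: simulation temperature of the packaged kinetics runs, K (65 C)
T_SIM = 338.15
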