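"""Physical constants and unit conversions.

Engine-style unit system throughout the package: lengths in nm, time in ps,
temperature in K, energies in kJ/mol, charges in elementary charges (e),
pressures in bar.  Dipoles are carried in e*nm and reported in debye.
"""

#: Molar gas constant, J mol^-1 K^-1.
R_J = 8.31446

#: Molar gas constant, kJ mol^-1 K^-1.
R_KJ = R_J * 1e-3

#: Coulomb constant 1/(4 pi eps0), kJ mol^-1 nm e^-2.
KE = 138.935458

#: Debye per e*nm (1 e*nm = 48.032047 D).
DEBYE_PER_E_NM = 48.032047

#: e*nm per debye.
E_NM_PER_DEBYE = 1.0 / DEBYE_PER_E_NM

#: Avogadro constant, mol^-1.
N_A = 6.02214076e23

#: Boltzmann constant, J K^-1.
K_B = 1.380649e-23

#: bar * nm^3 expressed in kJ/mol (per-system pV work to molar energy).
BAR_NM3_TO_KJ_MOL = 1e5 * 1e-27 * N_A * 1e-3  # = 0.0602214076

#: Molar masses, g/mol.
M_H2O2 = 34.0147
M_H2O = 18.0153
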