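"""Physical constants in the internal unit system.

Internal units follow the GROMACS convention: length nm, time ps, mass u,
energy kJ/mol, charge e, temperature K.  With these choices velocity is
nm/ps and kJ/mol/u = (nm/ps)^2, so no hidden conversion factors appear in
the equations of motion.
"""

#: Boltzmann constant, kJ mol^-1 K^-1
KB = 0.00831446261815324

#: Coulomb prefactor 1/(4 pi eps0), kJ mol^-1 nm e^-2
F_COULOMB = 138.935458

#: Avogadro constant, mol^-1
N_AVOGADRO = 6.02214076e23

#: 1 e*nm in Debye
ENM_TO_DEBYE = 48.032047

#: pressure conversion: 1 kJ mol^-1 nm^-3 in bar
PRESSURE_TO_BAR = 16.6054

#: 1 u/nm^3 in g/cm^3
U_PER_NM3_TO_G_CM3 = 1.66053906660e-3

#: atomic masses, u
MASS_O = 15.9994
MASS_H = 1.008

#: molar mass of water, g/mol (= u per molecule)
M_WATER = MASS_O + 2.0 * MASS_H

#: diffusion conversion: 1 nm^2/ps in units of 1e-5 cm^2/s
DIFFUSION_TO_1E5_CM2_S = 1.0e3
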