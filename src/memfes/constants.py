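"""Physical constants and lookup tables shared across the package.

Units follow the conventions used throughout: lengths in nm (Å at the CV
interfaces, where noted), energies in kJ/mol, angles in degrees at public
interfaces, charges in elementary charges.
"""

from __future__ import annotations

#: Boltzmann constant, kJ/mol/K.
KB = 0.0083144621

#: Default simulation temperature, K (late-endosomal physiological temperature).
T_DEFAULT = 310.0

#: kT at 310 K, kJ/mol.
KT_310 = KB * T_DEFAULT  # 2.577...

#: Coulomb constant 1/(4 pi eps0), kJ mol^-1 nm e^-2.
COULOMB = 138.935458

#: Vacuum permittivity in e^2 mol kJ^-1 nm^-1 (i.e. 1/(4 pi COULOMB)).
EPS0 = 1.0 / (4.0 * 3.141592653589793 * COULOMB)

#: kJ/mol per (volt * e); divide a potential in kJ/mol/e by this to get volts.
FARADAY_KJ_PER_MOL_V = 96.48533212

#: Average residue (amino acid minus water) masses in Da, one-letter codes.
RESIDUE_MASS_DA = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

#: Membrane species recognised by the toy builders and the contact analysis.
LIPID_SPECIES = ("BMP", "CHOL", "SM", "DOPG", "POPC")

#: Nominal per-species bead charge (e) for the toy membranes: anionic lipids
#: carry -1, everything else is neutral.
SPECIES_CHARGE = {
    "BMP": -1.0, "CHOL": 0.0, "SM": 0.0, "DOPG": -1.0, "POPC": 0.0,
    "PROT": 0.0, "WAT": 0.0, "ION": 1.0,
}

#: Nominal bead vdW radii, nm.
SPECIES_RADIUS = {
    "BMP": 0.25, "CHOL": 0.22, "SM": 0.25, "DOPG": 0.25, "POPC": 0.25,
    "PROT": 0.19, "WAT": 0.14, "ION": 0.12,
}

#: Water-sized and insertion-loop-sized SASA probe radii, nm.
PROBE_WATER_NM = 0.14
PROBE_MIL_NM = 0.58

#: The membrane insertion loop sequence V59..P65 (one-letter).
MIL_SEQUENCE = "VMGIPVP"
MIL_RESIDUES = tuple(range(59, 66))
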