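"""Unit conversion factors and physical constants.

Cube-file geometry is natively in bohr; everything downstream of the
surface module works in angstroms.  Electrostatic potentials are stored
in hartree per unit charge in cube files and converted to kJ/mol when
sampled on a surface.
"""

BOHR_TO_ANGSTROM = 0.529177210903
ANGSTROM_TO_BOHR = 1.0 / BOHR_TO_ANGSTROM

#: hartree -> kJ/mol
HARTREE_TO_KJ_PER_MOL = 2625.4996

#: gas constant in kJ mol^-1 K^-1
GAS_CONSTANT = 8.3145e-3
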