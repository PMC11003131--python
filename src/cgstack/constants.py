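"""Physical constants and unit conventions.

Internal units follow the GROMACS convention: lengths in nm, times in ps,
masses in amu, energies in kJ/mol, temperatures in Kelvin.  In these units
1 amu nm^2 ps^-2 = 1 kJ/mol exactly, so no conversion factors appear in the
dynamics.  Angles are degrees at module interfaces and radians inside
numerical code.
"""

#: Boltzmann constant in kJ mol^-1 K^-1 (fixed; not configurable).
KB: float = 0.0083144621

#: Default simulation/analysis temperature (310.15 K = 37 C).
DEFAULT_TEMPERATURE: float = 310.15

#: Default nonbonded cutoff in nm.
DEFAULT_CUTOFF: float = 1.1

#: Angstrom -> nm.
ANGSTROM_TO_NM: float = 0.1
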