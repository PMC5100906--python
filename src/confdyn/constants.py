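"""Physical constants and unit conventions.

Internal units throughout the package: nanometres, kilojoules per mole,
picoseconds and kelvin.  PDB files store ångström; conversion happens at the
I/O boundary only.
"""

#: Boltzmann constant, kJ mol^-1 K^-1.
KB = 0.0083144621

#: Default simulation temperature, K.
DEFAULT_TEMPERATURE = 300.0

#: nm per Å.
NM_PER_ANGSTROM = 0.1
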