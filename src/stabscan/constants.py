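"""Physical constants.

All energies in this package are molar (kcal/mol), so the Boltzmann constant
and the gas constant are the same number and temperatures multiply R directly.
"""

#: molar gas constant, kcal/(mol·K)
R_GAS: float = 1.9872e-3

#: Boltzmann constant on the molar energy scale — identical to R_GAS
KB_MOLAR: float = R_GAS
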