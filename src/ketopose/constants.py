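"""Physical constants and shared defaults.

All energies are kcal/mol, distances Å, temperatures K unless a function
says otherwise (docking scores are consumed in kJ/mol, as scored).
"""

#: Gas constant in kcal mol^-1 K^-1.
R_KCAL: float = 1.98720425864e-3

#: Simulation/assay temperature (K) used as the default throughout.
DEFAULT_TEMPERATURE: float = 303.0

#: Atomic masses (amu) for the atoms this package does mass-weighting over.
ATOMIC_MASSES: dict[str, float] = {
    "H": 1.008,
    "C": 12.011,
    "N": 14.007,
    "O": 15.999,
    "P": 30.974,
    "S": 32.06,
}
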