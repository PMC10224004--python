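"""Physical constants and default substance registry.

Densities are pure-solvent literature values at 298 K and are held
temperature-independent; both are overridable per ``SolventSpec``.
Energies are computed in J/mol throughout and converted to kJ/mol only
for reporting.
"""

# Universal gas constant, J mol^-1 K^-1
R_GAS = 8.314

#: Standard reporting temperatures, K (25 C and body temperature)
T_STANDARD = 298.2
T_BODY = 310.2

#: name -> (molar mass g/mol, density g/cm^3 at 298 K)
SOLVENTS = {
    "1-octanol": (130.23, 0.8262),
    "n-hexane": (86.18, 0.6548),
}

#: name -> molar mass g/mol
SOLUTES = {
    "IPN": 179.22,   # iproniazid
    "INZ": 137.14,   # isoniazid
    "iNAM": 122.12,  # isonicotinamide
}
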