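# Default substance registry (overridable via --config)
solvents:
  1-octanol:
    molar_mass: 130.23   # g/mol
    density: 0.8262      # g/cm^3, pure solvent at 298 K
  n-hexane:
    molar_mass: 86.18
    density: 0.6548
solutes:
  IPN: 179.22    # iproniazid
  INZ: 137.14    # isoniazid
  iNAM: 122.12   # isonicotinamide
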