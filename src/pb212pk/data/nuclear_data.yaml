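# Pinned nuclear-data constants for the 212Pb decay series.
# Half-lives and branching fractions are standard evaluated nuclear data,
# recorded here so every computation in the package is reproducible from
# one versioned table.
nuclides:
  - name: pb212
    half_life_value: 10.64
    half_life_unit: h
    branches:
      - daughter: bi212
        fraction: 1.0
  - name: bi212
    half_life_value: 60.55
    half_life_unit: min
    branches:
      - daughter: po212   # beta branch
        fraction: 0.6406
      - daughter: tl208   # alpha branch
        fraction: 0.3594
  - name: po212
    half_life_value: 0.299
    half_life_unit: us
    branches:
      - daughter: pb208
        fraction: 1.0
  - name: tl208
    half_life_value: 3.053
    half_life_unit: min
    branches:
      - daughter: pb208
        fraction: 1.0
  - name: pb208
    stable: true

# Photon emission yield of the 212Pb 238.6 keV gamma line (photons per
# decay), used to convert gamma-counter net counts to activity.
gamma_yield_238kev: 0.436
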