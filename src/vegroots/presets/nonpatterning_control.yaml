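# Non-pattern-forming control: root augmentation too weak to produce
# patterns (E1 = 2); remaining rates adjusted so the shrub still invades.
base: default
P:      {value: 1400.0, unit: mm/y}
E1:     {value: 2.0,    unit: m^2/kg}
K1:     {value: 1.75,   unit: kg/m^2}
M1:     {value: 9.05,   unit: 1/y}
M2:     {value: 9.05,   unit: 1/y}
Lam1:   {value: 0.08,   unit: (1/mm)/y}
Lam2:   {value: 0.08,   unit: (1/mm)/y}
Gam1:   {value: 5.0,    unit: (m^2/kg)/y}
SG1:    {value: 0.01,   unit: m}
SD1:    {value: 0.1,    unit: m}
Wstar2: {value: 0.5,    unit: kg/m^2}
DW:     {value: 1.0,    unit: m^2/y}
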