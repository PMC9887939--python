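# Standard parameter set (low-altitude phenotype); P is scenario-dependent
# and defaults to 1000 mm/y here.
P:      {value: 1000.0, unit: mm/y}
E1:     {value: 16.0,   unit: m^2/kg}
E2:     {value: 5.0,    unit: m^2/kg}
K1:     {value: 0.7,    unit: kg/m^2}
K2:     {value: 0.35,   unit: kg/m^2}
M1:     {value: 7.05,   unit: 1/y}
M2:     {value: 7.05,   unit: 1/y}
N:      {value: 15.0,   unit: 1/y}
Lam1:   {value: 0.06,   unit: (1/mm)/y}
Lam2:   {value: 0.16,   unit: (1/mm)/y}
Gam1:   {value: 15.0,   unit: (m^2/kg)/y}
Gam2:   {value: 5.0,    unit: (m^2/kg)/y}
R1:     {value: 0.1,    unit: "-"}
R2:     {value: 0.1,    unit: "-"}
Th1:    {value: 3.125,  unit: 1/y}
Th2:    {value: 3.125,  unit: 1/y}
DW:     {value: 0.5,    unit: m^2/y}
SG1:    {value: 0.5,    unit: m}
SD1:    {value: 0.5,    unit: m}
SD2:    {value: 0.01,   unit: m}
Wstar1: {value: 0.5,    unit: kg/m^2}
Wstar2: {value: 2.0,    unit: kg/m^2}
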