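# High-altitude phenotype: short lateral roots, narrow sucker kernel,
# higher rainfall (1500-1750 mm/y range; 1600 is the working value).
base: default
P:   {value: 1600.0, unit: mm/y}
E1:  {value: 5.0,    unit: m^2/kg}
SD1: {value: 0.01,   unit: m}
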