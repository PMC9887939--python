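# Low-altitude phenotype: long lateral roots (large E1), wide sucker kernel.
# Identical to the default set; kept as a named preset for clarity.
base: default
P:   {value: 1000.0, unit: mm/y}
E1:  {value: 16.0,   unit: m^2/kg}
SD1: {value: 0.5,    unit: m}
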