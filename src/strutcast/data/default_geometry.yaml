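# Barrel + taper + capillary stand-in for a pneumatic syringe feeding a
# 450 um inner-diameter nozzle. Dimensions in millimetres.
segments:
- {kind: cylinder, r_in_mm: 4.0, r_out_mm: 4.0, length_mm: 60.0}
- {kind: cone, r_in_mm: 4.0, r_out_mm: 0.225, length_mm: 15.0}
- {kind: cylinder, r_in_mm: 0.225, r_out_mm: 0.225, length_mm: 5.0}
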