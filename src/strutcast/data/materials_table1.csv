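name,density_ref_kg_m3,T_ref_density_C,cte_per_C,eta_ref_Pa_s,T_ref_visc_C,surface_tension_N_m,contact_angle_deg
PCL,1145,25,165e-6,2211.35,120,0.040,75
DMSO2,1450,25,88e-6,0.00114,120,0.060,40
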