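label,liver_volume_factor,hematocrit,protein_binding_factor,gfr_ml_min,hepatic_intrinsic_clearance_factor,hepatic_flow_factor
CP-A,0.69,0.41,0.92,100,0.60,1.0
CP-B,0.55,0.37,0.86,70,0.45,1.0
CP-C,0.28,0.33,0.78,45,0.30,1.0
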