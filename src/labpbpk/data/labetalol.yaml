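# Labetalol model input parameters.
# Physicochemistry from PubChem-style reference values; clearance and
# permeability are the model inputs used by the simulation engine.
# "specific_organ_permeability" and "specific_clearance" are optimizer
# outputs of the original software and are carried as metadata only.
name: labetalol
molecular_weight: 328.412     # g/mol
pka: 9.38                     # monoprotic base convention
logp: 2.79
fraction_unbound: 0.45
intestinal_permeability: 4.67e-5   # cm/min
specific_organ_permeability: 0.1   # L/min (metadata, unused by engine)
total_body_clearance: 15.0         # mL/min/kg
specific_clearance: 6.0            # L/h (metadata, unused by engine)
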