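organ,f_water,f_neutral_lipid,f_phospholipid
plasma,0.9600,0.0023,0.0013
adipose,0.1800,0.7900,0.0020
bone,0.4400,0.0740,0.0011
brain,0.7700,0.0510,0.0565
gut,0.7200,0.0490,0.0163
heart,0.7600,0.0115,0.0166
kidney,0.7900,0.0207,0.0162
liver,0.7500,0.0348,0.0252
lung,0.8100,0.0030,0.0090
muscle,0.7600,0.0238,0.0072
skin,0.7200,0.0284,0.0111
rest,0.7500,0.0200,0.0100
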