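organ,volume_l_per_70kg,flow_l_per_h_per_70kg
arterial_blood,1.80,
venous_blood,3.60,
lung,0.55,
liver,1.80,25.5
gut,1.10,58.5
kidney,0.31,74.1
muscle,29.00,66.3
adipose,13.00,19.5
skin,3.30,19.5
brain,1.45,46.8
heart,0.33,15.6
bone,10.00,19.5
rest,3.76,44.7
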