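study_id,population,route,n_subjects,dose_amount,dose_basis,n_female,age_min,age_max,weight_min_kg,weight_max_kg,weight_reported
1,healthy,oral,6,200,absolute_mg,2,20,24,,,false
2,healthy,oral,5,200,absolute_mg,0,21,26,,,false
3,healthy,iv_infusion,6,0.5,mg_per_kg,2,20,24,,,false
4,healthy,iv_infusion,5,0.5,mg_per_kg,0,21,26,,,false
5,healthy,iv_infusion,6,0.5,mg_per_kg,0,21,26,,,false
6,CP-A,iv_infusion,10,0.5,mg_per_kg,2,22,24,50,65,true
7,CP-A,oral,10,200,absolute_mg,2,22,42,50,65,true
8,CKD-severe,iv_infusion,4,1,mg_per_kg,1,37,70,75,87,true
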