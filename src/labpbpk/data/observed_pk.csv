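study_id,route,population,parameter,observed,predicted,ratio_printed,unit
3,iv_infusion,healthy,cmax,144.244,91.9,1.56,ng/mL
3,iv_infusion,healthy,auc_0_t,297.002,270.74,1.09,ng*h/mL
3,iv_infusion,healthy,cl,1.2,1,1.2,L/h
4,iv_infusion,healthy,cmax,143.099,120.083,1.19,ng/mL
4,iv_infusion,healthy,auc_0_t,299.91,288.59,1.039,ng*h/mL
4,iv_infusion,healthy,cl,0.99,1.1,0.9,L/h
5,iv_infusion,healthy,cmax,143.09,89.178,1.60,ng/mL
5,iv_infusion,healthy,auc_0_t,419.66,279.972,1.498,ng*h/mL
5,iv_infusion,healthy,cl,0.7,1.1,0.63,L/h
1,oral,healthy,cmax,150.228,131.91,1.13,ng/mL
1,oral,healthy,auc_0_t,384.602,477.93,0.80,ng*h/mL
1,oral,healthy,cl,320,270,1.18,L/h
2,oral,healthy,cmax,166.82,131.91,1.26,ng/mL
2,oral,healthy,auc_0_t,432.0,482.57,0.89,ng*h/mL
2,oral,healthy,cl,244,260,0.93,L/h
6,iv_infusion,CP-A,cmax,143.18,144.1995,0.99,ng/mL
6,iv_infusion,CP-A,auc_0_t,265.30,283.060,0.93,ng*h/mL
6,iv_infusion,CP-A,cl,1.4,1.2,1.16,L/h
7,oral,CP-A,cmax,295.567,112.14,2.635,ng/mL
7,oral,CP-A,auc_0_t,608.733,382.41,1.5,ng*h/mL
7,oral,CP-A,cl,250.6,376,0.6,L/h
8,iv_infusion,CKD-severe,cmax,535.697,588.037,0.9109,ng/mL
8,iv_infusion,CKD-severe,auc_0_t,590.26,758.806,0.77,ng*h/mL
8,iv_infusion,CKD-severe,cl,1.4,0.98,1.5,L/h
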