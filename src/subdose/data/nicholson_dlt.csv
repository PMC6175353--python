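dose,subgroup,dlt_weight,no_dlt_weight,is_pseudo
100,0,0,5,False
150,0,0,4,False
180,0,0,4,False
215,0,0,6,False
245,0,2,5,False
260,0,1,0,False
100,1,1,5,False
150,1,0,4,False
180,1,0,8,False
215,1,2,2,False
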