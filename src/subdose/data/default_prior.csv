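scope,dose,dlt_proportion,patient_weight
negative,100,0.16666666666666666,2
negative,260,0.5,1
positive,100,0.16666666666666666,2
positive,260,0.5,1
pooled,100,0.16666666666666666,4
pooled,260,0.5,2
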