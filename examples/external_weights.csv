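module,sex,age_group,cause_id,weight
adult,male,15-49,cirrhosis,0.054
adult,male,15-49,stroke,0.446
adult,male,15-49,road_traffic,0.500
adult,*,*,cirrhosis,0.040
adult,*,*,stroke,0.460
adult,*,*,road_traffic,0.500
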