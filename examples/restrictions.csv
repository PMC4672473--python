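cause_id,field,op,value
cervical_cancer,sex,eq,male
breast_cancer,sex,eq,male
maternal,sex,eq,male
prostate_cancer,sex,eq,female
malaria,site,eq,non_endemic
maternal,age,gt,55
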