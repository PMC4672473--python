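text_item,cause_id
word_road,stomach_cancer
word_road,lung_cancer
word_road,colorectal_cancer
word_hospit,*
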