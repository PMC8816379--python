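# miRNA definitions: name, mature sequence 5'->3'
name	mature_seq
hsa-let-7a-5p	UGAGGUAGUAGGUUGUAUAGUU
hsa-miR-125b-5p	UCCCUGAGACCCUAACUUGUGA
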