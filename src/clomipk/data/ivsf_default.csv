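reaction_id,activity_score,ivsf
*,0.0,0.0
*,0.5,0.2
*,0.75,0.3
*,1.0,0.4
*,2.0,1.0
*,3.0,1.8
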