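family	gene
checkpoint_stimulatory	CD40
checkpoint_stimulatory	CD80
checkpoint_stimulatory	TNFSF9
checkpoint_inhibitory	IDO1
checkpoint_inhibitory	VCAM1
interleukin	IL15RA
interleukin	IL6
chemokine	CCL5
chemokine	CXCL10
transcription_factor	RELB
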