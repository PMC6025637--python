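id	clade	hu_per_mg	source
rHct-S3	Clade I	33000	this_family
rHct-A3	Clade I	20000	this_family
rHct-A5	Clade II	1000	this_family
rHct-A2	Clade I	40000	prior_report
rHct-S5	Clade II	1000	prior_report
rHct-S6	Clade II	4200	prior_report
RTX-S		50000	prior_report
RTX-A		35000	prior_report
RTX-G		10000	prior_report
RTX-SII		36000	prior_report
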