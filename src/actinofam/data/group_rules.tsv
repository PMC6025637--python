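label	parent	priority	positions
IA		1	24:T;131:K;138:N;170:K
IB		2	28:Q;82:D;139:S
IC		3	78:N;82:E;96:D
ID		4	10:DE;21:K;78:D
IE		5	18:V;44:T;69:T;112:W
ID1	ID	1	82:E;96:D
ID3	ID	2	17:Q
ID4	ID	3	112:F
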