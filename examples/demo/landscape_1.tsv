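0	0	0	0	0	0	0	0	2	2	0	0
0	0	0	0	0	0	0	0	2	2	0	0
0	0	0	0	0	0	0	0	2	2	2	0
0	0	0	0	0	0	0	0	2	2	2	2
2	2	2	0	0	0	0	2	2	2	2	2
2	2	2	2	0	0	0	2	2	2	2	2
2	2	2	2	2	2	0	0	2	2	2	2
2	2	2	2	2	2	2	0	2	2	2	2
2	2	2	2	0	0	0	0	2	2	2	2
2	2	0	0	0	0	0	0	2	2	2	2
2	0	0	0	0	0	0	0	2	2	2	2
0	0	0	0	0	0	0	0	2	2	2	2
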