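hybridoma	mouse_id	clone_label	isotype	v_call	j_call	mutations_total	mutations_nonsilent	cdr3_aa_imgt	n_arg_kabat_printed
4B10.1	mouse1	#1	IgG2c	V5-17	J4	4	3	ARRKLRNYYAMDY	2
6B9.1	mouse1	#1	IgG2c	V5-17	J4	3	2	ARRKLRNYYAMDY	2
7F4.1	mouse1	#2	IgG2b	V1-82	J2	1	1	ARPGRRGRYYFDY	3
3C5.2	mouse1	#2	IgG2c	V1-82	J2	2	0	ARPGRRGRYYFDY	3
3F5.1	mouse1	#3	IgG2c	V1-7	J3	4	2	ARSYYGSKGWFTY	0
3E2.1	mouse1	#4	IgG2c	V1-26	J2	6	2	ASGDSSGPFDY	0
1E7.1	mouse1	#5	IgG2c	V2-2	J4	1	0	ARNRLRRGLDY	3
2B11.1	mouse1	#6	IgG2c	V1-81	J2	9	6	AGEHAGPYYFDY	0
10A12.1	mouse1	#7	IgG2c	V5-9-1	J3	5	3	TRGGDSSGYRFAY	1
1E5	mouse2	#1	IgG2c	V5-17	J4	1	1	ARRGLRGVMDY	2
8F4	mouse2	#1	IgG2c	V5-17	J4	7	5	VRRGLRGAMDY	2
8H4	mouse2	#1	IgG2c	V5-17	J4	4	1	VRRGLRGAMDY	2
1G2.1	mouse2	#1	IgG2c	V5-17	J4	4	3	ARRGLRGAMNY	2
2C1.2	mouse2	#1	IgG2c	V5-17	J4	4	2	VRRGLRGAMDY	2
4H2.1	mouse2	#1	IgG2c	V5-17	J4	2	0	ARRGLRGAMDY	2
5G3	mouse2	#2	IgG2b	V5-17	J4	6	4	AKQLRLRYYAMDY	2
6E5	mouse2	#2	IgG2b	V5-17	J4	4	3	SKQLRLRYYAMDY	2
9A10	mouse2	#2	IgG2b	V5-17	J4	6	5	AKQLRLRYYAMDY	2
3C5	mouse2	#3	IgG2b	V9-4	J4	1	1	ARDGNSYEGFAY	0
5G12	mouse3	#1	IgG2c	V1-81	J3	7	6	AEDGYAWFTY	0
5F11	mouse3	#1	IgG2c	V1-81	J3	4	4	AEDGYVWFAY	0
4C2	mouse3	#1	IgG2c	V1-81	J3	13	10	AEDGYVWFAY	0
3B7	mouse3	#2	IgG2c	V1-9	J3	9	4	ARERNYITGFAY	1
1F10	mouse3	#2	IgG2c	V1-9	J3	9	7	ARERNYITGFAY	1
1D12	mouse3	#2	IgG2c	V1-9	J3	2	1	ARERNYITGFAY	1
2A2	mouse3	#3	IgG2c	V7-3	J2	1	1	ARFPAGTRRYYFDY	2
5B4	mouse3	#3	IgG2c	V7-3	J2	4	2	ARFPAGTRRYYFDY	2
3A9	mouse3	#3	IgG2c	V7-3	J2	3	2	ARFPAGTRRYYFDY	2
1G1	mouse3	#4	IgG2c	V5-17	J3	7	6	ARNYYVNRRGFAY	2
1G5	mouse3	#5	IgG2c	V5-17	J3	8	6	TSRQLRLRRVAY	4
3F12	mouse3	#6	IgG3	V1-26	J3	3	2	TRKGWDDAY	0
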