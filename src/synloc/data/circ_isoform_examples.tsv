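gene	donor	acceptor	log2fc	p
ATF6	9	2	-2.81	0.00740
ATF6	15	10	1.94	0.00860
ATF6	14	10	-1.25	0.0363
ANKS1B	4	2	1.21	0.000585
ANKS1B	8	2	-1.01	0.0170
GSK3B	9	7	1.58	0.00370
GSK3B	10	9	-1.68	0.00666
UBA2	16	9	-1.84	0.00755
UBA2	16	10	1.49	0.0473
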