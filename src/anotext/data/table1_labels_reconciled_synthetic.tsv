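# SYNTHETIC reconciliation of table1_labels.tsv to the published
# stratified error percentages (43 scored pathological + 52 control
# records). Constructed, not observed: one pathological row is dropped
# and three labels flipped so the error-count marginals per group and
# expert label match the published error table; the choice of edited
# rows is not identifiable from the source. See docs/methods.md.
doc_id	group	expert	rnn	dict
p01	pathological	1	-1	1
p02	pathological	1	-1	-1
p03	pathological	1	-1	-1
p04	pathological	-1	1	-1
p05	pathological	-1	-1	-1
p06	pathological	-1	-1	-1
p07	pathological	1	1	-1
p08	pathological	-1	-1	-1
p09	pathological	1	1	-1
p10	pathological	1	1	1
p11	pathological	-1	1	-1
p12	pathological	-1	-1	-1
p14	pathological	-1	1	-1
p15	pathological	1	1	1
p16	pathological	1	1	1
p17	pathological	1	-1	-1
p18	pathological	-1	-1	-1
p19	pathological	-1	1	-1
p20	pathological	-1	1	-1
p21	pathological	1	1	1
p22	pathological	1	1	-1
p23	pathological	1	1	-1
p24	pathological	-1	-1	-1
p25	pathological	-1	-1	1
p26	pathological	1	1	1
p27	pathological	-1	1	-1
p28	pathological	-1	-1	-1
p29	pathological	-1	-1	1
p30	pathological	1	1	-1
p31	pathological	1	1	1
p32	pathological	1	-1	-1
p33	pathological	-1	-1	-1
p34	pathological	-1	1	-1
p35	pathological	-1	1	-1
p36	pathological	1	1	1
p37	pathological	-1	-1	-1
p38	pathological	1	1	1
p39	pathological	-1	-1	-1
p40	pathological	-1	-1	1
p41	pathological	1	1	1
p42	pathological	-1	1	-1
p43	pathological	-1	-1	-1
p44	pathological	-1	1	1
c01	control	0	-1	1
c02	control	1	1	1
c03	control	1	1	1
c04	control	-1	1	-1
c05	control	1	1	-1
c06	control	0	1	0
c07	control	1	-1	-1
c08	control	0	-1	-1
c09	control	0	1	1
c10	control	1	1	1
c11	control	0	-1	-1
c12	control	1	1	1
c13	control	-1	-1	1
c14	control	1	1	-1
c15	control	1	1	1
c16	control	-1	-1	0
c17	control	0	1	0
c18	control	1	1	1
c19	control	1	1	1
c20	control	1	1	-1
c21	control	1	1	1
c22	control	1	1	1
c23	control	1	1	-1
c24	control	-1	1	1
c25	control	1	1	1
c26	control	1	1	0
c27	control	1	1	1
c28	control	1	1	1
c29	control	1	1	0
c30	control	1	1	0
c31	control	1	1	0
c32	control	-1	1	0
c33	control	1	1	1
c34	control	1	1	-1
c35	control	1	1	1
c36	control	1	-1	1
c37	control	-1	-1	-1
c38	control	-1	1	1
c39	control	-1	-1	1
c40	control	1	1	1
c41	control	1	1	1
c42	control	1	1	-1
c43	control	1	1	0
c44	control	1	1	0
c45	control	0	-1	-1
c46	control	1	-1	1
c47	control	1	1	1
c48	control	1	1	1
c49	control	-1	-1	1
c50	control	1	1	1
c51	control	-1	-1	1
c52	control	1	1	1
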