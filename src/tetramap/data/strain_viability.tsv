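# Published sporulation and spore-viability counts for the SUMO-diminished
# chromosome III cross panel (tetrad dissections; row labels are strain names).
# sporulation_pct is the printed percentage, cells_counted its denominator;
# n4..n0 are tetrad counts by number of viable spores; viability_pct is the
# printed overall spore viability recomputed by tetramap.viability.
strain	sporulation_pct	cells_counted	n4	n3	n2	n1	n0	viability_pct
SMT3/SMT3 (PM89, K189)	54	3360	268	28	9	1	1	96
SMT3/smt3 (LFT36, K197)	54	3002	1	4	280	25	3	48
P_SCC1[SMT3]/smt3 (LFT46, K196, K223)	13	6103	6	1	435	74	21	45
pch2/pch2 SMT3/SMT3 (K167)	54	2071	212	54	14	4	1	91
pch2/pch2 SMT3/smt3 (K325)	58	2034	0	6	320	69	15	44
pch2/pch2 P_SCC1[SMT3]/smt3 (LFT85, K198)	60	5012	2	1	296	72	17	43
P_SCC1[SMT3]/P_SCC1[SMT3] (K188)	44	2003	192	35	24	3	1	91
pch2/pch2 P_SCC1[SMT3]/P_SCC1[SMT3] (K191)	62	2031	225	64	14	4	3	91
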