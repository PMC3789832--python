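# Published random-spore map distances for three chromosome III intervals
# (2-spore-viable tetrads only; row labels are strain names).
# pct_recombinant is the printed 100*r/t percentage, t the total colonies
# assessed, se the printed standard error; r is reconstructed downstream as
# round(pct_recombinant * t / 100).
strain	interval	t	pct_recombinant	se
SMT3/SMT3 (K189)	HIS4-CEN3	756	27	1.6
SMT3/SMT3 (K189)	CEN3-MAT	756	19	1.4
SMT3/SMT3 (K189)	MAT-RAD18	756	32	1.7
SMT3/smt3 (K197)	HIS4-CEN3	480	26	2.0
SMT3/smt3 (K197)	CEN3-MAT	480	20	1.8
SMT3/smt3 (K197)	MAT-RAD18	480	30	2.0
P_SCC1[SMT3]/smt3 (K196)	HIS4-CEN3	432	34	2.2
P_SCC1[SMT3]/smt3 (K196)	CEN3-MAT	432	35	2.3
P_SCC1[SMT3]/smt3 (K196)	MAT-RAD18	432	40	2.3
P_SCC1[SMT3]/smt3 (K223)	HIS4-CEN3	218	39	3.3
P_SCC1[SMT3]/smt3 (K223)	CEN3-MAT	218	36	3.3
P_SCC1[SMT3]/smt3 (K223)	MAT-RAD18	218	36	3.3
P_SCC1[SMT3]/P_SCC1[SMT3] (K188)	HIS4-CEN3	921	35	1.6
P_SCC1[SMT3]/P_SCC1[SMT3] (K188)	CEN3-MAT	921	38	1.6
P_SCC1[SMT3]/P_SCC1[SMT3] (K188)	MAT-RAD18	921	35	1.6
pch2/pch2 SMT3/SMT3 (K167)	HIS4-CEN3	1015	27	1.4
pch2/pch2 SMT3/SMT3 (K167)	CEN3-MAT	1015	27	1.4
pch2/pch2 SMT3/SMT3 (K167)	MAT-RAD18	1015	40	1.5
pch2/pch2 SMT3/smt3 (K325)	HIS4-CEN3	467	25	2.0
pch2/pch2 SMT3/smt3 (K325)	CEN3-MAT	467	23	1.9
pch2/pch2 SMT3/smt3 (K325)	MAT-RAD18	467	41	2.3
pch2/pch2 P_SCC1[SMT3]/smt3 (K198)	HIS4-CEN3	416	31	2.3
pch2/pch2 P_SCC1[SMT3]/smt3 (K198)	CEN3-MAT	416	34	2.3
pch2/pch2 P_SCC1[SMT3]/smt3 (K198)	MAT-RAD18	416	35	2.3
pch2/pch2 P_SCC1[SMT3]/P_SCC1[SMT3] (K191)	HIS4-CEN3	1113	27	1.3
pch2/pch2 P_SCC1[SMT3]/P_SCC1[SMT3] (K191)	CEN3-MAT	1113	29	1.4
pch2/pch2 P_SCC1[SMT3]/P_SCC1[SMT3] (K191)	MAT-RAD18	1113	42	1.5
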