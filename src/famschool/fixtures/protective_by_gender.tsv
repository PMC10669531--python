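stratum	lhs	support_pct	confidence_pct	lift
male	high peer support	23.09	88.67	1.19
male	high family cohesion	21.61	87.99	1.18
male	low family conflict;no family economic strain	25.00	87.01	1.17
male	low family conflict;no family structure risk;no family economic strain	20.75	86.91	1.17
male	low family conflict;no family structure risk	26.91	86.35	1.16
male	low family conflict;non-left-behind children	22.14	86.15	1.16
male	low family conflict	32.73	85.88	1.16
male	high teacher support;no family structure risk	22.74	85.34	1.15
male	high autonomy support;no family structure risk	20.23	85.04	1.14
male	high teacher support	28.30	84.24	1.13
male	high teacher support;no family economic strain	20.31	83.27	1.12
male	high autonomy support	25.35	82.95	1.12
female	high family cohesion;no family structure risk	20.43	87.13	1.32
female	high family cohesion;no family economic strain	20.82	86.50	1.31
female	high family cohesion	23.99	86.35	1.31
female	high peer support;no family structure risk	20.74	84.54	1.28
female	high peer support;no family economic strain	21.67	83.83	1.27
female	high peer support	25.62	82.96	1.26
female	low family conflict;no family structure risk	23.07	82.09	1.24
female	low family conflict	28.48	80.35	1.22
female	high teacher support	23.07	80.32	1.22
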