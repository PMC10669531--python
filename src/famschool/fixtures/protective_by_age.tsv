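stratum	lhs	support_pct	confidence_pct	lift
primary	high family cohesion	20.81	88.32	1.22
primary	high teacher support;no family structure risk	21.15	88.17	1.22
primary	high peer support	24.51	86.63	1.20
primary	low family conflict;no family structure risk	26.31	85.24	1.18
primary	low family conflict;no family structure risk;no family economic strain	20.03	84.73	1.17
primary	high teacher support	27.09	84.22	1.17
primary	low family conflict	33.19	83.55	1.16
primary	low family conflict;not left-behind children	21.58	83.11	1.15
primary	low family conflict;no family economic strain	25.37	83.10	1.15
primary	high autonomy support	22.36	82.02	1.14
middle	high family cohesion;no family structure risk	21.55	86.79	1.28
middle	high family cohesion	24.75	86.14	1.27
middle	high peer support;no family structure risk	20.69	86.04	1.27
middle	high family cohesion;no family economic strain	20.37	85.29	1.26
middle	high peer support	24.36	84.32	1.24
middle	high peer support;no family economic strain	20.45	83.97	1.24
middle	not left-behind children;low family conflicts	20.37	83.39	1.23
middle	low family conflict;no family economic strain	23.03	83.33	1.23
middle	low family conflict;no family structure risk	23.58	83.20	1.23
middle	low family conflict	28.02	82.53	1.22
middle	high autonomy support;no family structure risk	21.86	80.69	1.19
middle	high teacher support	24.12	80.47	1.19
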