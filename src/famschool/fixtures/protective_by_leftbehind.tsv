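stratum	lhs	support_pct	confidence_pct	lift
non_left_behind	high family cohesion	26.49	89.29	1.25
non_left_behind	high family cohesion;no family structure risk	23.82	89.29	1.25
non_left_behind	high family cohesion;no family economic strain;no family structure risk	20.27	88.37	1.23
non_left_behind	high family cohesion;no family economic strain	22.49	88.28	1.23
non_left_behind	high peer support;no family structure risk	23.70	87.35	1.22
non_left_behind	high peer support;no family economic strain	22.62	86.20	1.20
non_left_behind	high peer support	26.94	86.00	1.20
non_left_behind	high teacher support;no family structure risk	23.57	84.13	1.17
non_left_behind	high teacher support;no family economic strain	20.97	83.76	1.17
non_left_behind	low family conflict;no family economic strain;no family structure risk	23.25	83.56	1.17
non_left_behind	low family conflict;no family structure risk	28.34	83.52	1.17
non_left_behind	high teacher support	26.37	83.50	1.17
non_left_behind	low family conflict	32.53	83.25	1.16
non_left_behind	low family conflict;no family economic strain	26.49	83.23	1.16
non_left_behind	high autonomy support;no family economic strain	20.46	83.20	1.16
non_left_behind	high autonomy support;no family structure risk	22.17	83.10	1.16
non_left_behind	high autonomy support	25.35	81.43	1.14
left_behind	low family conflict	26.78	82.62	1.24
left_behind	high teacher support	24.02	80.08	1.20
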