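stratum	lhs	support_pct	confidence_pct	lift
non_left_behind	high family conflict;low family cohesion	5.59	82.24	2.90
left_behind	high family conflict;low family cohesion;low peer support	5.63	90.74	2.72
left_behind	low family cohesion;high family conflict;absence of counselors in the school;absence of counseling rooms in the school	6.32	87.30	2.62
left_behind	low family cohesion;high family conflict;absence of counseling rooms in the school	6.44	86.15	2.58
left_behind	low family cohesion;high family conflict;female	5.63	85.96	2.58
left_behind	low family cohesion;high family conflict;middle school students	6.21	85.71	2.57
left_behind	low family cohesion;high family conflict;absence of counselors in the school	7.47	85.53	2.57
left_behind	low family cohesion;high family conflict;absence of psychology courses;absence of counselors in the school	5.17	84.91	2.55
left_behind	low family cohesion;low peer support;female	5.63	84.48	2.53
left_behind	low family cohesion;high family conflict;absence of psychology courses;absence of counselors in the school	5.63	84.48	2.53
left_behind	low family cohesion;high family conflict	9.31	84.38	2.53
left_behind	low family cohesion;low teacher support;low peer support	5.98	83.87	2.52
left_behind	low family cohesion;low teacher support;low peer support;absence of counselors in the school	5.06	83.02	2.49
left_behind	high family conflict;low peer support	6.90	82.19	2.47
left_behind	low family cohesion;low teacher support;absence of psychology courses;absence of counselors in the school	5.29	82.14	2.46
left_behind	low family cohesion;low teacher support;absence of psychology courses	5.75	81.97	2.46
left_behind	low family cohesion;low peer support;middle school students	5.17	81.82	2.45
left_behind	low family cohesion;low teacher support;low autonomy support	5.63	81.67	2.45
left_behind	high family conflict;low peer support;absence of counselors in the school	5.75	80.65	2.42
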