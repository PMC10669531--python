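stratum	lhs	support_pct	confidence_pct	lift
primary	low family cohesion;low peer support	7.39	70.49	2.54
middle	high family conflict;low family cohesion;low peer support	5.23	90.54	2.81
middle	high family conflict;low family cohesion;female	6.17	86.81	2.69
middle	high family conflict;low family cohesion;low parental education level	5.31	86.08	2.67
middle	high family conflict;low family cohesion;absence of counselors in the school	5.62	85.71	2.66
middle	high family conflict;low family cohesion;absence of counseling rooms in the school	5.39	85.19	2.64
middle	high family conflict;low peer support	6.48	84.69	2.63
middle	high family conflict;low family cohesion	9.06	84.67	2.63
middle	low peer support;low family cohesion	7.88	80.80	2.51
middle	low peer support;low family cohesion;absence of counselors in the school	5.15	80.49	2.50
middle	low family cohesion;absence of counseling rooms in the school;female	5.85	79.79	2.47
middle	low family cohesion;absence of counselors in the school;female	6.17	78.22	2.43
middle	low family cohesion;female;absence of counseling rooms in the school;absence of counselors in the school	5.31	78.16	2.42
middle	low family cohesion;female	9.99	78.05	2.42
middle	low family cohesion;low teacher support	5.70	77.66	2.41
middle	high family conflict;female;absence of counselors in the school	5.85	75.76	2.35
middle	low family cohesion;family economic strain	5.62	75.00	2.33
middle	low peer support;female	8.51	74.66	2.32
middle	high family conflict;female;absence of counseling rooms in the school	5.46	74.47	2.31
middle	low family cohesion;female;Low parental education level	5.78	74.00	2.30
middle	low family cohesion;low autonomy support	6.01	72.64	2.25
middle	low family cohesion;absence of counselors in the school	9.76	71.84	2.23
middle	low peer support;female;low parental education level	5.15	71.74	2.23
middle	high family conflict;absence of counselors in the school	7.88	71.63	2.22
middle	low family cohesion;absence of counseling rooms in the school	9.45	71.60	2.22
middle	high family conflict;separation from parents	5.70	71.57	2.22
middle	high family conflict;absence of counselors in the school;absence of counseling rooms in the school	6.79	71.31	2.21
middle	low family cohesion;absence of counseling rooms in the school;absence of psychological counselors	8.51	71.24	2.21
middle	low family cohesion;absence of psychology courses	8.27	70.67	2.19
middle	low family cohesion;absence of counselors in the school;absence of psychology courses	7.03	70.31	2.18
middle	high family conflict;absence of counseling rooms in the school	7.73	70.21	2.18
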