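stratum	lhs	support_pct	confidence_pct	lift
male	low family cohesion;high family conflict	5.56	78.05	3.04
male	low family cohesion;low teacher support	5.30	70.93	2.76
female	low family cohesion;high family conflict;absence of counselors in the school	5.03	89.04	2.61
female	high family conflict;low peer support	6.27	88.04	2.59
female	low family cohesion;high family conflict;middle school students	6.11	86.81	2.55
female	low family cohesion;high family conflict	8.13	86.78	2.55
female	low family cohesion;low peer support	7.97	85.12	2.50
female	low family cohesion;low peer support;absence of counselors in the school	5.26	85.00	2.50
female	low family cohesion;middle school students;absence of counseling rooms in the school	5.80	79.79	2.34
female	low peer support;low teacher support	5.57	78.26	2.30
female	low family cohesion;middle school students;absence of counselors in the school	6.11	78.22	2.30
female	low family cohesion;middle school students;absence of counselors in the school;absence of counseling rooms in the school	5.26	78.16	2.30
female	low family cohesion;middle school students	9.91	78.05	2.29
female	low family cohesion;low teacher support	5.65	76.04	2.23
female	high family conflict;middle school students;absence of counselors in the school	5.80	75.76	2.22
female	high family conflict;separation from parents	5.26	74.73	2.19
female	low peer support;middle school students	8.44	74.66	2.19
female	high family conflict;middle school students;absence of counseling rooms in the school	5.42	74.47	2.19
female	low family cohesion;middle school students;low parental education level	5.73	74.00	2.17
female	high family conflict;absence of counselors in the school	7.89	73.38	2.15
female	high family conflict;absence of counselors in the school;absence of counseling rooms in the school	6.81	73.33	2.15
female	high family conflict;absence of counseling rooms in the school	7.43	72.73	2.14
female	low peer support;absence of counselors in the school	9.29	72.29	2.12
female	low peer support;low parental education level;absence of counselors in the school	5.03	72.22	2.12
female	low peer support;average academic ranking	6.81	72.13	2.12
female	low peer support;middle school students;low parental education level	5.11	71.74	2.11
female	low peer support;separation from parents	5.65	70.87	2.08
female	high family conflict;average academic ranking	5.57	70.59	2.07
female	low peer support;family economic strain	5.19	70.53	2.07
female	high family conflict;absence of counselors in the school;absence of psychological courses	5.11	70.21	2.06
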