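sample_id	analyte	mean	sd	n	group
QJ-RZ	volatile_oil	10.44	0.75	3	Sub-high
QJ-RZ	galangin	12.95	0.19	3	Sub-high
HA-RZ	volatile_oil	2.98	0.53	3	Low
HA-RZ	galangin	5.13	0.47	3	Low
HN-RZ	volatile_oil	3.36	0.18	3	Low
HN-RZ	galangin	5.56	1.09	3	Low
GZ-RZ	volatile_oil	9.96	0.94	3	Sub-high
GZ-RZ	galangin	11.66	0.76	3	Sub-high
GY-RZ	volatile_oil	7.68	0.24	3	Intermediate
GY-RZ	galangin	9.62	0.65	3	Intermediate
GX-RZ	volatile_oil	7.28	0.50	3	Intermediate
GX-RZ	galangin	9.76	0.46	3	Intermediate
KM-RZ	volatile_oil	7.92	0.15	3	Intermediate
KM-RZ	galangin	9.27	0.34	3	Intermediate
FJ-RZ	volatile_oil	7.75	0.27	3	Intermediate
FJ-RZ	galangin	8.88	0.23	3	Intermediate
LT-4-RZ	volatile_oil	14.65	0.71	3	High
LT-4-RZ	galangin	16.89	0.24	3	High
LT-3-RZ	volatile_oil	10.10	0.39	3	Sub-high
LT-3-RZ	galangin	12.89	0.14	3	Sub-high
LT-2-RZ	volatile_oil	7.09	0.26	3	Intermediate
LT-2-RZ	galangin	9.88	0.35	3	Intermediate
LT-1-RZ	volatile_oil	3.06	0.08	3	Low
LT-1-RZ	galangin	5.42	0.62	3	Low
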