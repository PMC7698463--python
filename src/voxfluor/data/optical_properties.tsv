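band	role	wavelength_nm	tissue	mu_a	mu_s	g	n
VIS	excitation	488	skin	6.0	625	0.9	1.37
VIS	excitation	488	fat	6.0	310	0.9	1.45
VIS	excitation	488	duct	0.2	317	0.9	1.42
VIS	excitation	488	cancer	1.0	300	0.9	1.45
VIS	emission	520	skin	5.8	450	0.9	1.37
VIS	emission	520	fat	4.0	300	0.9	1.45
VIS	emission	520	duct	0.2	268	0.9	1.42
VIS	emission	520	cancer	1.0	230	0.9	1.45
NIR	excitation	780	skin	2.0	241	0.9	1.37
NIR	excitation	780	fat	1.4	136	0.9	1.45
NIR	excitation	780	duct	0.2	169	0.9	1.42
NIR	excitation	780	cancer	1.0	150	0.9	1.45
NIR	emission	820	skin	1.2	228	0.9	1.37
NIR	emission	820	fat	1.2	132	0.9	1.45
NIR	emission	820	duct	0.2	198	0.9	1.42
NIR	emission	820	cancer	0.7	140	0.9	1.45
SWIR	excitation	970	skin	1.0	210	0.9	1.37
SWIR	excitation	970	fat	0.9	76.6	0.9	1.45
SWIR	excitation	970	duct	0.3	122	0.9	1.42
SWIR	excitation	970	cancer	0.9	75.5	0.9	1.45
SWIR	emission	1100	skin	0.7	176	0.9	1.37
SWIR	emission	1100	fat	0.6	72.3	0.9	1.45
SWIR	emission	1100	duct	0.3	122	0.9	1.42
SWIR	emission	1100	cancer	1.0	80.0	0.9	1.45
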