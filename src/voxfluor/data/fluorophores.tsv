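name	band	ex_nm	em_nm	qy	conc_molar	epsC
fluorescein	VIS	488	520	0.95	7.5e-4	12.0
icg	NIR	780	820	0.09	2.0e-4	20.0
pbs_qd	SWIR	970	1100	0.40	1.0e-6	0.63
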