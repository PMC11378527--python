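gene_id	condition	control_value	treated_value	pvalue	printed_log2fc	checkable
SJ08268	HypoS	15.17359	437.4219	4.19E-19	5.629176	0
SJ08268	HL	15.17359	53.51954	0.000785	1.95766	0
SJ08268	HyperS	15.17359	95.1102	3.15E-06	2.658753	0
SJ10859	HypoS	892.388	158.1475	0.000159	-1.71391	0
SJ10859	HL	892.388	231.039	3.77E-05	-1.8184	0
SJ08396	AC	139.0346	50.23922	0.002744	-1.63848	0
SJ08396	HL	139.0346	32.91407	0.000257	-2.00546	0
SJ08396	HT	139.0346	46.53296	0.001502	-1.72623	0
SJ08396	HyperS	139.0346	32.08796	0.000132	-2.13269	0
SJ16113	HypoS	247.9107	36.70475	1.25E-06	-1.99801	0
SJ16113	HL	247.9107	107.737	0.003346	-1.0885	0
SJ16113	HyperS	247.9107	94.44194	0.000321	-1.40548	0
SJ03714	HypoS	227.1891	24.63375	1.31E-06	-2.47049	0
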