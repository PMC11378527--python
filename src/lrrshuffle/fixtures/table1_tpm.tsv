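gene_id	condition	control_value	treated_value	pvalue	printed_log2fc	checkable
Ec-01_001850	SP	2.16	6.51	0.00	1.94	0
Ec-11_005360	SP	6.00	11.17	0.00	1.28	0
Ec-01_002500	SP	0.60	13.25	0.00	4.79	0
Ec-10_004370	SP	12.63	28.93	0.00	1.59	0
Ec-19_000270	SP	1.24	2.90	0.00	1.58	0
Ec-15_004840	SP	17.51	4.28	0.00	-1.60	0
Ec-15_004730	SP	0.77	48.30	0.00	6.32	0
Ec-06_001640	SP	4.84	9.03	0.00	1.28	0
Ec-03_001790	SP	1.89	3.34	0.00	1.19	0
Ec-03_000720	SP	7.91	13.08	0.00	1.11	0
Ec-23_004280	SP	5.80	1.95	0.01	-1.14	0
Ec-19_000290	SP	0.07	0.63	0.00	2.94	0
Ec-27_002510	SP	0.62	3.95	0.00	2.96	0
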