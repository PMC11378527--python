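gene_id	condition	control_value	treated_value	pvalue	printed_log2fc	checkable
Ec-15_004730	HyperS	43.39584	368.2413	0.028	3.08	1
Ec-15_004730-4	HyperS	636.6641	2087.261	0.008	1.71	1
Ec-11_005360	Oxi	508.7174	171.5529	0.018	-1.56	1
Ec-15_004840	HypoS	154.372	621.1525	0.033	2.008	1
Ec-15_004840	Cu_4	343.7432	1616.576	0.01	2.232	1
Ec-15_004840	Cu_8	706.7696	2219.009	0.049	1.65	1
Ec-03_000780-2	HyperS	9542.071	3186.97	0.002	-1.586	1
Ec-01_001850	HyperS	3216.841	14330.86	0.001	2.155	1
Ec-10_000570-3	HyperS	415.3863	2984.452	0.002	2.844	1
Ec-10_000570-3	Cu_8	1771.102	756.998	0.28	-1.227	1
Ec-03_000710	Cu_4	1459.545	744.6286	0.006	-0.971	1
Ec-08_002960	Oxi	355.4299	1341.698	0.04	1.916	1
Ec-10_004370-3	Oxi	531.1694	3495.323	0.04	2.718	1
Ec-10_004370-3	Cu_4	711.6216	3580.153	0.01	2.33	1
Ec-01_002500	HyperS	31.63884	399.6878	0.027	3.658	1
Ec-03_000770	HyperS	324.2043	1237.802	0.017	1.929	1
Ec-03_000770	HypoS	324.2043	46.87266	0.013	-2.795	1
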