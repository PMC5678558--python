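chrom	ap13_total_peaks	ap13_annotated_peaks	vs16_total_peaks	vs16_annotated_peaks	length_mb
Chr01a	9383	1298	6610	953	97.81
Chr01b	8176	1230	5673	907	80.38
Chr02a	10727	1502	7608	1165	103.95
Chr02b	9030	1296	6631	1035	93.55
Chr03a	7695	1339	5610	1004	73.00
Chr03b	5355	729	3697	533	57.82
Chr04a	6214	949	4312	686	63.56
Chr04b	5599	820	3813	584	56.30
Chr05a	11457	1836	8246	1406	116.48
Chr05b	10597	1575	7576	1200	100.40
Chr06a	6429	957	4663	744	72.90
Chr06b	7013	801	5118	626	80.13
Chr07a	6179	953	4392	731	75.76
Chr07b	6646	978	4721	738	70.77
Chr08a	5524	720	3774	520	73.87
Chr08b	5968	733	3762	517	77.82
Chr09a	12929	1845	9148	1397	122.78
Chr09b	9541	1460	7322	1189	87.97
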