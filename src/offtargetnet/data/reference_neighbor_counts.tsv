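drug_a	drug_b	m11	m10	m01	jaccard	jaccard_distance
Sartans	Paxlovid	17	303	11	0.05136	0.94864
Sartans (COVID-19)	Paxlovid	0	60	28	0	1
Sartans	Perphenazine	19	301	132	0.042035	0.957965
Sartans (COVID-19)	Perphenazine	12	308	139	0.026144	0.973856
Paxlovid	Perphenazine	0	28	151	0	1
Sartans	Sartans (COVID-19)	51	269	9	0.155015	0.844985
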