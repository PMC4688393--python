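gene_a	gene_b	ka	ks	ka_ks	mya
PtrFLA2	PtrFLA12	0.0600	0.2364	0.2539	13.0
PtrFLA3	PtrFLA21	0.0685	0.2571	0.2665	14.1
PtrFLA4	PtrFLA10	0.0845	0.3179	0.2658	17.5
PtrFLA6	PtrFLA26	0.0357	0.2945	0.1211	16.2
PtrFLA7	PtrFLA25	0.0225	0.3196	0.0705	17.5
PtrFLA8	PtrFLA11	0.0263	0.2573	0.1022	14.1
PtrFLA13	PtrFLA23	0.0733	0.3306	0.2216	18.2
PtrFLA14	PtrFLA24	0.0387	0.2409	0.1605	13.2
PtrFLA15	PtrFLA19	0.0276	0.0909	0.3036	5.0
PtrFLA16	PtrFLA30	0.0722	0.3050	0.2369	16.8
PtrFLA17	PtrFLA18	0.0396	0.1197	0.3311	6.6
PtrFLA31	PtrFLA34	0.0428	0.0858	0.4991	4.7
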