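gene_symbol	locus_id	position	gene_length	orf_length	protein_length	mol_wt	pI	localization
PtrFLA1	Potri.001G320800	Chr01: 32566530–32567917	1388	732	243	26072.9	7.99	Membrane
PtrFLA2	Potri.001G367900	Chr01: 38081667–38084340	2674	1221	406	43115.3	5.62	Membrane
PtrFLA3	Potri.002G223300	Chr02: 21076590–21078318	1729	792	263	27722.3	4.65	Membrane
PtrFLA4	Potri.004G210600	Chr04: 21827522–21828762	1241	807	268	28250.5	8.89	Membrane
PtrFLA5	Potri.005G079500	Chr05:5852241-5853569	1329	1329	442	47582.5	5.95	Membrane
PtrFLA6	Potri.006G129200	Chr06: 10546378–10547472	1095	720	239	25127.5	5.27	Membrane
PtrFLA7	Potri.006G200300	Chr06: 21552110–21555071	2962	1401	466	50976	6.16	Mem, chlo
PtrFLA8	Potri.008G012400	Chr08: 685882–690857	4976	1392	463	51037	6.06	Membrane
PtrFLA9	Potri.009G012100	Chr09: 2101448–2102467	1020	792	263	28752.2	8.77	Membrane
PtrFLA10	Potri.009G012200	Chr09: 2104068–2105349	1282	810	269	28351.4	7.74	Membrane
PtrFLA11	Potri.010G244900	Chr10: 21994487–21999392	4906	1380	459	50838.8	5.95	Membrane
PtrFLA12	Potri.011G093500	Chr11: 11364228–11367418	3191	1227	408	43721	5.58	Membrane
PtrFLA13	Potri.012G015000	Chr12: 1466939–1471579	4641	810	269	28147.6	7.80	Membrane
PtrFLA14	Potri.012G127900	Chr12: 14557761–14560026	2266	723	240	25352.7	5.33	Membrane
PtrFLA15	Potri.013G014200	Chr13: 912614–913708	1095	801	266	28178	7.02	Membrane
PtrFLA16	Potri.013G120600	Chr13: 13393705–13394592	888	717	238	24798.2	6.55	Membrane
PtrFLA17	Potri.013G151300	Chr13: 15545458–15546340	883	810	269	28400.3	6.18	Membrane
PtrFLA18	Potri.013G151400	Chr13: 15548757–15553715	4959	810	269	28340.2	7.06	Membrane
PtrFLA19	Potri.013G151500	Chr13: 15559778–15560942	1165	795	264	27569.4	7.91	Membrane
PtrFLA20	Potri.014G071700	Chr14: 5793739–5795660	1922	1266	421	43250.3	5.37	Mem, Chlo
PtrFLA21	Potri.014G162900	Chr14: 12850627–12852961	2335	789	262	27635.3	5.63	Membrane
PtrFLA22	Potri.014G168100	Chr14: 13433009–13434622	1614	1194	397	42646.6	5.64	Membrane
PtrFLA23	Potri.015G013300	Chr15: 869556–870642	1087	804	267	28234.8	7.80	Membrane
PtrFLA24	Potri.015G129400	Chr15: 14100586–14102248	1663	723	240	25389.9	6.72	Membrane
PtrFLA25	Potri.016G066500	Chr16: 4713550–4716897	3348	1401	466	51132.1	6.06	Mem, chlo
PtrFLA26	Potri.016G088700	Chr16: 7097575–7099033	1459	720	239	25188.5	5.73	Membrane
PtrFLA27	Potri.017G111600	Chr17: 12724860–12725918	1059	1059	352	38260.7	4.38	Membrane
PtrFLA28	Potri.019G002300	Chr19: 281955–282806	852	852	283	30637.6	10.8	Membrane
PtrFLA29	Potri.019G049600	Chr19:7413805-7414563	759	759	252	27188.4	6.28	Membrane
PtrFLA30	Potri.019G093300	Chr19: 12352008–12352993	986	738	245	25481.9	6.72	Membrane
PtrFLA31	Potri.019G120900	Chr19: 14875495–14876429	935	684	227	23832.3	6.96	Membrane
PtrFLA32	Potri.019G121100	Chr19: 14892331–14893290	960	789	262	27526.4	6.50	Membrane
PtrFLA33	Potri.019G121200	Chr19: 14900852–14901643	792	792	263	27479.3	6.28	Membrane
PtrFLA34	Potri.019G122800	Chr19: 15107258–15108050	793	759	252	26545.3	6.64	Membrane
PtrFLA35	Potri.019G123200	Chr19: 15135778–15137005	1228	792	263	27583.5	6.97	Membrane
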