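transcript_id	table	chrom	strand	exon_number	locus	length_bp	log2fc	p_value	q_value
MSTRG.6875.40	S	Chr15	-	5	10767271-10770633;10770728-10775914;10776269-10776550;10776821-10778416;10778901-10779037	10565	12.44	0.00032639	0.001405702
MSTRG.3932.19	S	Chr12	-	4	1060573-1060629;1062299-1062828;1063040-1063243;1063448-1065307	2651	8.68	7.76E-09	8.36E-08
MSTRG.11012.44	S	Chr2	+	5	17944191-17945059;17946907-17947142;17950697-17950970;17953572-17954029;17955731-17956328	2435	8.50	6.46E-10	8.17E-09
MSTRG.2776.2	S	Chr10	-	2	26454062-26455136;26475255-26475998	1819	8.45	2.44E-94	2.03E-91
MSTRG.20713.2	S	Chr4	+	2	21929023-21932131;21932153-21934797	5754	7.84	1.10E-05	6.58E-05
MSTRG.18071.3	S	Chr28	+	2	10375469-10380019;10380114-10380217	4655	7.61	0.0001034	0.000501427
MSTRG.3932.24	S	Chr12	-	4	1061852-1061880;1062299-1063243;1063448-1063651;1063849-1065581	2911	6.92	1.48E-12	2.60E-11
MSTRG.3932.15	S	Chr12	-	4	1060572-1060629;1062299-1062646;1062829-1063243;1063448-1065307	2681	6.33	1.10E-06	8.07E-06
MSTRG.17405.1	S	Chr27	+	2	11469445-11470705;11472274-11472518	1506	5.21	4.23E-06	2.78E-05
MSTRG.10602.2	S	Chr2	+	2	4355379-4355881;4407450-4407698	752	5.14	0.00111817	0.004155295
MSTRG.4909.2	S	Chr13	+	2	1575626-1585474;1585507-1585531	9874	5.14	3.31E-05	0.000180403
MSTRG.17825.3	S	Chr28	-	3	3751409-3767991;3786614-3786676;3816087-3816305	16865	5.14	3.88E-05	0.000208446
MSTRG.7482.1	S	Chr16	-	2	3114234-3114956;3114982-3115061	803	4.92	8.31E-09	8.92E-08
MSTRG.29804.10	S	Scaffold 789	-	5	37879-38503;38652-38681;38817-38878;38902-38943;42553-43887	2094	4.84	1.32E-14	2.96E-13
MSTRG.29873.1	S	Scaffold 83	-	2	21148-22080;22110-23497	2321	4.69	0.00181057	0.00631492
MSTRG.17825.2	S	Chr28	-	4	3751409-3758714;3758762-3767991;3809101-3809293;3816087-3816347	16990	4.51	4.84E-19	1.83E-17
MSTRG.9533.1	S	Chr18	-	2	22324962-22326781;22332655-22333456	2622	4.32	3.06E-09	3.49E-08
MSTRG.29805.1	S	Scaffold 789	+	2	37827-38367;42417-42970	1095	3.89	2.19E-08	2.19E-07
MSTRG.713.1	S	Chr1	+	2	19868296-19869308;19870259-19876056	6811	3.88	1.54E-16	4.42E-15
MSTRG.22483.6	S	Chr6	+	2	2938722-2938846;2941360-2944153	2919	3.82	0.00036102	0.001534732
MSTRG.25315.3	R	Chr8	+	7	22677723-22678101;22749104-22749274;22749522-22749632;22749844-22749990;22750410-22750610;22750917-22751064;22751107-22756133	6184	15.70	1.39E-35	1.64E-33
MSTRG.25316.8	R	Chr8	-	2	22699728-22709465;22714458-22716431	11712	14.85	2.02E-35	2.37E-33
MSTRG.25723.1	R	Chr9	-	2	5260089-5260324;5260848-5261965	1354	12.11	0.001931984	0.006687415
MSTRG.17282.3	R	Chr27	-	2	9094064-9096939;9097421-9098545	4001	11.85	2.80E-22	1.47E-20
MSTRG.11012.32	R	Chr2	+	6	17944191-17944758;17946606-17946660;17951139-17951384;17952309-17953058;17953983-17954029;17955731-17956328	2264	10.05	7.69E-14	1.56E-12
MSTRG.17788.5	R	Chr28	+	2	3055427-3055865;3067332-3067769	877	9.23	6.90E-78	4.02E-75
MSTRG.7200.3	R	Chr15	-	2	22250366-22253327;22253357-22254342	3948	9.21	1.25E-10	1.74E-09
MSTRG.17632.2	R	Chr28	+	2	155617-156240;157354-157412	683	8.17	6.66E-10	8.41E-09
MSTRG.29804.8	R	Scaffold 789	-	5	37827-38499;38648-38681;38817-38943;42553-42688;42828-43181	1324	7.92	1.75E-07	1.48E-06
MSTRG.11011.14	R	Chr2	-	6	17944162-17945020;17946868-17946941;17950424-17950483;17950556-17951345;17952270-17952464;17956158-17956328	2149	7.81	7.04E-06	4.39E-05
MSTRG.8464.1	R	Chr17	+	2	13024071-13024252;13024645-13024942	480	7.54	6.81E-06	4.26E-05
MSTRG.11011.22	R	Chr2	-	5	17944162-17945790;17949556-17949599;17953157-17953625;17954550-17955319;17956097-17956328	3144	7.34	2.29E-24	1.43E-22
MSTRG.16430.2	R	Chr26	+	2	6123733-6123812;6127962-6128560	679	7.05	1.20E-05	7.14E-05
MSTRG.16712.6	R	Chr26	+	3	12454424-12454523;12454611-12454620;12471577-12471779	313	6.93	0.000146114	0.00068547
MSTRG.8465.1	R	Chr17	+	2	13034463-13034697;13035057-13035745	924	6.62	1.12E-07	9.79E-07
MSTRG.25727.1	R	Chr9	-	4	5596254-5596306;5596605-5596722;5596854-5596918;5597006-5597106	337	6.54	4.62E-06	3.00E-05
MSTRG.3908.1	R	Chr12	-	2	866882-866923;875029-875217	231	6.52	5.89E-05	0.000303147
MSTRG.3932.9	R	Chr12	-	5	1060001-1060089;1061991-1062027;1062647-1062828;1063040-1063243;1064053-1065319	1779	6.44	0.00024098	0.001070053
MSTRG.8218.1	R	Chr17	-	2	3839813-3840316;3846632-3848147	2020	6.30	1.32E-07	1.14E-06
MSTRG.13055.1	R	Chr21	+	2	3668903-3668944;3674496-3675310	857	6.16	8.12E-07	6.10E-06
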