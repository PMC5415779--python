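start	stop	gene	p	bold
1	100	D-Loop	-	0
101	200	D-Loop	-	0
201	300	D-Loop	-	0
301	400	D-Loop	-	0
401	500	D-Loop	7.99E-03	0
501	600	MT-TF	4.49E-03	0
601	700	MT-TF/MT-RNR1	1.16E-02	0
701	800	MT-RNR1	3.22E-03	0
801	900	MT-RNR1	1.91E-04	1
901	1000	MT-RNR1	ND	0
1001	1100	MT-RNR1	ND	0
1101	1200	MT-RNR1	ND	0
1201	1300	MT-RNR1	ND	0
1301	1400	MT-RNR1	ND	0
1401	1500	MT-RNR1	ND	0
1501	1600	MT-RNR1	ND	0
1601	1700	MT-RNR1/MT-TV/MT-RNR2	ND	0
1701	1800	MT-RNR2	ND	0
1801	1900	MT-RNR2	ND	0
1901	2000	MT-RNR2	ND	0
2001	2100	MT-RNR2	ND	0
2101	2200	MT-RNR2	ND	0
2201	2300	MT-RNR2	ND	0
2301	2400	MT-RNR2	8.10E-03	0
2401	2500	MT-RNR2	7.50E-03	0
2501	2600	MT-RNR2	5.14E-03	0
2601	2700	MT-RNR2	ND	0
2701	2800	MT-RNR2	ND	0
2801	2900	MT-RNR2	-	0
2901	3000	MT-RNR2	-	0
3001	3100	MT-RNR2	-	0
3101	3200	MT-RNR2	-	0
3201	3300	MT-RNR2/MT-TL	1.51E-03	0
3301	3400	MT-TL1/MT-ND1	-	0
3401	3500	MT-ND1	1.37E-02	0
3501	3600	MT-ND1	4.27E-03	0
3601	3700	MT-ND1	5.56E-03	0
3701	3800	MT-ND1	8.21E-03	0
3801	3900	MT-ND1	-	0
3901	4000	MT-ND1	-	0
4001	4100	MT-ND1	3.07E-06	1
4101	4200	MT-ND1	-	0
4201	4300	MT-ND1/MT-TI	ND	0
4301	4400	MT-TI/MT-TQ	ND	0
4401	4500	MT-TM/MT-ND2	ND	0
4501	4600	MT-ND2	ND	0
4601	4700	MT-ND2	ND	0
4701	4800	MT-ND2	ND	0
4801	4900	MT-ND2	ND	0
4901	5000	MT-ND2	ND	0
5001	5100	MT-ND2	ND	0
5101	5200	MT-ND2	ND	0
5201	5300	MT-ND2	ND	0
5301	5400	MT-ND2	ND	0
5401	5500	MT-ND2	ND	0
5501	5600	MT-ND2/MT-TW/MT-TA	ND	0
5601	5700	MT-TA/MT-TN	ND	0
5701	5800	MT-TN/MT-TC	ND	0
5801	5900	MT-TC/MT-TY	ND	0
5901	6000	MT-CO1	ND	0
6001	6100	MT-CO1	ND	0
6101	6200	MT-CO1	ND	0
6201	6300	MT-CO1	ND	0
6301	6400	MT-CO1	ND	0
6401	6500	MT-CO1	ND	0
6501	6600	MT-CO1	ND	0
6601	6700	MT-CO1	ND	0
6701	6800	MT-CO1	ND	0
6801	6900	MT-CO1	ND	0
6901	7000	MT-CO1	ND	0
7001	7100	MT-CO1	ND	0
7101	7200	MT-CO1	ND	0
7201	7300	MT-CO1	ND	0
7301	7400	MT-CO1	ND	0
7401	7500	MT-CO1/MT-TS1	ND	0
7501	7600	MT-TS1/MT-TD/MT-CO2	ND	0
7601	7700	MT-CO2	ND	0
7701	7800	MT-CO2	ND	0
7801	7900	MT-CO2	ND	0
7901	8000	MT-CO2	ND	0
8001	8100	MT-CO2	ND	0
8101	8200	MT-CO2	ND	0
8201	8300	MT-CO2/MT-TK	ND	0
8301	8400	MT-TK/MT-ATP8	ND	0
8401	8500	MT-ATP8	ND	0
8501	8600	MT-ATP8/MT-ATP6	ND	0
8601	8700	MT-ATP6	ND	0
8701	8800	MT-ATP6	ND	0
8801	8900	MT-ATP6	ND	0
8901	9000	MT-ATP6	ND	0
9001	9100	MT-ATP6	ND	0
9101	9200	MT-ATP6	ND	0
9201	9300	MT-ATP6/MT-CO3	ND	0
9301	9400	MT-CO3	ND	0
9401	9500	MT-CO3	ND	0
9501	9600	MT-CO3	ND	0
9601	9700	MT-CO3	ND	0
9701	9800	MT-CO3	ND	0
9801	9900	MT-CO3	-	0
9901	10000	MT-CO3/MT-TG	-	0
10001	10100	MT-TG/MT-ND3	1.81E-02	0
10101	10200	MT-ND3	1.39E-02	0
10201	10300	MT-ND3	3.53E-04	1
10301	10400	MT-ND3/MT-TR/MT-ND4L	1.19E-05	1
10401	10500	MT-ND4L	2.61E-04	1
10501	10600	MT-ND4L	9.05E-04	0
10601	10700	MT-ND4L	ND	0
10701	10800	MT-ND4L/MT-ND4	ND	0
10801	10900	MT-ND4	ND	0
10901	11000	MT-ND4	ND	0
11001	11100	MT-ND4	ND	0
11101	11200	MT-ND4	ND	0
11201	11300	MT-ND4	8.86E-05	1
11301	11400	MT-ND4	1.65E-03	0
11401	11500	MT-ND4	ND	0
11501	11600	MT-ND4	ND	0
11601	11700	MT-ND4	ND	0
11701	11800	MT-ND4	ND	0
11801	11900	MT-ND4	ND	0
11901	12000	MT-ND4	ND	0
12001	12100	MT-ND4	ND	0
12101	12200	MT-ND4/MT-TH	ND	0
12201	12300	MT-TS2/MT-TL2	ND	0
12301	12400	MT-TL2/MT-ND5	-	0
12401	12500	MT-ND5	-	0
12501	12600	MT-ND5	-	0
12601	12700	MT-ND5	-	0
12701	12800	MT-ND5	1.81E-03	0
12801	12900	MT-ND5	1.05E-02	0
12901	13000	MT-ND5	8.23E-03	0
13001	13100	MT-ND5	ND	0
13101	13200	MT-ND5	ND	0
13201	13300	MT-ND5	ND	0
13301	13400	MT-ND5	1.44E-03	0
13401	13500	MT-ND5	9.13E-04	0
13501	13600	MT-ND5	1.61E-02	0
13601	13700	MT-ND5	3.89E-02	0
13701	13800	MT-ND5	2.77E-04	1
13801	13900	MT-ND5	2.80E-03	0
13901	14000	MT-ND5	1.88E-02	0
14001	14100	MT-ND5	9.31E-03	0
14101	14200	MT-ND5/MT-ND6	-	0
14201	14300	MT-ND6	-	0
14301	14400	MT-ND6	1.04E-02	0
14401	14500	MT-ND6	1.99E-02	0
14501	14600	MT-ND6	2.26E-02	0
14601	14700	MT-ND6/MT-TE	3.82E-03	0
14701	14800	MT-TE/MT-CYB	1.92E-02	0
14801	14900	MT-CYB	ND	0
14901	15000	MT-CYB	ND	0
15001	15100	MT-CYB	ND	0
15101	15200	MT-CYB	3.30E-02	0
15201	15300	MT-CYB	-	0
15301	15400	MT-CYB	-	0
15401	15500	MT-CYB	8.52E-04	0
15501	15600	MT-CYB	7.43E-04	0
15601	15700	MT-CYB	1.16E-02	0
15701	15800	MT-CYB	2.24E-02	0
15801	15900	MT-CYB/MT-TT	-	0
15901	16000	MT-TT/MT-TP	-	0
16001	16100	MT-TP	-	0
16101	16200	D-Loop	2.23E-03	0
16201	16300	D-Loop	5.02E-04	1
16301	16400	D-Loop	1.84E-03	0
16401	16500	D-Loop	1.12E-03	0
16501	16600	D-Loop	2.20E-03	0
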