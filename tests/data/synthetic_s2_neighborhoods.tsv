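species	focal_gene	offset	symbol	strand
gar	HIF1A	-1	U1	+
gar	HIF1A	-2	U2	+
gar	HIF1A	-3	U3	+
gar	HIF1A	-4	U4	+
gar	HIF1A	-5	U5	+
gar	HIF1A	-6	U6	+
gar	HIF1A	-7	U7	+
gar	HIF1A	-8	U8	+
gar	HIF1A	-9	U9	+
gar	HIF1A	-10	U10	+
gar	HIF1A	1	D1	+
gar	HIF1A	2	D2	+
gar	HIF1A	3	D3	+
gar	HIF1A	4	D4	+
gar	HIF1A	5	D5	+
gar	HIF1A	6	D6	+
gar	HIF1A	7	D7	+
gar	HIF1A	8	D8	+
gar	HIF1A	9	D9	+
gar	HIF1A	10	D10	+
zebrafish	HIF1Aa	-1	U1	+
zebrafish	HIF1Aa	-2	U2	+
zebrafish	HIF1Aa	-3	U3	+
zebrafish	HIF1Aa	-4	U4	+
zebrafish	HIF1Aa	-5	U5	+
zebrafish	HIF1Aa	-6	U6	+
zebrafish	HIF1Aa	-7	U7	+
zebrafish	HIF1Aa	-8	U8	+
zebrafish	HIF1Aa	-9	U9	+
zebrafish	HIF1Aa	-10	U10	+
zebrafish	HIF1Aa	1	D1	+
zebrafish	HIF1Aa	2	D2	+
zebrafish	HIF1Aa	3	D3	+
zebrafish	HIF1Aa	4	ZA1	+
zebrafish	HIF1Aa	5	ZA2	+
zebrafish	HIF1Aa	6	ZA3	+
zebrafish	HIF1Aa	7	ZA4	+
zebrafish	HIF1Aa	8	ZA5	+
zebrafish	HIF1Aa	9	ZA6	+
zebrafish	HIF1Aa	10	ZA7	+
zebrafish	HIF1Ab	-1	U2	+
zebrafish	HIF1Ab	-2	U1	+
zebrafish	HIF1Ab	-3	U4	+
zebrafish	HIF1Ab	-4	ZB1	+
zebrafish	HIF1Ab	-5	ZB2	+
zebrafish	HIF1Ab	-6	ZB3	+
zebrafish	HIF1Ab	-7	ZB4	+
zebrafish	HIF1Ab	-8	ZB5	+
zebrafish	HIF1Ab	-9	ZB6	+
zebrafish	HIF1Ab	-10	ZB7	+
zebrafish	HIF1Ab	1	D2	+
zebrafish	HIF1Ab	2	D1	+
zebrafish	HIF1Ab	3	D5	+
zebrafish	HIF1Ab	4	ZC1	+
zebrafish	HIF1Ab	5	ZC2	+
zebrafish	HIF1Ab	6	ZC3	+
zebrafish	HIF1Ab	7	ZC4	+
zebrafish	HIF1Ab	8	ZC5	+
zebrafish	HIF1Ab	9	ZC6	+
zebrafish	HIF1Ab	10	ZC7	+
gar	HIF2A	-1	V1	+
gar	HIF2A	-2	V2	+
gar	HIF2A	-3	V3	+
gar	HIF2A	-4	V4	+
gar	HIF2A	-5	V5	+
gar	HIF2A	-6	V6	+
gar	HIF2A	-7	V7	+
gar	HIF2A	-8	V8	+
gar	HIF2A	-9	V9	+
gar	HIF2A	-10	V10	+
gar	HIF2A	1	W1	+
gar	HIF2A	2	W2	+
gar	HIF2A	3	W3	+
gar	HIF2A	4	W4	+
gar	HIF2A	5	W5	+
gar	HIF2A	6	W6	+
gar	HIF2A	7	W7	+
gar	HIF2A	8	W8	+
gar	HIF2A	9	W9	+
gar	HIF2A	10	W10	+
zebrafish	hif2ab	-1	V1	+
zebrafish	hif2ab	-2	V2	+
zebrafish	hif2ab	-3	V3	+
zebrafish	hif2ab	-4	V4	+
zebrafish	hif2ab	-5	V5	+
zebrafish	hif2ab	-6	ZD1	+
zebrafish	hif2ab	-7	ZD2	+
zebrafish	hif2ab	-8	ZD3	+
zebrafish	hif2ab	-9	ZD4	+
zebrafish	hif2ab	-10	ZD5	+
zebrafish	hif2ab	1	W1	+
zebrafish	hif2ab	2	W2	+
zebrafish	hif2ab	3	W3	+
zebrafish	hif2ab	4	W4	+
zebrafish	hif2ab	5	ZE1	+
zebrafish	hif2ab	6	ZE2	+
zebrafish	hif2ab	7	ZE3	+
zebrafish	hif2ab	8	ZE4	+
zebrafish	hif2ab	9	ZE5	+
zebrafish	hif2ab	10	ZE6	+
zebrafish	hif2aa	-1	V1	+
zebrafish	hif2aa	-2	V2	+
zebrafish	hif2aa	-3	Y1	+
zebrafish	hif2aa	-4	Y2	+
zebrafish	hif2aa	-5	Y3	+
zebrafish	hif2aa	-6	Y4	+
zebrafish	hif2aa	-7	Y5	+
zebrafish	hif2aa	-8	Y6	+
zebrafish	hif2aa	-9	Y7	+
zebrafish	hif2aa	-10	Y8	+
zebrafish	hif2aa	1	W1	+
zebrafish	hif2aa	2	W2	+
zebrafish	hif2aa	3	Y9	+
zebrafish	hif2aa	4	Y10	+
zebrafish	hif2aa	5	Y11	+
zebrafish	hif2aa	6	Y12	+
zebrafish	hif2aa	7	Y13	+
zebrafish	hif2aa	8	Y14	+
zebrafish	hif2aa	9	Y15	+
zebrafish	hif2aa	10	ZF1	+
platyfish	HIF2Ab_tr	-1	Y1	+
platyfish	HIF2Ab_tr	-2	Y2	+
platyfish	HIF2Ab_tr	-3	Y3	+
platyfish	HIF2Ab_tr	-4	Y4	+
platyfish	HIF2Ab_tr	-5	Y5	+
platyfish	HIF2Ab_tr	-6	Y6	+
platyfish	HIF2Ab_tr	-7	Y7	+
platyfish	HIF2Ab_tr	-8	Y8	+
platyfish	HIF2Ab_tr	-9	Y9	+
platyfish	HIF2Ab_tr	-10	Y10	+
platyfish	HIF2Ab_tr	1	Y11	+
platyfish	HIF2Ab_tr	2	Y12	+
platyfish	HIF2Ab_tr	3	Y13	+
platyfish	HIF2Ab_tr	4	Y14	+
platyfish	HIF2Ab_tr	5	Y15	+
platyfish	HIF2Ab_tr	6	M1	+
platyfish	HIF2Ab_tr	7	M2	+
platyfish	HIF2Ab_tr	8	M3	+
platyfish	HIF2Ab_tr	9	M4	+
platyfish	HIF2Ab_tr	10	M5	+
gar	HIF3A	-1	P1	+
gar	HIF3A	-2	P2	+
gar	HIF3A	-3	P3	+
gar	HIF3A	-4	P4	+
gar	HIF3A	-5	P5	+
gar	HIF3A	-6	P6	+
gar	HIF3A	-7	P7	+
gar	HIF3A	-8	P8	+
gar	HIF3A	-9	P9	+
gar	HIF3A	-10	unknown	+
gar	HIF3A	1	Q1	+
gar	HIF3A	2	Q2	+
gar	HIF3A	3	Q3	+
gar	HIF3A	4	Q4	+
gar	HIF3A	5	Q5	+
gar	HIF3A	6	Q6	+
gar	HIF3A	7	Q7	+
gar	HIF3A	8	Q8	+
gar	HIF3A	9	Q9	+
gar	HIF3A	10	Q10	+
zebrafish	HIF3A	-1	P1	+
zebrafish	HIF3A	-2	ZG1	+
zebrafish	HIF3A	-3	ZG2	+
zebrafish	HIF3A	-4	ZG3	+
zebrafish	HIF3A	-5	ZG4	+
zebrafish	HIF3A	-6	ZG5	+
zebrafish	HIF3A	-7	ZG6	+
zebrafish	HIF3A	-8	ZG7	+
zebrafish	HIF3A	-9	ZG8	+
zebrafish	HIF3A	-10	unknown	+
zebrafish	HIF3A	1	Q1	+
zebrafish	HIF3A	2	Q2	+
zebrafish	HIF3A	3	ZH1	+
zebrafish	HIF3A	4	ZH2	+
zebrafish	HIF3A	5	ZH3	+
zebrafish	HIF3A	6	ZH4	+
zebrafish	HIF3A	7	ZH5	+
zebrafish	HIF3A	8	ZH6	+
zebrafish	HIF3A	9	ZH7	+
zebrafish	HIF3A	10	ZH8	+
pike	HIF1Aa	-1	K1	+
pike	HIF1Aa	-2	K2	+
pike	HIF1Aa	-3	K3	+
pike	HIF1Aa	-4	K4	+
pike	HIF1Aa	-5	K5	+
pike	HIF1Aa	-6	K6	+
pike	HIF1Aa	-7	K7	+
pike	HIF1Aa	-8	K8	+
pike	HIF1Aa	-9	K9	+
pike	HIF1Aa	-10	K10	+
pike	HIF1Aa	1	K11	+
pike	HIF1Aa	2	K12	+
pike	HIF1Aa	3	K13	+
pike	HIF1Aa	4	K14	+
pike	HIF1Aa	5	K15	+
pike	HIF1Aa	6	K16	+
pike	HIF1Aa	7	K17	+
pike	HIF1Aa	8	K18	+
pike	HIF1Aa	9	K19	+
pike	HIF1Aa	10	K20	+
trout	HIF1Aa_s1	-1	K1	+
trout	HIF1Aa_s1	-2	K2	+
trout	HIF1Aa_s1	-3	K3	+
trout	HIF1Aa_s1	-4	TA1	+
trout	HIF1Aa_s1	-5	TA2	+
trout	HIF1Aa_s1	-6	TA3	+
trout	HIF1Aa_s1	-7	TA4	+
trout	HIF1Aa_s1	-8	TA5	+
trout	HIF1Aa_s1	-9	TA6	+
trout	HIF1Aa_s1	-10	TA7	+
trout	HIF1Aa_s1	1	K11	+
trout	HIF1Aa_s1	2	K12	+
trout	HIF1Aa_s1	3	K13	+
trout	HIF1Aa_s1	4	TB1	+
trout	HIF1Aa_s1	5	TB2	+
trout	HIF1Aa_s1	6	TB3	+
trout	HIF1Aa_s1	7	TB4	+
trout	HIF1Aa_s1	8	TB5	+
trout	HIF1Aa_s1	9	TB6	+
trout	HIF1Aa_s1	10	TB7	+
trout	HIF1Aa_s2	-1	K1	+
trout	HIF1Aa_s2	-2	TC1	+
trout	HIF1Aa_s2	-3	TC2	+
trout	HIF1Aa_s2	-4	TC3	+
trout	HIF1Aa_s2	-5	TC4	+
trout	HIF1Aa_s2	-6	TC5	+
trout	HIF1Aa_s2	-7	TC6	+
trout	HIF1Aa_s2	-8	TC7	+
trout	HIF1Aa_s2	-9	TC8	+
trout	HIF1Aa_s2	-10	TC9	+
trout	HIF1Aa_s2	1	K11	+
trout	HIF1Aa_s2	2	TD1	+
trout	HIF1Aa_s2	3	TD2	+
trout	HIF1Aa_s2	4	TD3	+
trout	HIF1Aa_s2	5	TD4	+
trout	HIF1Aa_s2	6	TD5	+
trout	HIF1Aa_s2	7	TD6	+
trout	HIF1Aa_s2	8	TD7	+
trout	HIF1Aa_s2	9	TD8	+
trout	HIF1Aa_s2	10	TD9	+
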