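genome	tu	name	sequence	position
Acaryochloris marina MBIC11017	AM1_3549 AM1_3550	- recA	AATAAATCTGTACT	-97
Acaryochloris marina MBIC11017	AM1_3948	lexA	AGTACAGGTGTTTT	-132
Anabaena variabilis ATCC 29413	Ava_2176	-	AGTTCTCATGTACT	-144
Anabaena variabilis ATCC 29413	Ava_1462	-	AGTACTTATGTACT	-56
Anabaena variabilis ATCC 29413	Ava_3591	-	AGTTCTTCTGTATC	-112
Anabaena variabilis ATCC 29413	Ava_2198	lexA	AGTACTAATGTTCT	-47
Anabaena variabilis ATCC 29413	Ava_2059 Ava_2058	- -	CGTACATTTGTACC	-71
Anabaena variabilis ATCC 29413	Ava_4925	recA	AGTATATCTGTTCT	-93
Cyanothece PCC 8801	PCC8801_0945	-	AAAACTCTTGTACT	-78
Cyanothece PCC 8801	PCC8801_2186 PCC8801_2185	- -	AGTACTTATGTTCG	-101
Microcystis aeruginosa NIES 843	MAE_39060	ssb	CATACTATTGTACT	-59
Microcystis aeruginosa NIES 843	MAE_16070	recA	CATACTGCTGTACT	-68
Nostoc punctiforme PCC 73102	Npun_F1842	-	AGTACACCTGTACT	-56
Nostoc punctiforme PCC 73102	Npun_F2914	recA	AGTATATCTGTTCT	-102
Nostoc punctiforme PCC 73102	Npun_F6100 Npun_F6101 Npun_F6102	- - -	AGTACGATTGTTCT	-111
Nostoc punctiforme PCC 73102	Npun_R5568 Npun_R5567	- -	CGTACATTTGTACT	-74
Nostoc sp PCC7120	alr4908	lexA	AGTACTAATGTTCT	-35
Nostoc sp PCC7120	all4790 all4789	- -	CGTACATTTGTACC	-31
Nostoc sp PCC7120	alr4905	-	AGTTCTCATGTACT	-100
Nostoc sp PCC7120	alr3716	uvrA	AGTACTATTGTTCT	-72
Nostoc sp PCC7120	alr0088	ssb	AGTACTTATGTACT	-16
Nostoc sp PCC7120	all3272	recA	AGTATATCTGTTCT	-52
Prochlorococcus marinus AS9601	A9601_17691	recA	AGTACAGATGTACT	-126
Prochlorococcus marinus CCMP1375	Pro1784	ssb	AAAACATAAGTATT	-109
Prochlorococcus marinus MED4	PMM1562	recA	AGTACACATGTACT	-123
Prochlorococcus marinus MED4	PMM1262	lexA	GGTACAAATGTATT	-57
Prochlorococcus marinus MIT9313	PMT0380	-	GGTACACATGTATT	-56
Prochlorococcus marinus MIT9211	P9211_13051 P9211_13041	lexA -	GGTACATATGTATT	-69
Prochlorococcus marinus MIT9215	P9215_18341	recA	AGTACAGATGTACT	-126
Prochlorococcus marinus MIT9301	P9301_17531	recA	AGTACAGATGTACT	-125
Prochlorococcus marinus MIT9303	P9303_19141	lexA	GGTACACATGTATT	-81
Prochlorococcus marinus MIT9312	PMT9312_1654	recA	AGTACAGATGTACT	-126
Prochlorococcus marinus MIT9515	P9515_17441	recA	AGTACGCATGTACT	-123
Prochlorococcus marinus MIT9515	P9515_18121	-	AATATATCTATTCT	-139
Prochlorococcus marinus NATL1A	NATL1_20071	recA	CGTACGTCTGTACT	-132
Prochlorococcus marinus NATL1A	NATL1_16801	lexA	AGGACAAATGTACT	-52
Prochlorococcus marinus NATL2A	PMN2A_1133	recA	CGTACGTCTGTACT	-132
Prochlorococcus marinus NATL2A	PMN2A_0828	lexA	AGGACGAATGTACT	-52
Synechococcus CC9605	Syncc9605_0929	lexA	GGTACAAATGTATT	-61
Synechococcus CC9605	Syncc9605_0104	-	GATACCGCAGTTTA	-140
Synechococcus CC9902	Syncc9902_1949	recA	CGTACGTTTGTACT	-104
Synechococcus CC9902	Syncc9902_1481	lexA	GGTACAAATGTATT	-59
Synechococcus PCC7002	SYNPCC7002_A0426 SYNPCC7002_A0425 SYNPCC7002_A0424	recA - -	AGTACGATTGAACT	-90
Synechococcus PCC7002	SYNPCC7002_A0119	ssb	AGAACAGTTGTATG	-53
Synechococcus RCC307	SynRCC307_1756	lexA	GGCACAAATGTATT	-39
Synechococcus WH7803	SynWH7803_0171	ssb	CAACCGTCAGTTCT	-56
Synechococcus WH7803	SynWH7803_0439	recA	CGTACATCTGTACT	-172
Synechococcus sp WH8102	SYNW2062	recA	CGTACGCCTGTACT	-104
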