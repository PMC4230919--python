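Location	Code	Lon	Lat	Date	SampleType	Host	Accessions
St. Andrews	StA1	-61.750	45.499	01-04-11	ES	A. maculatum	KJ711228;KJ711229;KJ711248
St. Andrews	StA2	-61.750	45.499	05-05-12	ES	A. maculatum	KJ711230;KJ711231;KJ711232
East Bay	EB	-60.362	46.013	25-04-11	ES	A. maculatum	KJ711198;KJ711238
Graywood (Hwy 8)	GW	-65.426	44.622	14-05-11	ES	A. maculatum	KJ711202
Wolfville	WV	-64.297	45.001	13-05-11	ES	A. maculatum	KJ711236;KJ711237
Hwy#7	H7	-62.055	45.318	21-04-12	ES	A. maculatum	KJ711242;KJ711205;KJ711206
Fairmont	FM	-61.922	45.684	26-04-12	ES	A. maculatum	KJ711199;KJ711200;KJ711201
Snakepit 2	SP2	-63.639	44.872	28-04-12	ES	A. maculatum	KJ711226;KJ711227;KJ711246;KJ711247
Trafalgar	TF	-62.566	45.121	29-04-12	ES	A. maculatum	KJ711233;KJ711234;KJ711235
Queensville	QV	-61.366	45.734	29-04-12	ES	A. maculatum	KJ711215;KJ711216;KJ711217;KJ711218;KJ711219
Rocky Mountain	RM	-62.253	45.394	02-05-12	ES	A. maculatum	KJ711220;KJ711221;KJ711222
Mira River	MR	-60.015	46.017	05-05-12	ES	A. maculatum	KJ711207;KJ711208;KJ711209
Oxford	O	-63.886	45.707	11-05-12	ES	A. maculatum	KJ711210;KJ711211;KJ711243
Point Michaud	PM	-60.668	45.593	22-05-12	ES	A. maculatum	KJ711212;KJ711213;KJ711214
Cape George	CG	-61.941	45.836	28-05-12	ES	A. maculatum	KJ711196;KJ711197
Halifax	Hb_cul	-63.654	44.617	2011	CI	A. maculatum	KJ711137
Halifax	H	-63.666	44.691	2009	ES	A. maculatum	KJ711203;KJ711204;KJ711239;KJ711240;KJ711241
Beaver Bank	BB_cul	-63.680	44.818	2011	CI	A. maculatum	KJ711131;KJ711132;KJ711134;KJ711135;KJ711136;KJ711138
Halifax	R	-63.654	44.617	2011	ES	L. sylvatica	KJ711139;KJ711140;KJ711141;KJ711142;KJ711143;KJ711144;KJ711145;KJ711146;KJ711147
Bamfield	BF	-125.016	48.871	05-05-11	ES	A. gracile	KJ711133;KJ711162;KJ711163;KJ711164;KJ711165;KJ711166;KJ711167;KJ711168;KJ711169;KJ711170;KJ711171;KJ711172;KJ711173
Wood Lake	WL	-125.581	48.991	24-03-12	ES	L. aurora	KJ711223
Swan Lake	SL	-125.595	49.001	21-03-12	ES	L. aurora	KJ711224;KJ711225;KJ711244;KJ711245
Greenbrook Sanctuary	GSa	-73.924	40.914	17-03-12	ES	A. maculatum	KJ711181;KJ711182;KJ711183;KJ711184;KJ711186;KJ711187;KJ711188;KJ711189;KJ711190;KJ711193
Greenbrook Sanctuary	GSb	-73.924	40.914	25-03-12	ES	A. maculatum	KJ711174;KJ711175;KJ711176;KJ711177;KJ711194
Greenbrook Sanctuary	GSc	-73.924	40.914	14-04-12	ES	A. maculatum	KJ711178;KJ711179;KJ711180;KJ711185
Greenbrook Sanctuary	GSa_cul	-73.924	40.914	17-03-12	CI	A. maculatum	KJ711195
Greenbrook Sanctuary	GSb_cul	-73.924	40.914	25-03-12	CI	A. maculatum	KJ711191;KJ711192
Sewanee	TN	-85.910	35.204	02-18-13	ES	A. maculatum	KJ711249;KJ711250;KJ711251;KJ711252;KJ711253;KJ711254;KJ711255;KJ711256
Arcata	CA	-124.082	40.867	03-07-12	ES	A. gracile	KJ711148;KJ711149;KJ711150;KJ711151;KJ711152;KJ711153;KJ711154;KJ711155;KJ711156;KJ711157;KJ711158;KJ711159;KJ711160;KJ711161
C. gloeophila	SAG 12-4	-86.568	39.143	1953	CI	A. maculatum	KJ711128
C. gloeophila	SAG 12-5	-76.475	42.447	1953	CI	A. maculatum	KJ711129
C. gloeophila	CCAP 11/127	-2.935	54.381	1992	CI	Free-living	KJ711130
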