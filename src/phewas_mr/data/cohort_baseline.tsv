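characteristic	level	total	exposed	unexposed
age_group	<55	125241	16489	108752
age_group	55-64	153097	17695	135402
age_group	>=65	68014	5779	62235
sex	male	161621	11585	156353
sex	female	184731	28378	150036
townsend_quintile	1	86491	10163	76328
townsend_quintile	2	86488	9800	76688
townsend_quintile	3	86477	9979	76498
townsend_quintile	4	86476	9967	76509
townsend_quintile	unknown	420	54	366
bmi_group	normal	113826	15072	98754
bmi_group	overweight	147662	15492	132170
bmi_group	obese	83765	9282	74483
bmi_group	unknown	1099	117	982
smoking	never	188601	22398	166203
smoking	previous	121858	14098	107760
smoking	current	34709	3374	31335
smoking	unknown	1184	93	1091
alcohol	never	10517	1286	9231
alcohol	previous	11844	1664	10180
alcohol	current	323685	36985	286700
alcohol	unknown	306	28	278
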