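variant	dg_P	dg_T	reported_ddg	kd_variant	kd_nM	kd_sd_nM
WTDbh	-2251.8	-3465.7		WTDbh	54.8	3.8
Sdbh				Sdbh	51.2	2.4
KSKIP(241-245)RVRKS	-2579.5	-3670.2	-532.2	SdbhKSKIP(241-245)RVRKS	34.8	1.2
M76I	-2414.7	-3682.8	-380	SdbhM76I	42.8	3.1
L250V	-2422.1	-3603.7	-318.3	SdbhL250V	50.4	3.4
T37F	-2313.6	-3562.9	-159	SdbhT37F	49.7	3.1
A221S	-2344.03	-3473.91	-100.45	SdbhA221S	47.5	3.0
I62V	-2145.6	-3632.2	-60.3	SdbhI62V	49.8	2.6
K337R	-2554.6	-3120.5	42.4	SdbhK337R	55.5	4.1
Y249I	-2305.0	-3118.9	293.6	SdbhY249I	56.2	3.4
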