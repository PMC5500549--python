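variant	template_base	dntp	km_uM	km_sd	vmax_nM_min	vmax_sd	reported_eff
Dbh	G	dCTP	88.2	12.0	1.0	0.1	11
Dbh	G	dATP	215.2	18.7	0.019	0.001	0.088
Dbh	8-oxoG	dCTP	67.7	6.3	0.5	0.02	7.4
Dbh	8-oxoG	dATP	139.8	3.1	0.18	0.002	1.3
Sdbh	G	dCTP	75.2	12.0	1.4	0.1	19
Sdbh	G	dATP	128.4	26.3	0.04	0.003	0.31
Sdbh	8-oxoG	dCTP	59.6	11.1	0.61	0.07	10
Sdbh	8-oxoG	dATP	114.9	27.8	0.23	0.009	2.0
SdbhM76I	G	dCTP	54.9	8.6	1.9	0.2	35
SdbhM76I	G	dATP	76.7	7.1	0.08	0.01	0.10
SdbhM76I	8-oxoG	dCTP	55.5	4.9	1.0	0.05	18
SdbhM76I	8-oxoG	dATP	69.1	9.3	0.4	0.05	5.8
SdbhKSKIP(241-245)RVRKS	G	dCTP	40.1	5.2	2.3	0.1	57
SdbhKSKIP(241-245)RVRKS	G	dATP	71.7	9.6	0.16	0.02	0.22
SdbhKSKIP(241-245)RVRKS	8-oxoG	dCTP	33.5	2.7	1.0	0.04	30
SdbhKSKIP(241-245)RVRKS	8-oxoG	dATP	55.1	2.9	0.5	0.04	9.1
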