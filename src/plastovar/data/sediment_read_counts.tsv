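taxon	method	sample	assembled	assembled_with_dup	unassembled	unassembled_with_dup	total	breadth_pct	relative_pct
Alnus	capture	60 cal yr BP	32	1421	1	5	33	2.60	0.74
Alnus	capture	1900 cal yr BP	409	43751	41	1053	450	21.20	7.11
Alnus	capture	5400 cal yr BP	953	46091	53	660	1006	28.50	43.08
Alnus	capture	6700 cal yr BP	1008	43919	64	623	1072	29.10	47.16
Alnus	shotgun	60 cal yr BP	16	22	0	0	16	1.20	0.26
Alnus	shotgun	1900 cal yr BP	609	721	18	20	627	31.20	7.35
Alnus	shotgun	5400 cal yr BP	763	808	9	11	772	33.50	41.20
Alnus	shotgun	6700 cal yr BP	578	617	9	10	587	29.50	50.60
Betula	capture	60 cal yr BP	137	18703	15	449	152	8.90	3.43
Betula	capture	1900 cal yr BP	259	26067	29	985	288	15.20	4.55
Betula	capture	5400 cal yr BP	33	1593	3	80	36	2.20	1.54
Betula	capture	6700 cal yr BP	35	1189	2	7	37	2.80	1.63
Betula	shotgun	60 cal yr BP	281	347	5	5	286	17.70	4.68
Betula	shotgun	1900 cal yr BP	412	483	13	13	425	23.60	4.98
Betula	shotgun	5400 cal yr BP	27	29	0	0	27	1.70	1.44
Betula	shotgun	6700 cal yr BP	18	19	0	0	18	1.30	1.55
Salix	capture	60 cal yr BP	3783	523884	463	10789	4246	51.70	95.82
Salix	capture	1900 cal yr BP	5024	564634	571	11785	5595	55.70	88.35
Salix	capture	5400 cal yr BP	1227	57425	66	576	1293	33.30	55.37
Salix	capture	6700 cal yr BP	1082	41608	82	898	1164	32.40	51.21
Salix	shotgun	60 cal yr BP	5647	6970	161	184	5808	75.70	95.06
Salix	shotgun	1900 cal yr BP	7289	8740	185	207	7474	77.80	87.66
Salix	shotgun	5400 cal yr BP	1060	1117	15	16	1075	43.40	57.36
Salix	shotgun	6700 cal yr BP	545	574	10	11	555	30.30	47.84
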