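# Default donor-group markers: marker_name<TAB>subgroup<TAB>flags
# flags: cpr | giant_virus | -
Amoebozoa	Amoebozoa	-
Parcubacteria	Parcubacteria	cpr
Microgenomates	Microgenomates	cpr
Peregrinibacteria	Peregrinibacteria	cpr
Doudnabacteria	Doudnabacteria	cpr
CPR2	CPR2	cpr
Klosneuvirinae	Klosneuvirinae	giant_virus
Bodo saltans virus	Klosneuvirinae	giant_virus
Klosneuvirus KNV1	Klosneuvirinae	giant_virus
Catovirus CTV1	Klosneuvirinae	giant_virus
Hokovirus HKV1	Klosneuvirinae	giant_virus
Indivirus ILV1	Klosneuvirinae	giant_virus
Tupanvirus	Tupanvirus	giant_virus
Orpheovirus	Orpheovirus	giant_virus
Faustovirus	Faustovirus	giant_virus
Kaumoebavirus	Kaumoebavirus	giant_virus
Cedratvirus	Cedratvirus	giant_virus
Pandoravirus	Pandoravirus	giant_virus
Phycodnaviridae	Phycodnaviridae	giant_virus
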