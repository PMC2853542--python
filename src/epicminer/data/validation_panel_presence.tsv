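taxon	1777E4	4174E20	8680E2	8680E3	14867E1	19231E4	25073E1	36298E1	40245E5	55305E1	55378E1	59107E2
Thryssa_hamiltonii	0	1	1	1	1	1	1	0	1	1	0	0
Danio_rerio	1	1	1	1	1	1	1	1	1	1	1	1
Hypophthalmichthys_molitrix	1	1	0	1	1	1	1	1	0	1	1	1
Hypophthalmichthys_nobilis	1	1	0	1	1	1	1	1	0	1	1	1
Larimichthys_crocea	1	1	1	1	1	1	1	1	1	1	1	1
Siniperca_chuatsi	1	1	0	1	1	0	1	1	1	1	1	0
Odontobutis_potamophila	1	1	0	0	1	0	1	1	0	1	1	1
Micropercops_swinhonis	1	1	0	1	0	0	1	1	0	1	1	1
Rhinogobius_giurinus	1	1	1	0	0	0	0	0	0	0	1	1
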