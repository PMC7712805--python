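region,service,beds,ad_share,eur_per_bed_day
khk,Respite Care,67,0.78,44.65
khk,Week Care Centres,9,0.47,45.58
khk,Homes for the Elderly,2019,0.17,39.77
khk,Special Regime Homes,447,0.90,44.73
khk,Health Care Facilities,34,0.47,23.77
vys,Respite Care,39,0.78,71.15
vys,Week Care Centres,0,0.47,76.92
vys,Homes for the Elderly,1977,0.20,51.92
vys,Special Regime Homes,812,0.80,53.85
vys,Health Care Facilities,57,0.47,33.08
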