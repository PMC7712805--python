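region,year,medical_meur,nonmedical_meur,total_meur
khk,2020,4.289,21.347,25.636
khk,2030,6.866,33.422,40.288
khk,2040,8.589,42.795,51.384
khk,2050,9.592,47.671,57.263
khk,2060,10.695,53.730,64.425
khk,2070,11.245,57.773,69.018
vys,2020,3.977,34.508,38.484
vys,2030,6.441,54.593,61.034
vys,2040,8.229,70.358,78.587
vys,2050,9.490,81.184,90.674
vys,2060,10.683,91.342,102.025
vys,2070,11.184,96.799,107.983
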