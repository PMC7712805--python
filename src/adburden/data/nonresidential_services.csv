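region,service,fte,ad_share,eur_per_fte_month
khk,Personal Assistance,82,0.50,1605.96
khk,Day Services Centres,8,0.50,2184.31
khk,Daycare Centres,31,0.50,1681.62
khk,Domiciliary Service,412,0.50,1804.54
khk,Respite Care,0,0.78,0.00
vys,Personal Assistance,83,0.50,1961.54
vys,Day Services Centres,23,0.50,2153.85
vys,Daycare Centres,117,0.50,2153.85
vys,Domiciliary Service,405,0.50,1961.54
vys,Respite Care,25,0.78,2346.15
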