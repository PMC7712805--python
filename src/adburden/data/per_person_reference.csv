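region,stage,medical_eur_pp,nonmedical_eur_pp,total_eur_pp
khk,mild,359,2330,2689
khk,moderate,298,2330,2628
khk,severe,1624,2330,3954
khk,all,482,2330,2812
vys,mild,354,4229,4583
vys,moderate,389,4229,4618
vys,severe,1671,4229,5900
vys,all,504,4229,4733
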