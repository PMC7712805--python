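region,stage,age_band,category,eur_per_treated_year
khk,mild,65-69,outpatient_points,435.77
khk,mild,65-69,outpatient_other,31.77
khk,mild,65-69,medicines,72.00
khk,mild,65-69,inpatient_points,0.00
khk,mild,65-69,acute_care,243.42
khk,mild,65-69,other_care,442.54
khk,mild,70-79,outpatient_points,268.15
khk,mild,70-79,outpatient_other,34.35
khk,mild,70-79,medicines,22.35
khk,mild,70-79,inpatient_points,0.00
khk,mild,70-79,acute_care,236.88
khk,mild,70-79,other_care,489.04
khk,mild,80-89,outpatient_points,187.77
khk,mild,80-89,outpatient_other,15.23
khk,mild,80-89,medicines,33.35
khk,mild,80-89,inpatient_points,0.00
khk,mild,80-89,acute_care,264.69
khk,mild,80-89,other_care,574.23
khk,mild,90+,outpatient_points,164.85
khk,mild,90+,outpatient_other,6.27
khk,mild,90+,medicines,3.35
khk,mild,90+,inpatient_points,0.00
khk,mild,90+,acute_care,263.15
khk,mild,90+,other_care,976.08
khk,moderate,65-69,outpatient_points,227.35
khk,moderate,65-69,outpatient_other,23.46
khk,moderate,65-69,medicines,77.27
khk,moderate,65-69,inpatient_points,0.00
khk,moderate,65-69,acute_care,166.77
khk,moderate,65-69,other_care,557.00
khk,moderate,70-79,outpatient_points,212.31
khk,moderate,70-79,outpatient_other,24.12
khk,moderate,70-79,medicines,9.46
khk,moderate,70-79,inpatient_points,0.00
khk,moderate,70-79,acute_care,291.65
khk,moderate,70-79,other_care,772.62
khk,moderate,80-89,outpatient_points,182.96
khk,moderate,80-89,outpatient_other,13.08
khk,moderate,80-89,medicines,50.15
khk,moderate,80-89,inpatient_points,0.15
khk,moderate,80-89,acute_care,242.38
khk,moderate,80-89,other_care,506.92
khk,moderate,90+,outpatient_points,154.69
khk,moderate,90+,outpatient_other,10.19
khk,moderate,90+,medicines,5.54
khk,moderate,90+,inpatient_points,0.00
khk,moderate,90+,acute_care,125.00
khk,moderate,90+,other_care,0.00
khk,severe,65-69,outpatient_points,188.42
khk,severe,65-69,outpatient_other,52.58
khk,severe,65-69,medicines,25.58
khk,severe,65-69,inpatient_points,0.00
khk,severe,65-69,acute_care,170.04
khk,severe,65-69,other_care,356.77
khk,severe,70-79,outpatient_points,213.77
khk,severe,70-79,outpatient_other,21.85
khk,severe,70-79,medicines,294.54
khk,severe,70-79,inpatient_points,0.00
khk,severe,70-79,acute_care,307.88
khk,severe,70-79,other_care,685.92
khk,severe,80-89,outpatient_points,161.15
khk,severe,80-89,outpatient_other,11.81
khk,severe,80-89,medicines,9.00
khk,severe,80-89,inpatient_points,0.00
khk,severe,80-89,acute_care,298.85
khk,severe,80-89,other_care,715.96
khk,severe,90+,outpatient_points,120.42
khk,severe,90+,outpatient_other,8.35
khk,severe,90+,medicines,7.65
khk,severe,90+,inpatient_points,0.00
khk,severe,90+,acute_care,224.54
khk,severe,90+,other_care,891.38
vys,mild,65-69,outpatient_points,244.69
vys,mild,65-69,outpatient_other,30.85
vys,mild,65-69,medicines,454.62
vys,mild,65-69,inpatient_points,0.00
vys,mild,65-69,acute_care,316.85
vys,mild,65-69,other_care,586.85
vys,mild,70-79,outpatient_points,232.23
vys,mild,70-79,outpatient_other,19.54
vys,mild,70-79,medicines,75.58
vys,mild,70-79,inpatient_points,0.00
vys,mild,70-79,acute_care,194.00
vys,mild,70-79,other_care,453.85
vys,mild,80-89,outpatient_points,251.15
vys,mild,80-89,outpatient_other,12.00
vys,mild,80-89,medicines,14.19
vys,mild,80-89,inpatient_points,0.00
vys,mild,80-89,acute_care,260.92
vys,mild,80-89,other_care,711.69
vys,mild,90+,outpatient_points,157.42
vys,mild,90+,outpatient_other,6.54
vys,mild,90+,medicines,7.08
vys,mild,90+,inpatient_points,0.00
vys,mild,90+,acute_care,308.73
vys,mild,90+,other_care,668.38
vys,moderate,65-69,outpatient_points,194.35
vys,moderate,65-69,outpatient_other,24.38
vys,moderate,65-69,medicines,1.85
vys,moderate,65-69,inpatient_points,0.00
vys,moderate,65-69,acute_care,107.42
vys,moderate,65-69,other_care,761.92
vys,moderate,70-79,outpatient_points,202.00
vys,moderate,70-79,outpatient_other,19.12
vys,moderate,70-79,medicines,5.92
vys,moderate,70-79,inpatient_points,0.00
vys,moderate,70-79,acute_care,167.58
vys,moderate,70-79,other_care,708.12
vys,moderate,80-89,outpatient_points,201.35
vys,moderate,80-89,outpatient_other,8.65
vys,moderate,80-89,medicines,3.92
vys,moderate,80-89,inpatient_points,0.00
vys,moderate,80-89,acute_care,193.62
vys,moderate,80-89,other_care,722.12
vys,moderate,90+,outpatient_points,187.04
vys,moderate,90+,outpatient_other,13.50
vys,moderate,90+,medicines,4.54
vys,moderate,90+,inpatient_points,0.00
vys,moderate,90+,acute_care,263.73
vys,moderate,90+,other_care,868.12
vys,severe,65-69,outpatient_points,185.35
vys,severe,65-69,outpatient_other,25.23
vys,severe,65-69,medicines,2.73
vys,severe,65-69,inpatient_points,0.00
vys,severe,65-69,acute_care,187.19
vys,severe,65-69,other_care,647.42
vys,severe,70-79,outpatient_points,210.12
vys,severe,70-79,outpatient_other,18.42
vys,severe,70-79,medicines,41.81
vys,severe,70-79,inpatient_points,0.00
vys,severe,70-79,acute_care,215.08
vys,severe,70-79,other_care,531.62
vys,severe,80-89,outpatient_points,261.31
vys,severe,80-89,outpatient_other,9.08
vys,severe,80-89,medicines,12.58
vys,severe,80-89,inpatient_points,0.00
vys,severe,80-89,acute_care,257.73
vys,severe,80-89,other_care,832.12
vys,severe,90+,outpatient_points,157.92
vys,severe,90+,outpatient_other,3.23
vys,severe,90+,medicines,19.58
vys,severe,90+,inpatient_points,0.00
vys,severe,90+,acute_care,276.35
vys,severe,90+,other_care,987.19
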