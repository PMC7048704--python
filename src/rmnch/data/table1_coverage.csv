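indicator,year,stratum_type,stratum,coverage
cci,2001,overall,overall,46
cci,2006,overall,overall,56
cci,2011,overall,overall,63
cci,2016,overall,overall,75
cpr_modern,2001,overall,overall,35
cpr_modern,2006,overall,overall,44
cpr_modern,2011,overall,overall,43
cpr_modern,2016,overall,overall,43
unmet_need,2001,overall,overall,28
unmet_need,2006,overall,overall,25
unmet_need,2011,overall,overall,28
unmet_need,2016,overall,overall,24
fp_need_satisfied,2001,overall,overall,56
fp_need_satisfied,2006,overall,overall,64
fp_need_satisfied,2011,overall,overall,61
fp_need_satisfied,2016,overall,overall,64
sba,2001,overall,overall,12
sba,2006,overall,overall,20
sba,2011,overall,overall,41
sba,2016,overall,overall,63
anc_skilled,2001,overall,overall,28
anc_skilled,2006,overall,overall,44
anc_skilled,2011,overall,overall,59
anc_skilled,2016,overall,overall,86
dpt3,2001,overall,overall,72
dpt3,2006,overall,overall,89
dpt3,2011,overall,overall,92
dpt3,2016,overall,overall,86
msl,2001,overall,overall,71
msl,2006,overall,overall,85
msl,2011,overall,overall,88
msl,2016,overall,overall,90
td2plus,2001,overall,overall,46
td2plus,2006,overall,overall,64
td2plus,2011,overall,overall,69
td2plus,2016,overall,overall,65
bcg,2001,overall,overall,85
bcg,2006,overall,overall,93
bcg,2011,overall,overall,97
bcg,2016,overall,overall,98
all_basic,2001,overall,overall,66
all_basic,2006,overall,overall,83
all_basic,2011,overall,overall,87
all_basic,2016,overall,overall,78
ort,2001,overall,overall,42.6
ort,2006,overall,overall,36.8
ort,2011,overall,overall,46.7
ort,2016,overall,overall,61.4
cpnm,2001,overall,overall,26.1
cpnm,2006,overall,overall,42.9
cpnm,2011,overall,overall,49.5
cpnm,2016,overall,overall,84.9
vitamin_a,2001,overall,overall,
vitamin_a,2006,overall,overall,88
vitamin_a,2011,overall,overall,87
vitamin_a,2016,overall,overall,83
improved_water,2001,overall,overall,85
improved_water,2006,overall,overall,85
improved_water,2011,overall,overall,92
improved_water,2016,overall,overall,95
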