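indicator,year,stratum_type,stratum,coverage
cci,2016,residence,urban,77.9
cci,2016,residence,rural,72.5
cpr_modern,2016,residence,urban,44.2
cpr_modern,2016,residence,rural,40.6
unmet_need,2016,residence,urban,22.7
unmet_need,2016,residence,rural,25.3
fp_need_satisfied,2016,residence,urban,66.1
fp_need_satisfied,2016,residence,rural,61.6
anc_skilled,2016,residence,urban,87.7
anc_skilled,2016,residence,rural,83.0
td2plus,2016,residence,urban,67.3
td2plus,2016,residence,rural,63.2
sba,2016,residence,urban,71.4
sba,2016,residence,rural,52.8
bcg,2016,residence,urban,98.1
bcg,2016,residence,rural,96.8
dpt3,2016,residence,urban,85.6
dpt3,2016,residence,rural,86.3
msl,2016,residence,urban,91.2
msl,2016,residence,rural,89.5
all_basic,2016,residence,urban,78.5
all_basic,2016,residence,rural,77.0
vitamin_a,2016,residence,urban,82.1
vitamin_a,2016,residence,rural,83.0
ort,2016,residence,urban,61.8
ort,2016,residence,rural,60.8
cpnm,2016,residence,urban,89.7
cpnm,2016,residence,rural,80.7
improved_water,2016,residence,urban,93.7
improved_water,2016,residence,rural,96.1
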