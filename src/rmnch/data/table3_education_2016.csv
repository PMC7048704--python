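indicator,year,stratum_type,stratum,coverage
cci,2016,education,educated,77.2
cci,2016,education,no_education,73.2
cpr_modern,2016,education,educated,34.1
cpr_modern,2016,education,no_education,48.8
unmet_need,2016,education,educated,28.2
unmet_need,2016,education,no_education,20.6
fp_need_satisfied,2016,education,educated,54.7
fp_need_satisfied,2016,education,no_education,70.3
anc_skilled,2016,education,educated,90.2
anc_skilled,2016,education,no_education,80.8
td2plus,2016,education,educated,73
td2plus,2016,education,no_education,57.8
sba,2016,education,educated,78
sba,2016,education,no_education,47.8
bcg,2016,education,educated,98.6
bcg,2016,education,no_education,96.4
dpt3,2016,education,educated,90
dpt3,2016,education,no_education,82.2
msl,2016,education,educated,94.3
msl,2016,education,no_education,86.8
all_basic,2016,education,educated,85.1
all_basic,2016,education,no_education,71
vitamin_a,2016,education,educated,84.2
vitamin_a,2016,education,no_education,81.2
ort,2016,education,educated,70.6
ort,2016,education,no_education,55.3
cpnm,2016,education,educated,82.5
cpnm,2016,education,no_education,87
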