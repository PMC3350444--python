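key,value
total_cases,2427
all_cause_admissions,626770
male,1610
under_5_years,2244
infants,872
enema_success,2255
surgical,175
resection,52
secondary,76
complications,27
deaths,2
readmission_episodes,37
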