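age_bin,lower_years,upper_years,all_cause_admissions,intussusceptions,secondary_cases
0,0,0,157494,872,14
1,1,1,88125,657,8
2,2,2,51900,415,12
3-4,3,4,74689,300,7
5-12,5,12,157099,148,22
13-18,13,18,97463,35,13
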