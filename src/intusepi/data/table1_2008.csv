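stratum,national_beds,db_beds,cases_half_year
1,566658,119853,97
2,175715,89627,169
3,88870,49740,78
4,78995,50245,71
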