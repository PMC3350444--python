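stratum,national_beds,db_beds,cases_half_year
1,566658,138979,86
2,175715,98050,176
3,88870,54351,98
4,78995,50245,97
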