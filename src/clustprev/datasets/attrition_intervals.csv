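handling,attrition,structure,estimate,lcb,ucb
complete_case,0.0,none,9.40,8.60,10.20
complete_case,0.0,three_level,9.15,7.11,11.20
complete_case,0.0,household_site,9.63,7.68,11.58
complete_case,0.1,none,8.40,7.64,9.16
complete_case,0.1,three_level,8.35,6.01,10.69
complete_case,0.2,three_level,7.67,4.18,11.16
sknn_imputed,0.1,none,9.58,8.77,10.38
sknn_imputed,0.1,three_level,9.10,7.10,11.10
sknn_imputed,0.2,three_level,9.07,7.11,11.04
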