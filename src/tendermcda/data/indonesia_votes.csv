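round_purpose,option_value,vote_count
price_weight,40%,1
price_weight,45%,5
price_weight,50%,8
price_weight,55%,1
price_weight,60%,1
price_cutoff,25%,5
price_cutoff,50%,8
price_cutoff,75%,3
exclusion_vote_1,macroeconomic-benefit,12
exclusion_vote_1,none,4
exclusion_vote_2,added-value-services,11
exclusion_vote_2,none,5
smart_round_1,quality-assurance,9
smart_round_1,equivalence,4
smart_round_1,supply-reliability,3
smart_round_2,equivalence,8
smart_round_2,stability-formulation,6
smart_round_2,supply-reliability,2
smart_round_3,stability-formulation,10
smart_round_3,supply-reliability,4
smart_round_3,real-world-outcomes,2
smart_round_4,supply-reliability,11
smart_round_4,real-world-outcomes,5
smart_round_5,real-world-outcomes,9
smart_round_5,pharmacovigilance,7
swing_step_1,10%,3
swing_step_1,15%,10
swing_step_1,20%,3
swing_step_2,90%,1
swing_step_2,100%,14
swing_step_3,45%,4
swing_step_3,50%,9
swing_step_3,60%,3
swing_step_4,0%,16
swing_step_5,45%,2
swing_step_5,50%,12
swing_step_5,60%,1
price_weight_adjustment,35%,1
price_weight_adjustment,40%,7
price_weight_adjustment,45%,7
price_cutoff_adjustment,75%,3
price_cutoff_adjustment,100%,9
price_cutoff_adjustment,125%,3
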