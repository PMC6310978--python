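product_id,price,equivalence,real-world-outcomes,stability-formulation,quality-assurance,macroeconomic-benefit,supply-reliability,pharmacovigilance,added-value-services
test-case-1,2200,interchangeability-local,no-rwd,non-inferior-local,non-gmp-api,significant-investment,minor-frequent-problems,no-system,no-service
test-case-2,2900,bioequivalence-local,local-rwd-equal,improved-expiry,non-gmp-process,minor-investment,no-problems,qualified-person-system,major-service-outcomes
test-case-3,3000,bioequivalence-local,local-rwd-equal,improved-expiry,non-gmp-process,minor-investment,no-problems,qualified-person-system,major-service-outcomes
test-case-4,3800,bioequivalence-ema-fda,international-rwd-equal,improved-stability-local,who-gmp,moderate-investment,single-problem,qualified-person,value-added-service
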