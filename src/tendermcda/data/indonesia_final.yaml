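# Final elicited 6+1 criteria framework for the Indonesian off-patent
# pharmaceutical tender pilot. Weights are stored at full precision and come
# from the swing-weighting ladder (base 10; increments +15%, +100%, +50%,
# +0%, +50% from least to most important), normalized and combined with the
# adjusted price weight of 40%; the price cut-off excess is +100%. Displayed
# half-up to one decimal percent the weights read
# 40.0 / 18.8 / 12.5 / 12.5 / 8.4 / 4.2 / 3.6.
schema_version: 1
name: indonesia-opp-tender
version: final
notes: >-
  Elicited framework: 6 non-price criteria plus acquisition price; the
  macroeconomic-benefit and added-value-services criteria were removed by
  majority vote. Prices in IDR.
price_weight: 0.4
price_cutoff_excess: 1.0
criteria:
  - id: price
    name: Price
    definition: Acquisition cost of the pharmaceutical product compared to the lowest price available.
    is_price: true
    weight: 0.4
    categories: []
  - id: equivalence
    name: Equivalence with the reference (original) product
    definition: Evidence on health outcomes from pharmaceutical-, bioequivalence- and clinical trials.
    is_price: false
    weight: 0.12526475037821483
    categories:
      - {label: no-pe-data, level: 0, score_fraction: 0.0, description: No data on pharmaceutical equivalence, is_exclusion: false}
      - {label: pharmaceutical-equivalence, level: 1, score_fraction: 0.16666666666666666, description: Pharmaceutical equivalence, is_exclusion: false}
      - {label: interchangeability-local, level: 2, score_fraction: 0.3333333333333333, description: Interchangeability defined based on local criteria, is_exclusion: false}
      - {label: bioequivalence-local, level: 3, score_fraction: 0.5, description: Bioequivalence proven based on local criteria, is_exclusion: false}
      - {label: bioequivalence-ema-fda, level: 4, score_fraction: 0.6666666666666666, description: Bioequivalence proven based on European EMA or US FDA criteria, is_exclusion: false}
      - {label: therapeutic-equivalence, level: 5, score_fraction: 0.8333333333333334, description: Therapeutic equivalence proven in clinical trial, is_exclusion: false}
      - {label: improved-efficacy-safety, level: 6, score_fraction: 1.0, description: Improvement in efficacy and/or safety based on clinical trial data, is_exclusion: false}
  - id: real-world-outcomes
    name: Real world clinical or economic outcomes
    definition: Evidence on effectiveness and costs (adherence, tolerability, non-drug costs) from real-world data.
    is_price: false
    weight: 0.041754916792738274
    categories:
      - {label: no-rwd, level: 0, score_fraction: 0.0, description: No real world data on equal tolerability, adherence and persistence, or non-drug cost, is_exclusion: false}
      - {label: international-rwd-equal, level: 1, score_fraction: 0.25, description: International real world data on equal tolerability, adherence or non-drug cost, is_exclusion: false}
      - {label: local-rwd-equal, level: 2, score_fraction: 0.5, description: Local real world data on equal tolerability, adherence or non-drug cost, is_exclusion: false}
      - {label: international-rwd-improved, level: 3, score_fraction: 0.75, description: International real world data on improvement in tolerability, adherence or non-drug cost, is_exclusion: false}
      - {label: local-rwd-improved, level: 4, score_fraction: 1.0, description: Local real world data on improvement in tolerability, adherence or non-drug cost, is_exclusion: false}
  - id: stability-formulation
    name: Product stability and drug formulation
    definition: Evidence on stability and drug formulation.
    is_price: false
    weight: 0.12526475037821483
    categories:
      - {label: no-stability-data, level: 0, score_fraction: 0.0, description: No data on product expiry or stability, is_exclusion: false}
      - {label: non-inferior-local, level: 1, score_fraction: 0.25, description: Data on non-inferior product expiry or stability in local environment, is_exclusion: false}
      - {label: improved-expiry, level: 2, score_fraction: 0.5, description: Data on improved product expiry, is_exclusion: false}
      - {label: improved-stability-local, level: 3, score_fraction: 0.75, description: Data on improved product stability in local environment, is_exclusion: false}
      - {label: improved-expiry-stability, level: 4, score_fraction: 1.0, description: Data on improved product expiry and stability in local environment, is_exclusion: false}
  - id: quality-assurance
    name: Quality assurance
    definition: Evidence on manufacturing quality, product quality and standardisation.
    is_price: false
    weight: 0.18789712556732224
    categories:
      - {label: limited-info, level: 0, score_fraction: 0.0, description: Limited information on quality assurance, is_exclusion: false}
      - {label: non-gmp-api, level: 1, score_fraction: 0.25, description: Local/non GMP quality assurance only for active product ingredient, is_exclusion: false}
      - {label: non-gmp-process, level: 2, score_fraction: 0.5, description: Local/non GMP quality assurance for the entire manufacturing process, is_exclusion: false}
      - {label: who-gmp, level: 3, score_fraction: 0.75, description: WHO GMP certification, is_exclusion: false}
      - {label: eu-pics-gmp, level: 4, score_fraction: 1.0, description: EU or PIC/S GMP certification, is_exclusion: false}
  - id: supply-reliability
    name: Reliability of drug supply
    definition: Stability and reliability of drug supply (history and future guarantee).
    is_price: false
    weight: 0.08350983358547655
    categories:
      - {label: major-problems, level: 0, score_fraction: 0.0, description: Major and multiple supply problems in the last 5 years, is_exclusion: false}
      - {label: minor-frequent-problems, level: 1, score_fraction: 0.25, description: Minor and fairly frequent supply problems in the last 5 years, is_exclusion: false}
      - {label: single-problem, level: 2, score_fraction: 0.5, description: Single precedence of supply problems in the last 5 years, is_exclusion: false}
      - {label: no-problems, level: 3, score_fraction: 0.75, description: No precedence of supply problems in the last 5 years, is_exclusion: false}
      - {label: guaranteed-supply, level: 4, score_fraction: 1.0, description: Manufacturer is financially capable and willing to guarantee supply, is_exclusion: false}
  - id: pharmacovigilance
    name: Pharmacovigilance
    definition: Data collection and assessment on adverse events of pharmaceuticals.
    is_price: false
    weight: 0.036308623298033284
    categories:
      - {label: no-system, level: 0, score_fraction: 0.0, description: No pharmacovigilance system, is_exclusion: false}
      - {label: qualified-person, level: 1, score_fraction: 0.5, description: Qualified person for pharmacovigilance, is_exclusion: false}
      - {label: qualified-person-system, level: 2, score_fraction: 1.0, description: Qualified person and sophisticated system to collect pharmacovigilance data, is_exclusion: false}
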