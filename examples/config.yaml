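# Full configuration schema with the shipped defaults.
# Any subset may be given; omitted keys keep their defaults.

project: covid_watch

cohort:
  condition_keywords:          # lowercase substrings matched against
    - covid                    # conditions, brief title and official title
    - covid-19
    - sars-cov-2
    - sars-cov2
    - 2019-ncov
    - novel coronavirus
  eligible_statuses:           # recruiting, active or ended
    - recruiting
    - active_not_recruiting
    - enrolling_by_invitation
    - completed
    - terminated
  vaccine_title_keyword: vaccine
  focus_country: United States

weights:                       # publication attention score
  type_weight:
    result: 1.0
    protocol: 0.5
    other: 0.25
  us_bonus: 0.5
  update_unit: 0.01            # per record update beyond registration
  update_cap: 0.25
  recency_scale_days: 180
  recency_weight: 0.25
  intervention_weight: 0.1

termination_lexicon:           # lowercase substrings, first category wins
  recruitment: [recruit, enroll, enrol, accrual]
  safety: [safety, adverse, toxicity, harm]
  futility: [futility, lack of efficacy, no efficacy, ineffective, no benefit]
  external_results:
    - other trial
    - other studies
    - results from other
    - another study
    - external evidence
    - landscape
    - no longer needed
    - approval of

synonyms:                      # applied after name normalization
  hcq: hydroxychloroquine
  anti sars cov 2 convalescent plasma: convalescent plasma
  convalescent covid 19 plasma: convalescent plasma

shortlist_min_updates: 2       # updates beyond initial registration
minutes_per_abstract: 2.0      # review-time-saved estimate
top_n_interventions: 10
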