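# Baseline parameter values. Every key shown equals the built-in default,
# so an empty config produces exactly this parameter set.
biology:
  background_mortality_rate: 0.1175   # instantaneous hazard per day
  cycle_length: 2.85                  # days per gonotrophic cycle
  host_search_time: 1.26              # days
  oviposition_search_time: 1.26       # days
  resting_time: 0.32                  # days
  infectious_human_fraction: 0.0428
  nonhuman_host_prob: 0.17
  pre_bite_attack_mortality: 0.05
  post_bite_attack_mortality: 0.05
  malaria_infection_prob: 1.0
  eggs_per_laying: 100.0
  sporogony_cycles: 3                 # whole cycles; derived from 10.78 days
  sporogony_days: 10.78               # documentation only
  max_age_classes: 10
  infectious_at_m_equal_d: false      # true: bites infectious already at m == D
population:
  initial_genotype_fractions: [0.999999999, 1.0e-09, 0.0]   # ss, sr, rr
  dominance: 1                        # 1 resistant allele dominant, 0 recessive
  recruitment_lag: 3                  # periods from egg laying to emergence
  male_fitness_factors: [1.0, 1.0, 1.0]
  n_periods: 2000
interventions: []
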