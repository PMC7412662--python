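# gistcea parameter configuration
# Annual probabilities/utilities, costs in 2017 SGD, model settings.
# For each uncertain parameter: value, <name>_low/_high (deterministic
# sensitivity range) and <name>_dist (PSA family).
p_rec_post_apr: 0.0871
p_rec_post_apr_low: 0.0435
p_rec_post_apr_high: 0.13
p_rec_post_apr_dist: beta
p_local_given_rec: 0.135
p_local_given_rec_low: 0.0675
p_local_given_rec_high: 0.203
p_local_given_rec_dist: uniform
p_prog1_met: 0.37
p_prog1_met_low: 0.296
p_prog1_met_high: 0.444
p_prog1_met_dist: beta
p_prog2_met: 0.811
p_prog2_met_low: 0.649
p_prog2_met_high: 0.973
p_prog2_met_dist: beta
p_prog3_met: 0.708
p_prog3_met_low: 0.566
p_prog3_met_high: 0.85
p_prog3_met_dist: beta
p_death_post_regorafenib: 0.405
p_death_post_regorafenib_low: 0.27
p_death_post_regorafenib_high: 0.41
p_death_post_regorafenib_dist: beta
p_surgical_mortality: 0.005
p_surgical_mortality_low: 0.005
p_surgical_mortality_high: 0.005
p_surgical_mortality_dist: fixed
u_post_apr: 0.83
u_post_apr_low: 0.65
u_post_apr_high: 1.0
u_post_apr_dist: beta
u_ciup: 0.935
u_ciup_low: 0.75
u_ciup_high: 1.0
u_ciup_dist: beta
u_recurrence: 0.748
u_recurrence_low: 0.598
u_recurrence_high: 0.898
u_recurrence_dist: beta
u_met_pd: 0.712
u_met_pd_low: 0.685
u_met_pd_high: 0.739
u_met_pd_dist: beta
c_imatinib400: 37040.0
c_imatinib400_low: 7408.0
c_imatinib400_high: 44448.0
c_imatinib400_dist: gamma
c_sunitinib: 64063.0
c_sunitinib_low: 51250.0
c_sunitinib_high: 76876.0
c_sunitinib_dist: gamma
c_regorafenib: 72001.0
c_regorafenib_low: 57601.0
c_regorafenib_high: 86401.0
c_regorafenib_dist: gamma
c_apr: 38000.0
c_apr_low: 30400.0
c_apr_high: 45600.0
c_apr_dist: gamma
c_salvage: 38000.0
c_salvage_low: 30400.0
c_salvage_high: 45600.0
c_salvage_dist: gamma
c_followup: 3000.0
c_followup_low: 2400.0
c_followup_high: 3600.0
c_followup_dist: gamma
p_prog_ciup: 0.37
p_prog_ciup_low: 0.296
p_prog_ciup_high: 0.444
p_prog_ciup_dist: fixed
p_local_given_prog_ciup: 0.135
p_local_given_prog_ciup_low: 0.0675
p_local_given_prog_ciup_high: 0.203
p_local_given_prog_ciup_dist: fixed
discount_rate: 0.03
wtp: 50000.0
start_age: 60
horizon: 20
cycle_length: 1.0
adjuvant_years_uapr: 2
adjuvant_years_post_salvage: 3
imatinib800_multiplier: 1.0
half_cycle_correction: true
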