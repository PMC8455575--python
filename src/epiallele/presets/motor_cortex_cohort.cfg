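# motor-cortex preset: two-group motor-cortex cohort.
# Controls decline linearly with age (80% at 55, 50% at 85); cases are
# age-flat at 65% from age 45. Ages in years, levels in percent.
n_controls = 11
n_cases = 10
age_range = 45,90
case_age_range = 45,80
control_trend = 135.0,-1.0
als_level = 65.0
biological_noise_sd = 4.0
allele_linkage = 0.6
n_fragments_per_sample = 2000
conversion_failure_rate = 0.005
sequencing_error_rate = 0.001
tissue = motor_cortex
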