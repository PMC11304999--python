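# Serial mouse -> mouse passage of an already mouse-adapted community:
# near-complete retention and weak host reassembly.
s_asvs = 400
donor_sigma = 2.0
retention_alpha = 1.5
retention_beta = 0.9
retention_correlation = 0.9
inflamed_retention_correlation = 0.6
fitness_sigma = 2.5
host_sigma = 0.9
passage_retention = 0.95
passage_fitness_sigma = 0.6
passage_host_sigma = 0.5
passage_influx_rate = 2.0
influx_rate = 4.0
depth_mean = 50000
input_depth_mean = 200000
depth_log_sigma = 0.2
n_input_replicates = 3
n_recipients = 8
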