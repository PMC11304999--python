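# Calibrated constants for the human -> germ-free mouse engraftment scenario:
# strong cross-host bottleneck with host-environment reassembly.
s_asvs = 400
donor_sigma = 2.0
retention_alpha = 1.5
retention_beta = 0.9
retention_correlation = 0.9
inflamed_retention_correlation = 0.6
fitness_sigma = 2.5
host_sigma = 0.9
inflamed_host_sigma = 1.5
pathobiont_boost = 15.0
bloom_sigma = 1.5
protective_suppression = 0.08
influx_rate = 4.0
influx_log10_mu = -3.0
influx_log10_sigma = 0.3
depth_mean = 50000
input_depth_mean = 200000
depth_log_sigma = 0.2
n_input_replicates = 3
n_recipients = 8
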