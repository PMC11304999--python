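# Exchangeable-recipient null: one event, 16 identically distributed
# recipients split into two arbitrary 8-mouse groups (type-I-error checks).
s_asvs = 400
donor_sigma = 2.0
retention_alpha = 1.5
retention_beta = 0.9
retention_correlation = 0.9
inflamed_retention_correlation = 0.6
fitness_sigma = 2.5
host_sigma = 0.9
influx_rate = 4.0
depth_mean = 50000
input_depth_mean = 200000
n_recipients = 16
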