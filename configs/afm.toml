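# Synthetic AFM recovery study configuration.
# Acquisition emulates the stomatal mapping protocol (45 N/m lever,
# 1000 nN setpoint, 128 x 128 points); study maps are 30-um zooms centered
# on one stoma so the 1-um wall-pair separation is resolved.

[afm]
spring_constant = 45.0      # N/m
sensitivity = 20.0          # nm/V
tip_half_angle_deg = 17.5
setpoint_nN = 1000.0
poisson = 0.5
map_size_um = 30.0
grid = 128

[noise]
deflection_noise_nN = 10.0  # 1% of setpoint
contact_jitter_nm = 5.0
tilt_slope_nN_per_nm = 0.01
offset_nN = 20.0
modulus_jitter_rel = 0.05

[study]
n_mature = 14
n_young = 18
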