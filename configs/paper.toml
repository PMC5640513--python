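# Shipped default simulation configuration.
# Geometry dimensions are calibration stand-ins for a large broad-bean-type
# stomatal complex; wall thicknesses (1.0 / 0.3 um) are the literature-
# anchored values. Material constants are the frozen calibration set (see
# docs/methods.md): chosen so the baseline aperture-pressure curve opens
# near 1.3 MPa and saturates only above 5 MPa, then left alone.

[geometry]
complex_length = 45.0   # um
complex_width = 30.0    # um
pore_length0 = 18.0     # um
pore_width0 = 4.0       # um
cross_section_kind = "circular"
t_wall = 1.0            # um
t_pole = 0.3            # um
m_v = 1.0
mesh_resolution = 3000  # elements per guard cell for analysis runs
z_flatten = 1.0

[material]
c1 = 1.0        # MPa
c2 = 3.0
c3 = 0.5        # MPa
c4 = 5.0
c5 = 50.0       # MPa
lam_star = 1.05

[protocol]
p_epi_max = 0.5  # MPa
p_gc_max = 6.0   # MPa
n_steps = 60
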