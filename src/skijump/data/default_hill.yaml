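# HS106-like hill (K-point 95 m). All lengths in metres, angles in degrees.
# The in-run edge is the local origin; the landing profile is given as
# (x, y, dy/dx) knots of a C1 piecewise-cubic hill shape.
hill:
  inrun_straight_angle_deg: 35.0
  transition_radius_m: 90.0
  table_angle_deg: 11.0
  table_length_m: 6.5
  inrun_total_arc_length_m: 90.0
  k_point_distance_m: 95.0
  gate_ref: 15
  gate_ref_arc_position_m: 4.0
  gate_spacing_m: 0.8
  landing_knots:
    - [0.0,   -1.0,  -0.12]
    - [10.0,  -3.0,  -0.30]
    - [25.0,  -10.0, -0.55]
    - [45.0,  -23.0, -0.70]
    - [65.0,  -37.5, -0.72]
    - [85.0,  -51.0, -0.60]
    - [100.0, -58.5, -0.40]
    - [115.0, -63.5, -0.25]
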