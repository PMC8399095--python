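# Sagittal right-side body-segment parameters.
#
# Mass fractions and centre-of-mass fractions (measured from the proximal
# landmark) follow the Zatsiorsky tables with the De Leva adjustments,
# collapsed onto the landmark set this package tracks: both legs/arms are
# lumped onto the right-side chain, and the foot mass is merged into the
# shank segment (its CoM fraction is shifted distally to compensate).
# Reference segment lengths are for a ~1.78 m athlete and are used for
# image self-calibration; edit per athlete.
#
# Equipment point masses (helmet, boots, skis) are attached to landmarks
# with a fixed sagittal offset; masses are typical jumping equipment.
segment_model:
  body_mass_kg: 65.0
  segments:
    - {name: shank_plus_feet, proximal: knee, distal: ankle,
       mass_fraction: 0.1140, com_fraction: 0.5792, reference_length_m: 0.43}
    - {name: thigh, proximal: hip, distal: knee,
       mass_fraction: 0.2832, com_fraction: 0.4095, reference_length_m: 0.42}
    - {name: trunk, proximal: hip, distal: shoulder,
       mass_fraction: 0.4346, com_fraction: 0.5500, reference_length_m: 0.52}
    - {name: head_neck, proximal: upper_neck, distal: head_top,
       mass_fraction: 0.0694, com_fraction: 0.4000, reference_length_m: 0.22}
    - {name: upper_arm, proximal: shoulder, distal: elbow,
       mass_fraction: 0.0542, com_fraction: 0.5772, reference_length_m: 0.28}
    - {name: forearm_hand, proximal: elbow, distal: wrist,
       mass_fraction: 0.0446, com_fraction: 0.6000, reference_length_m: 0.27}
  equipment:
    - {name: helmet, attachment: head_top, offset_m: [0.0, 0.03], mass_kg: 0.5}
    - {name: boots, attachment: ankle, offset_m: [0.0, -0.08], mass_kg: 2.5}
    - {name: skis, attachment: ankle, offset_m: [0.3, -0.12], mass_kg: 7.0}
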