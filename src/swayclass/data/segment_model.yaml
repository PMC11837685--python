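# Winter-style anthropometric segment table mapped onto Kinect v2 joints.
# mass_fraction: segment mass as a fraction of body mass (sums to 1.0);
# com_fraction: segment-center position along the proximal->distal axis.
# Head, neck and trunk are merged into one axial segment; forearm and hand
# are merged per side.  Which of the 25 tracked joints delimit the
# "relevant body segments" is a package decision (see docs/methods.md).
segments:
  - {name: trunk_head,        proximal: SpineBase,     distal: Head,       mass_fraction: 0.5780, com_fraction: 0.50}
  - {name: upper_arm_left,    proximal: ShoulderLeft,  distal: ElbowLeft,  mass_fraction: 0.0280, com_fraction: 0.436}
  - {name: upper_arm_right,   proximal: ShoulderRight, distal: ElbowRight, mass_fraction: 0.0280, com_fraction: 0.436}
  - {name: forearm_hand_left, proximal: ElbowLeft,     distal: HandLeft,   mass_fraction: 0.0220, com_fraction: 0.682}
  - {name: forearm_hand_right, proximal: ElbowRight,   distal: HandRight,  mass_fraction: 0.0220, com_fraction: 0.682}
  - {name: thigh_left,        proximal: HipLeft,       distal: KneeLeft,   mass_fraction: 0.1000, com_fraction: 0.433}
  - {name: thigh_right,       proximal: HipRight,      distal: KneeRight,  mass_fraction: 0.1000, com_fraction: 0.433}
  - {name: shank_left,        proximal: KneeLeft,      distal: AnkleLeft,  mass_fraction: 0.0465, com_fraction: 0.433}
  - {name: shank_right,       proximal: KneeRight,     distal: AnkleRight, mass_fraction: 0.0465, com_fraction: 0.433}
  - {name: foot_left,         proximal: AnkleLeft,     distal: FootLeft,   mass_fraction: 0.0145, com_fraction: 0.50}
  - {name: foot_right,        proximal: AnkleRight,    distal: FootRight,  mass_fraction: 0.0145, com_fraction: 0.50}
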