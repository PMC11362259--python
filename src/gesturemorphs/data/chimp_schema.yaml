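# Default modifier schema for East African chimpanzee gesture coding:
# four standard modifiers (signaller body part, contact body part,
# rhythmic repetition, laterality), with left/right-handed unimanual
# gestures lumped as Unimanual and actions pre-split on repetition
# lumped back together.
modifiers:
  body_part_signaller: [Arm, Back, Body, Bottom, Face, Fingers, Foot, Hand, Head, Leg, Other]
  body_part_contact: [Arm, Back, Body, Bottom, Face, Genitals, Hand, Head, Leg, None, Other]
  repetition: ["Yes", "No"]
  laterality: [Unimanual, Both, Alternating]
codes:
  unknown: [unknown]
  not_valid: [not_valid, not valid, nv]
  missing: ["", na, nan]
  other: [other]
level_lumps:
  laterality:
    left: Unimanual
    right: Unimanual
    Left: Unimanual
    Right: Unimanual
action_lumps:
  Hitting:
    action: Hit
    induced: {repetition: "Yes"}
  Hit:
    action: Hit
    induced: {repetition: "No"}
communities: []
goals: []
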