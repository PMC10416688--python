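# Rule file for the information-extraction engine.  All patterns are
# Python regexes compiled case-insensitively.  Margin patterns are applied
# in order; a later pattern never re-claims text already matched by an
# earlier one, so put the most specific patterns first.
#
# Named groups used by margin patterns:
#   m1, m2  margin type words (peripheral/lateral/radial/deep); m2 for
#           "peripheral and deep" double mentions
#   dist    numeric clearance distance
#   bound   upper bound of a "less than X mm" mention

margin_patterns:
  - kind: involved
    regex: '(?:extends?(?:ing)?\s+(?:in)?to|involv(?:es|ing)|reach(?:es|ing)|infiltrat(?:es|ing)|transect(?:s|ed)?\s+at|present\s+at|seen\s+at)\s+(?:both\s+)?(?:the\s+)?(?P<m1>peripheral|lateral|radial|deep)(?:\s+and\s+(?:the\s+)?(?P<m2>peripheral|deep))?\s+(?:excision\s+)?margins?'
  - kind: involved
    regex: '(?P<m1>peripheral|lateral|radial|deep)\s+margins?\s+(?:is|are)\s+involved'
  - kind: involved
    regex: 'incomplete(?:ly)?\s+excis\w+\s+at\s+(?:the\s+)?(?P<m1>peripheral|lateral|radial|deep)(?:\s+and\s+(?:the\s+)?(?P<m2>peripheral|deep))?\s+(?:margins?|aspects?)'
  - kind: less_than
    regex: '(?P<m1>peripheral|lateral|radial|deep)?\s*(?:excision\s+)?margins?\s+(?:is\s+|are\s+|of\s+)?(?:clearance\s+)?(?:less\s+than|under|<)\s*(?P<bound>\d+(?:\.\d+)?)\s*(?:mm|millimetres?|millimeters?)'
  - kind: distance
    regex: '(?P<m1>peripheral|lateral|radial|deep)\s+(?:excision\s+)?margins?[^.;]*?(?P<dist>\d+(?:\.\d+)?)\s*(?:mm|millimetres?|millimeters?)'
  - kind: distance
    regex: '(?P<m1>peripheral|lateral|radial|deep)\s*[:=]?\s*(?P<dist>\d+(?:\.\d+)?)\s*(?:mm|millimetres?|millimeters?)'
  - kind: clear
    regex: '(?P<m1>peripheral|lateral|radial|deep)\s+margins?\s+(?:is\s+|are\s+|appears?\s+)?(?:clear|free\s+of\s+tumou?r|uninvolved|not\s+involved)'
  - kind: distance
    regex: '(?:(?:nearest|closest)\s+)?margins?\s+(?:of\s+excision\s+)?[^.;]*?(?P<dist>\d+(?:\.\d+)?)\s*(?:mm|millimetres?|millimeters?)'
  - kind: clear
    regex: 'margins?\s+(?:of\s+excision\s+)?(?:is\s+|are\s+|appears?\s+)?(?:all\s+)?(?:clear|free\s+of\s+tumou?r|uninvolved|not\s+involved)'
  - kind: clear
    regex: 'complete(?:ly)?\s+excis\w+|excision\s+(?:is\s+|appears\s+)?complete\b'
  - kind: involved
    regex: 'margins?\s+(?:is|are)\s+involved|incomplete\s+excision\b|incompletely\s+excised\b'

# hedge cues make a margin mention inexact (searched in the matched clause
# plus a short window before it)
hedge_cues: 'approximately|about|around|roughly|at\s+least|appears?|~'

negation:
  cues: '\bno\b|\bnot\b|\bwithout\b|\babsent\b|no\s+evidence\s+of|negative\s+for|free\s+of'
  clause_splitters: '\bbut\b|\bhowever\b|\balthough\b|;'
  sentence_splitters: '[.;\n]'

diagnosis_triggers:
  - basal cell carcinoma
  - bcc

subtypes:
  micronodular: [micronodular]
  nodular: [nodular, nodulocystic]
  superficial: [superficial]
  infiltrative: [infiltrative, infiltrating]
  morphoeic: [morphoeic, morpheaform, sclerosing]
  basosquamous: [basosquamous]

invasion_triggers:
  perineural_invasion: [perineural invasion, neural invasion, perineural infiltration]
  lymphovascular_invasion: [lymphovascular invasion, lymph-vascular invasion,
                            lymphovascular space invasion, vascular invasion]
recurrence_triggers: [recurrent, recurrence]

size_patterns:
  # lesion size, searched in the macroscopic section; specimen dimensions
  # ("ellipse of skin measuring 15 x 8 mm") deliberately do not match
  - '(?:nodule|tumou?r|lesion|plaque|papule|ulcer)\b[^.;]*?measur\w*\s+(?P<size>\d+(?:\.\d+)?)\s*(?:mm|millimetres?|millimeters?)'
  - '(?P<size>\d+(?:\.\d+)?)\s*(?:mm|millimetres?|millimeters?)\s+(?:in\s+)?(?:maximum\s+)?diameter'

procedure:
  diagnostic: [punch biopsy, incisional biopsy, incision biopsy, shave biopsy,
               curettings, curettage]
  excision: [ellipse, excision, excised, wide local]

sites:
  # surface form -> canonical site token (must exist in risk_rules site_regions)
  nose: nose
  nasal tip: nose
  ala of nose: nose
  upper lip: lip
  lower lip: lip
  lip: lip
  eyelid: eyelid
  medial canthus: periorbital
  periorbital region: periorbital
  periorbital: periorbital
  ear: ear
  helix: ear
  pinna: ear
  chin: chin
  temple: temple
  cheek: cheek
  forehead: forehead
  scalp: scalp
  neck: neck
  back: back
  chest: chest
  abdomen: abdomen
  shoulder: shoulder
  upper arm: arm
  arm: arm
  forearm: forearm
  hand: hand
  thigh: thigh
  lower leg: leg
  shin: leg
  calf: leg
  leg: leg
  foot: foot

specialties:
  plastic surgery: [plastic surgery, plastics, plastic and reconstructive surgery,
                    burns and plastic surgery]
  oral and maxillofacial surgery: [oral and maxillofacial surgery, maxillofacial surgery,
                                   oral surgery, omfs, max fax, maxfax]
  dermatology: [dermatology, derm]
  ear nose and throat surgery: [ear nose and throat surgery, "ear, nose and throat surgery",
                                otolaryngology, ent]
  general practice: [general practice, general practitioner, primary care, gp]
  ophthalmology: [ophthalmology, oculoplastic surgery, ophth]
  general surgery: [general surgery, gen surg]
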