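# Clinicopathological low/high risk stratification for BCC, after the
# BAD adaptation of the NCCN treatment guidelines.  A lesion is HIGH risk
# if any trigger fires:
#   - aggressive growth pattern (subtype below)
#   - perineural or lymphovascular invasion
#   - site in the facial "mask area" (high-risk region, any size)
#   - size at or above the regional threshold
#   - recurrent / previously excised lesion
# This table is an editable reconstruction of the published criteria.
aggressive_subtypes:
  - infiltrative
  - morphoeic
  - micronodular
  - basosquamous
site_regions:
  # mask area of the face: high risk at any size
  nose: mask
  lip: mask
  eyelid: mask
  ear: mask
  chin: mask
  temple: mask
  periorbital: mask
  # cheek/forehead/scalp/neck: high risk at >= 10 mm
  cheek: mid
  forehead: mid
  scalp: mid
  neck: mid
  # trunk and extremities: high risk at >= 20 mm
  back: low
  chest: low
  abdomen: low
  shoulder: low
  arm: low
  forearm: low
  hand: low
  thigh: low
  leg: low
  foot: low
size_thresholds_mm:
  mask: null   # site alone is the trigger
  mid: 10
  low: 20
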