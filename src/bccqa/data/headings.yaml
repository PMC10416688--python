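# Surface forms of the canonical pathology-report subheadings.
# Editable: add local heading variants without touching code.
clinical_details:
  - clinical details
  - clinical history
  - clinical information
  - history
macroscopic:
  - macroscopic description
  - macroscopy
  - gross description
  - specimen description
microscopic:
  - microscopic description
  - microscopy
  - histology
  - histological findings
conclusion:
  - conclusion
  - diagnosis
  - comment
  - summary
  - report
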