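# Section-heading aliases, matched case-insensitively, for both report styles.
# Keys are section kinds; only `findings` and `impression` feed the models.
basic:
  - basic patient information
  - patient information
clinical:
  - clinical information
  - clinical history
  - methods
  - method
  - technique
findings:
  - image findings
  - imaging findings
  - findings
  - finding
impression:
  - impressions
  - impression
  - conclusion
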