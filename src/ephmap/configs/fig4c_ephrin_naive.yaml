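builder: gap_assay
args:
  first_cue: ephrin
  second_cue: ephrin
  gap: 20
  naive: true
  seed: 1
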