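builder: tectal_entry
args:
  n: 200
  deflection: 1.0
  seed: 1
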