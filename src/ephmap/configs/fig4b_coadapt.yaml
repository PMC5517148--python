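builder: mapping
args:
  n: 200
  adaptation_mode: coadaptation
  seed: 1
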