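# Hsieh rule (approximate transcription; NON-CANONICAL, editable).
name: hsieh
assertions:
  - {position: 6, ineffective: [G]}
  - {position: 11, effective: [G]}
  - {position: 13, effective: [U]}
  - {position: 19, effective: [U]}
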