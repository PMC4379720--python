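# Takasaki rule (approximate transcription; NON-CANONICAL, editable).
name: takasaki
assertions:
  - {position: 3, effective: [A]}
  - {position: 13, ineffective: [G]}
  - {position: 19, effective: [A, U]}
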