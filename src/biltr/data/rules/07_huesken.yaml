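# Huesken motif rule (approximate transcription of the reported
# position-specific preferences; NON-CANONICAL, editable).
name: huesken
assertions:
  - {position: 1, effective: [G, C]}
  - {position: 10, effective: [A, U]}
  - {position: 19, effective: [A, U], ineffective: [G, C]}
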