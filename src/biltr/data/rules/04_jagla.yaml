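# Jagla rule (approximate transcription; NON-CANONICAL, editable):
# Ui-Tei-style ends plus A/U effective at position 10.
name: jagla
assertions:
  - {position: 1, effective: [G, C], ineffective: [A, U]}
  - {position: 10, effective: [A, U]}
  - {position: 19, effective: [A, U], ineffective: [G, C]}
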