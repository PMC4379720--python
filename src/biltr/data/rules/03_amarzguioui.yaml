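# Amarzguioui rule (approximate transcription; NON-CANONICAL, editable):
# strong 5' sense end (G/C at 1), A at 6, weak 3' sense end (A/U at 19,
# G disfavoured).
name: amarzguioui
assertions:
  - {position: 1, effective: [G, C]}
  - {position: 6, effective: [A]}
  - {position: 19, effective: [A, U], ineffective: [G]}
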