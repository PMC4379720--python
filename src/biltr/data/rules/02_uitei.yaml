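# Ui-Tei rule (approximate transcription from the primary publication;
# NON-CANONICAL, edit to taste): G/C effective and A/U ineffective at
# position 1; A/U effective and G/C ineffective at position 19.
name: uitei
assertions:
  - {position: 1, effective: [G, C], ineffective: [A, U]}
  - {position: 19, effective: [A, U], ineffective: [G, C]}
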