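# Reynolds rule, positional assertions only (canonical content).
# Effective bases: A at 3, U at 10, A/C/G at 13, A/U at 19.
# Non-positional criteria of the original rule (GC content 30-52%,
# >=3 A/U at 15-19, no internal repeats) are not expressible as
# single-column pairwise constraints and are therefore not compiled.
name: reynolds
assertions:
  - {position: 3, effective: [A]}
  - {position: 10, effective: [U]}
  - {position: 13, effective: [A, C, G]}
  - {position: 19, effective: [A, U]}
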