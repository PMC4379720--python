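"""Encode a short siRNA and transform it with a knockdown-strength matrix.

The column-wise inner product of a 4 x n transformation matrix T with an
n x 4 one-hot encoding X picks, at each position, the strength of the
base that actually occurs there.  Summing alpha R(X) beta over rules and
positions gives the predicted knockdown efficacy.
"""

import numpy as np

from biltr import (
    ModelParams,
    SiRNASequence,
    columnwise_inner_product,
    encode_sequence,
    predict,
)

T = np.array(
    [  # rows A, C, G, U; columns positions 1..5
        [0.5, 0.7, 0.32, 0.2, 0.5],
        [0.3, 0.1, 0.6, 0.6, 0.3],
        [0.1, 0.1, 0.08, 0.1, 0.1],
        [0.1, 0.1, 0.0, 0.1, 0.1],
    ]
)

seq = SiRNASequence("demo", "AUGCU")
X = encode_sequence(seq)
print("one-hot encoding of", seq.bases)
print(X.astype(int))

x = columnwise_inner_product(T, X)
print("transformed vector T o X:", x)
# Each entry is the strength of the observed base at that position:
# A at 1 -> 0.5, U at 2 -> 0.1, G at 3 -> 0.08, C at 4 -> 0.6, U at 5 -> 0.1.

model = ModelParams(matrices=T[None], alpha=[1.0], beta=np.ones(5))
print("prediction alpha R(X) beta with unit weights:", predict(model, X))
# With unit alpha and beta the prediction is just the sum of the
# transformed vector: 0.5 + 0.1 + 0.08 + 0.6 + 0.1 = 1.38.
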