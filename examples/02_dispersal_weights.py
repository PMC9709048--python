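"""Scaled inverse-distance weights from an effective-distance matrix.

Effective distances are measured along plausible ocean-current routes (km).
Each row of the weight matrix P is the normalized reciprocal distance from
one mixed stock to every rookery: closer rookeries get proportionally more
prior weight in the model, and each row sums to 1.
"""

import numpy as np

import mixedstock as ms
from mixedstock.distance import scaled_inverse_distance, uniform_matrix

D = ms.EffectiveDistanceMatrix(
    ("LagoonA", "ReefB"),
    ("North", "Central", "South"),
    np.array([[1000.0, 2000.0, 4000.0],
              [3000.0, 1500.0, 1500.0]]),
)
P = scaled_inverse_distance(D)
print("distances (km):\n", D.D)
print("scaled inverse-distance weights P:\n", np.round(P.P, 4))
print("row sums:", P.P.sum(axis=1))

U = uniform_matrix(D.mixed_stock_labels, D.rookery_labels)
print("\nuniform (matrix-of-ones) fallback:\n", U.P)
print("With uniform P the distance-weighted model reduces to the base model.")
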