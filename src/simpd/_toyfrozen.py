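"""Frozen oracle values for the 12-compound toy fixture.

Computed once during development and verified against independent
brute-force oracles (exhaustive pairwise bit-set Tanimoto arithmetic,
explicit exclusion-sphere centroid iteration, and RDKit's reference Butina
implementation), then frozen; unit tests compare the live code paths
against these values and re-derive them from the oracles at test time.
"""

import numpy as np

# pairwise Tanimoto similarity, radius-2 Morgan/2048 bits, 6 decimals
TANIMOTO_R2 = np.array([
    [1.000000, 0.444444, 0.400000, 0.400000, 0.035714, 0.032258, 0.029412, 0.068966, 0.133333, 0.121212, 0.148148, 0.000000],
    [0.444444, 1.000000, 0.400000, 0.400000, 0.035714, 0.066667, 0.060606, 0.068966, 0.096774, 0.121212, 0.107143, 0.047619],
    [0.400000, 0.400000, 1.000000, 0.363636, 0.000000, 0.096774, 0.057143, 0.031250, 0.090909, 0.181818, 0.100000, 0.000000],
    [0.400000, 0.400000, 0.363636, 1.000000, 0.000000, 0.030303, 0.027778, 0.031250, 0.090909, 0.114286, 0.100000, 0.000000],
    [0.035714, 0.035714, 0.000000, 0.000000, 1.000000, 0.458333, 0.461538, 0.545455, 0.057143, 0.025641, 0.062500, 0.041667],
    [0.032258, 0.066667, 0.096774, 0.030303, 0.458333, 1.000000, 0.576923, 0.275862, 0.025641, 0.102564, 0.027778, 0.076923],
    [0.029412, 0.060606, 0.057143, 0.027778, 0.461538, 0.576923, 1.000000, 0.290323, 0.023810, 0.069767, 0.025641, 0.068966],
    [0.068966, 0.068966, 0.031250, 0.031250, 0.545455, 0.275862, 0.290323, 1.000000, 0.054054, 0.050000, 0.058824, 0.038462],
    [0.133333, 0.096774, 0.090909, 0.090909, 0.057143, 0.025641, 0.023810, 0.054054, 1.000000, 0.551724, 0.392857, 0.000000],
    [0.121212, 0.121212, 0.181818, 0.114286, 0.025641, 0.102564, 0.069767, 0.050000, 0.551724, 1.000000, 0.235294, 0.000000],
    [0.148148, 0.107143, 0.100000, 0.100000, 0.062500, 0.027778, 0.025641, 0.058824, 0.392857, 0.235294, 1.000000, 0.000000],
    [0.000000, 0.047619, 0.000000, 0.000000, 0.041667, 0.076923, 0.068966, 0.038462, 0.000000, 0.000000, 0.000000, 1.000000],
])

# Taylor-Butina partition at similarity threshold 0.35
BUTINA_R2_ASSIGNMENT = [0, 0, 0, 0, 1, 1, 1, 1, 2, 2, 2, 3]
BUTINA_R3_ASSIGNMENT = [1, 1, 3, 4, 0, 0, 0, 0, 2, 2, 5, 6]

# spatial sums of the temporal 80/20 split (test = last 2 compounds)
TEMPORAL_SUM_G = 0.0
TEMPORAL_SUM_FPRIME = 23.5
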