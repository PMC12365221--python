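"""Exhaustive boundary-matrix Rips persistence; oracle for tiny clouds."""

import itertools

import numpy as np
from scipy.spatial.distance import pdist, squareform


def naive_barcode(X, max_dim=2, thresh=None, metric_input=False):
    D = X if metric_input else squareform(pdist(X))
    n = len(D)
    if thresh is None:
        thresh = np.min(np.max(D, axis=1))
    simplices = []
    for d in range(max_dim + 2):
        for vs in itertools.combinations(range(n), d + 1):
            diam = (
                0.0
                if d == 0
                else max(D[a, b] for a, b in itertools.combinations(vs, 2))
            )
            if diam <= thresh:
                simplices.append((diam, d, vs))
    simplices.sort(key=lambda s: (s[0], s[1], s[2]))
    index = {s[2]: i for i, s in enumerate(simplices)}
    m = len(simplices)
    cols = []
    for _, d, vs in simplices:
        col = 0
        if d > 0:
            for f in itertools.combinations(vs, d):
                col ^= 1 << index[f]
        cols.append(col)
    low_of = {}
    pairs = []
    for j in range(m):
        col = cols[j]
        while col:
            low = col.bit_length() - 1
            if low not in low_of:
                break
            col ^= cols[low_of[low]]
        cols[j] = col
        if col:
            low = col.bit_length() - 1
            low_of[low] = j
            pairs.append((low, j))
    paired = set()
    bars = {d: [] for d in range(max_dim + 1)}
    for low, j in pairs:
        paired.add(low)
        paired.add(j)
        b, d_, _ = simplices[low]
        db, _, _ = simplices[j]
        if d_ <= max_dim and db > b:
            bars[d_].append((b, db))
    for i, (diam, d, _) in enumerate(simplices):
        if i not in paired and cols[i] == 0 and d <= max_dim:
            bars[d].append((diam, np.inf))
    return {
        d: np.array(sorted(v)) if v else np.empty((0, 2)) for d, v in bars.items()
    }
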