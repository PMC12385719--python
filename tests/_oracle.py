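"""Independent straight-line oracle for the composite scoring chain.

Deliberately coded with different numerics from the package: SVD of the
standardized matrix instead of an eigendecomposition of the correlation
matrix, explicit loops for membership and weighting. Shares no code
with germeval beyond numpy.
"""

import math

import numpy as np


def composite_oracle(values, desirability=None, threshold=1.0, proportion=0.05):
    """Returns (F, eigenvalues, retained indices, weights, elite count)."""
    X = np.asarray(values, dtype=float)
    n, p = X.shape
    means = X.sum(axis=0) / n
    sds = np.sqrt(((X - means) ** 2).sum(axis=0) / (n - 1))
    Z = (X - means) / sds

    _, S, Vt = np.linalg.svd(Z, full_matrices=False)
    lam = (S**2) / (n - 1)
    load = Vt.T  # columns are components, singular values descending
    if load.shape[1] < p:  # rank-deficient: pad with zero components
        pad = p - load.shape[1]
        load = np.hstack([load, np.zeros((p, pad))])
        lam = np.concatenate([lam, np.zeros(pad)])

    for j in range(p):
        col = load[:, j]
        s = 0.0 if desirability is None else float(np.dot(desirability, col))
        if s < -1e-9:
            load[:, j] = -col
        elif abs(s) <= 1e-9:
            i = int(np.argmax(np.abs(col)))
            if col[i] < 0:
                load[:, j] = -col

    scores = Z @ load
    retained = [j for j in range(p) if lam[j] > threshold]
    w = np.array([lam[j] for j in retained])
    w = w / w.sum()
    F = np.zeros(n)
    for k, j in enumerate(retained):
        x = scores[:, j]
        u = (x - x.min()) / (x.max() - x.min())
        F = F + w[k] * u
    k_elite = math.ceil(proportion * n)
    return F, lam, retained, w, k_elite
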