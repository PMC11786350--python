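"""Independent plain multiplicative-update NMF, used as an oracle.

Deliberately minimal and separate from the package: the classic
Frobenius-norm updates of Lee & Seung with a small denominator guard,
W first, then H with the updated W.
"""

import numpy as np


def plain_nmf_run(X, W0, H0, n_iter, eps=1e-12):
    W, H = W0.copy(), H0.copy()
    iterates = []
    for _ in range(n_iter):
        W = W * (X @ H) / (W @ (H.T @ H) + eps)
        H = H * (X.T @ W) / (H @ (W.T @ W) + eps)
        iterates.append((W.copy(), H.copy()))
    return iterates
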