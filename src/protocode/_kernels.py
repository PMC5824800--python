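"""Numba kernels for the hot inner loops.

The simulator performs millions of per-sample gradient updates on a tiny
3-6-11 network; a compiled kernel keeps full runs tractable. Kernels are
straight transliterations of the numpy math in ``translation_network`` and
are checked against finite differences in the test suite. No fastmath, so
results are bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def sgd_train(w1, b1, w2, b2, X, D, order, eta):  # pragma: no cover - jit
    """Online backprop on squared-error loss, one sample per update.

    ``order`` is a flat index array (epochs * n_samples) giving the
    presentation sequence; weights are updated in place after each sample.
    """
    n_in, n_hid = w1.shape
    n_out = w2.shape[1]
    h = np.empty(n_hid)
    y = np.empty(n_out)
    d2 = np.empty(n_out)
    d1 = np.empty(n_hid)
    for k in order:
        x = X[k]
        d = D[k]
        # forward
        for j in range(n_hid):
            v = b1[j]
            for i in range(n_in):
                v += w1[i, j] * x[i]
            h[j] = 1.0 / (1.0 + np.exp(-v))
        for j in range(n_out):
            v = b2[j]
            for i in range(n_hid):
                v += w2[i, j] * h[i]
            y[j] = 1.0 / (1.0 + np.exp(-v))
        # backward: delta = -dE/dv for each node
        for j in range(n_out):
            e = d[j] - y[j]
            d2[j] = e * y[j] * (1.0 - y[j])
        for i in range(n_hid):
            s = 0.0
            for j in range(n_out):
                s += w2[i, j] * d2[j]
            d1[i] = s * h[i] * (1.0 - h[i])
        # update
        for i in range(n_hid):
            for j in range(n_out):
                w2[i, j] += eta * d2[j] * h[i]
        for j in range(n_out):
            b2[j] += eta * d2[j]
        for i in range(n_in):
            for j in range(n_hid):
                w1[i, j] += eta * d1[j] * x[i]
        for j in range(n_hid):
            b1[j] += eta * d1[j]
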