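"""Independent brute-force statistical oracles shared by the test suite."""

import numpy as np
import pandas as pd


def brute_force_tau_b(x, y):
    """Kendall tau-b by exhaustive pair enumeration with tie correction."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    C = D = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = np.sign(x[i] - x[j]) * np.sign(y[i] - y[j])
            C += s > 0
            D += s < 0
    n0 = n * (n - 1) / 2
    tx = sum(c * (c - 1) / 2 for c in pd.Series(x).value_counts())
    ty = sum(c * (c - 1) / 2 for c in pd.Series(y).value_counts())
    return (C - D) / np.sqrt((n0 - tx) * (n0 - ty))


def pearson(x, y):
    """Definitional Pearson correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xc, yc = x - x.mean(), y - y.mean()
    return (xc @ yc) / np.sqrt((xc @ xc) * (yc @ yc))
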