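"""Independent brute-force oracles shared across test modules."""

import numpy as np


def pava_exhaustive(y):
    """Least-squares monotone fit by exhaustive search over contiguous
    poolings (2^(n-1) partitions; valid for small n)."""
    y = np.asarray(y, float)
    n = len(y)
    best = None
    for mask in range(2 ** (n - 1)):
        bounds = [0] + [i + 1 for i in range(n - 1) if mask >> i & 1] + [n]
        blocks = list(zip(bounds[:-1], bounds[1:]))
        means = [y[a:b].mean() for a, b in blocks]
        if any(means[i] > means[i + 1] + 1e-12 for i in range(len(means) - 1)):
            continue
        fit = np.concatenate([np.full(b - a, m) for (a, b), m in zip(blocks, means)])
        sse = float(((fit - y) ** 2).sum())
        if best is None or sse < best[0] - 1e-12:
            best = (sse, fit)
    return best[1]
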