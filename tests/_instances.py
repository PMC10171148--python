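"""Shared random spatiotemporal point instances for clustering tests."""

import numpy as np


def random_instance(seed, n_max=500):
    """Clustered + scattered points: a few tight spatiotemporal blobs over
    a uniform background, sized to exercise cores, borders and noise."""
    rng = np.random.default_rng(seed)
    n_blobs = rng.integers(1, 6)
    xs, ys, ts = [], [], []
    for _ in range(n_blobs):
        k = int(rng.integers(3, 40))
        cx, cy = rng.uniform(0, 400, 2)
        ct = rng.uniform(0, 600)
        xs.append(rng.normal(cx, rng.uniform(1, 10), k))
        ys.append(rng.normal(cy, rng.uniform(1, 10), k))
        ts.append(rng.normal(ct, rng.uniform(2, 30), k))
    n_scatter = int(rng.integers(10, 120))
    xs.append(rng.uniform(0, 400, n_scatter))
    ys.append(rng.uniform(0, 400, n_scatter))
    ts.append(rng.uniform(0, 600, n_scatter))
    x = np.concatenate(xs)[:n_max]
    y = np.concatenate(ys)[:n_max]
    t = np.concatenate(ts)[:n_max]
    return x, y, t
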