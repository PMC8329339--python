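"""Concentration-of-measure experiment over the hypervector dimension.

For each dimension D, draw triples of i.i.d. random hypervectors, record
all pairwise distances (three per triple) and the distances from their
majority bundle to each input (three per triple).  As D grows, the
pairwise distances concentrate around 0.5 (quasi-orthogonality) and the
bundle-to-input distances around 0.25, with 1–99 percentile whiskers that
shrink smoothly.  The default sweep goes from D=100 to D=10,000 in steps
of 300; the default 2,000 repetitions per dimension are a desk-scale
version of the same experiment (the distributions are already tight there;
more repetitions only polish the percentile estimates).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

#: Default dimension sweep: 100 to 10,000 in steps of 300.
DEFAULT_DIMS = tuple(range(100, 10_001, 300))


def concentration_samples(D: int, reps: int, rng: np.random.Generator
                          ) -> tuple[np.ndarray, np.ndarray]:
    """Pairwise and bundle-to-input NHD samples from ``reps`` random triples.

    Returns two arrays of length ``3 * reps``.  Bundling three vectors is
    a pure 2-of-3 majority (no ties), so no tie RNG is involved.
    """
    triples = rng.integers(0, 2, size=(reps, 3, D), dtype=np.uint8)
    a, b, c = triples[:, 0], triples[:, 1], triples[:, 2]
    pair = np.concatenate([
        (a != b).mean(axis=1), (a != c).mean(axis=1), (b != c).mean(axis=1)])
    counts = triples.sum(axis=1, dtype=np.int16)
    bund = (counts >= 2).astype(np.uint8)
    to_input = np.concatenate([
        (bund != a).mean(axis=1), (bund != b).mean(axis=1), (bund != c).mean(axis=1)])
    return pair, to_input


def run_concentration_experiment(dims=None, reps: int = 2_000,
                                 seed: int = 0) -> pd.DataFrame:
    """Median and 1–99 percentile range of both NHD distributions per dimension.

    Columns: ``D``, ``rand_median``, ``rand_p01``, ``rand_p99``,
    ``rand_range``, and the same four with a ``bundle_`` prefix.
    """
    if reps < 100:
        raise ValueError(f"reps must be >= 100 for stable percentiles, got {reps}")
    dims = DEFAULT_DIMS if dims is None else tuple(int(d) for d in dims)
    rng = np.random.default_rng(seed)
    rows = []
    for D in dims:
        pair, to_input = concentration_samples(D, reps, rng)
        rp = np.percentile(pair, [1, 50, 99])
        bp = np.percentile(to_input, [1, 50, 99])
        rows.append({
            "D": D,
            "rand_median": rp[1], "rand_p01": rp[0], "rand_p99": rp[2],
            "rand_range": rp[2] - rp[0],
            "bundle_median": bp[1], "bundle_p01": bp[0], "bundle_p99": bp[2],
            "bundle_range": bp[2] - bp[0],
        })
    return pd.DataFrame(rows)
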