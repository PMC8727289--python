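"""Small numeric helpers: linear-interpolation percentiles, plain and count-weighted."""

from __future__ import annotations

import numpy as np


def percentile(values, q: float) -> float:
    """Linear-interpolation percentile between order statistics (numpy default)."""
    return float(np.percentile(np.asarray(values, dtype=float), q))


def weighted_percentile(values, counts, q: float) -> float:
    """Percentile of the multiset where ``values[i]`` occurs ``counts[i]`` times.

    Equivalent to ``np.percentile(np.repeat(values, counts), q)`` without
    materialising the expansion; counts must be positive integers.
    """
    v = np.asarray(values, dtype=float)
    c = np.asarray(counts, dtype=np.int64)
    if v.size == 0:
        raise ValueError("weighted_percentile of empty input")
    if np.any(c < 1):
        raise ValueError("counts must be >= 1")
    order = np.argsort(v, kind="stable")
    v = v[order]
    c = c[order]
    n = int(c.sum())
    h = q / 100.0 * (n - 1)  # 0-based fractional rank
    lo = int(np.floor(h))
    hi = int(np.ceil(h))
    cum = np.cumsum(c)  # cum[i] = number of expanded items at sorted index <= i
    x_lo = v[np.searchsorted(cum, lo + 1)]
    x_hi = v[np.searchsorted(cum, hi + 1)]
    return float(x_lo + (h - lo) * (x_hi - x_lo))
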