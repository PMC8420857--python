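"""Independent oracles used by the test suite.

These deliberately avoid the package's own algorithms: the assignment oracle
enumerates every labeling; the smoothing oracle is a plain Python loop.
"""

from functools import lru_cache

import numpy as np


@lru_cache(maxsize=None)
def all_count_tuples(n: int) -> np.ndarray:
    """Counts (n_H, n_E, seg_H, seg_E) for every one of the 3^n labelings."""
    codes = np.arange(3**n, dtype=np.int64)
    digits = (codes[:, None] // 3 ** np.arange(n, dtype=np.int64)) % 3  # 0=H 1=E 2=C
    n_h = (digits == 0).sum(axis=1)
    n_e = (digits == 1).sum(axis=1)

    def seg(code):
        starts = (digits[:, :1] == code).astype(np.int64).sum(axis=1)
        if n > 1:
            starts = starts + (
                (digits[:, 1:] == code) & (digits[:, :-1] != code)
            ).sum(axis=1)
        return starts

    return np.stack([n_h, n_e, seg(0), seg(1)], axis=1)


def brute_force_min_discrepancy(targets, lam: float = 1.0) -> float:
    """Exhaustive-search minimum of the discrepancy objective over 3^n labelings."""
    t = np.array(
        [
            targets.n_h_residues,
            targets.n_e_residues,
            targets.n_h_segments,
            targets.n_e_segments,
        ]
    )
    cnt = all_count_tuples(targets.n_res)
    d = np.abs(cnt[:, :2] - t[:2]).sum(axis=1) + lam * np.abs(cnt[:, 2:] - t[2:]).sum(
        axis=1
    )
    return float(d.min())


def loop_moving_average(values, window: int):
    """Centered moving average with shrinking edge windows, written as a loop."""
    n = len(values)
    half = window // 2
    out = []
    for i in range(n):
        lo = max(0, i - half)
        hi = min(n, i + half + 1)
        out.append(sum(values[lo:hi]) / (hi - lo))
    return out
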