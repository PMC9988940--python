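"""Dip-type unimodality statistic with a Monte-Carlo uniform-null test.

The statistic is the sup-norm distance between the empirical CDF and the
closest CDF that is convex left of a mode and concave right of it, computed
by gluing the greatest convex minorant (GCM) of the empirical CDF on a left
prefix to the least concave majorant (LCM) on the complementary suffix and
minimizing over the mode position. The p-value is calibrated by Monte Carlo
against samples from the uniform distribution (the least favourable unimodal
null), so the test is exact by construction for the statistic used.
"""

from __future__ import annotations

import numpy as np

__all__ = ["dip_statistic", "dip_test"]


def _prefix_gcm_deviation(x: np.ndarray, F: np.ndarray) -> np.ndarray:
    """For each prefix [0..m], sup deviation of F above its greatest convex
    minorant over the prefix. O(n^2) worst case, vectorized inner steps."""
    n = len(x)
    dev = np.zeros(n)  # deviation of each point from the current hull
    out = np.empty(n)
    hull: list[int] = [0]
    for m in range(n):
        if m > 0:
            # pop hull vertices that break convexity (lower hull of (x, F))
            while len(hull) >= 2:
                i, j = hull[-2], hull[-1]
                if (F[j] - F[i]) * (x[m] - x[j]) <= (F[m] - F[j]) * (x[j] - x[i]):
                    break
                hull.pop()
            a = hull[-1]
            # deviations over the new segment a..m
            if x[m] > x[a]:
                t = (x[a + 1 : m + 1] - x[a]) / (x[m] - x[a])
                line = F[a] + t * (F[m] - F[a])
            else:
                line = np.full(m - a, F[a])
            dev[a + 1 : m + 1] = F[a + 1 : m + 1] - line
            hull.append(m)
        out[m] = dev[: m + 1].max(initial=0.0)
    return out


def dip_statistic(x: np.ndarray) -> float:
    """Sup-distance of the empirical CDF to the nearest glued GCM/LCM
    unimodal envelope, halved (the L-infinity best approximation offset)."""
    x = np.sort(np.asarray(x, dtype=float))
    n = len(x)
    if n < 4 or x[0] == x[-1]:
        return 0.0
    F = (np.arange(1, n + 1)) / n
    d_left = _prefix_gcm_deviation(x, F)
    # right side: LCM deviation below F == GCM deviation of the reflected CDF
    xr = -x[::-1]
    Fr = 1.0 - F[::-1] + 1.0 / n
    d_right = _prefix_gcm_deviation(xr, Fr)[::-1]
    # distance achievable with the mode at position m, minimized over m
    return float(np.maximum(d_left, d_right).min() / 2.0 + 0.5 / n)


def dip_test(
    x: np.ndarray, n_null: int = 200, seed: int | None = None
) -> tuple[float, float]:
    """Dip statistic and Monte-Carlo p-value against the uniform null.

    Returns ``(dip, p)`` where p = (1 + #{null >= observed}) / (1 + n_null).
    Small p rejects unimodality.
    """
    x = np.asarray(x, dtype=float)
    obs = dip_statistic(x)
    rng = np.random.default_rng(seed)
    null = np.array(
        [dip_statistic(rng.uniform(size=len(x))) for _ in range(n_null)]
    )
    p = (1.0 + float((null >= obs).sum())) / (1.0 + n_null)
    return obs, p
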