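"""Naive brute-force reference implementations of ApEn and cross-ApEn.

These are direct O(N^2 * m) transcriptions of the defining formulas, kept
deliberately independent of the optimized kernels so they can serve as an
oracle: no sorting, no windowing, no shared code. They are only meant for
short series.
"""

from __future__ import annotations

import numpy as np


def apen_naive(u: np.ndarray, m: int = 2, r_factor: float = 0.2) -> float:
    """Approximate entropy by the textbook double loop.

    r = r_factor * SD(u) (population SD); Chebyshev distance; self-match
    included; Phi^m averaged over the N-m+1 templates of length m and
    Phi^{m+1} over the N-m templates of length m+1.
    """
    u = np.asarray(u, dtype=float)
    N = len(u)
    r = r_factor * u.std()
    if r == 0.0:
        return 0.0

    def phi(mm: int) -> float:
        n = N - mm + 1
        logs = []
        for i in range(n):
            xi = u[i:i + mm]
            count = 0
            for j in range(n):
                if np.max(np.abs(xi - u[j:j + mm])) <= r:
                    count += 1
            logs.append(np.log(count / n))
        return float(np.mean(logs))

    return phi(m) - phi(m + 1)


def capen_naive(u: np.ndarray, v: np.ndarray, m: int = 2,
                r_factor: float = 0.2) -> tuple[float, int, int]:
    """Cross-approximate entropy by the textbook double loop.

    Both series are z-scored and r = r_factor on that unit-SD scale.
    Templates come from ``u``, targets from ``v``. Templates with zero
    matches are excluded from the average of ln C and counted; returns
    (value, n_zero_match_m, n_zero_match_m1).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(u) != len(v):
        raise ValueError("series must have equal length")
    N = len(u)
    r = float(r_factor)

    def z(x: np.ndarray) -> np.ndarray:
        sd = x.std()
        return (x - x.mean()) / sd if sd > 0 else x - x.mean()

    zu, zv = z(u), z(v)

    def phi(mm: int) -> tuple[float, int]:
        n = N - mm + 1
        logs = []
        n_zero = 0
        for i in range(n):
            xi = zu[i:i + mm]
            count = 0
            for j in range(n):
                if np.max(np.abs(xi - zv[j:j + mm])) <= r:
                    count += 1
            if count > 0:
                logs.append(np.log(count / n))
            else:
                n_zero += 1
        return (float(np.mean(logs)) if logs else 0.0), n_zero

    pm, z_m = phi(m)
    pm1, z_m1 = phi(m + 1)
    return pm - pm1, z_m, z_m1
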