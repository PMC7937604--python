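"""Numba kernels for the template-matching counts behind ApEn and cross-ApEn.

Strategy: templates are sorted by their first coordinate, so the candidate
set for each template is one contiguous window (the first coordinate already
bounds the Chebyshev distance from below); the remaining coordinates are
checked branchlessly inside the window, which lets LLVM vectorize the inner
loop. Counts for embedding dimensions m and m+1 are accumulated in a single
pass. The window is a filter, never an approximation — counts are exact.

All kernels expect the series already standardized by the caller and the
tolerance r on that standardized scale. Templates that have no (m+1)-point
extension (exactly one per series, the last start index) are marked with a
sentinel coordinate so they can never match at dimension m+1, and are
excluded from the Phi^{m+1} average via ``inv_pos``.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_SENTINEL = 1e300


def _embed_sorted(x: np.ndarray, m: int):
    """Template coordinates gathered contiguously in first-coordinate order.

    Returns (coords, inv_pos) where coords has shape (m+1, N-m+1) and
    inv_pos is the sorted position of the single template without an
    (m+1)-th coordinate (its sentinel row value can never match).
    """
    N = x.shape[0]
    n_m = N - m + 1
    order = np.argsort(x[:n_m], kind="stable")
    coords = np.empty((m + 1, n_m))
    for k in range(m):
        coords[k] = x[order + k]
    ext = order + m
    inv_pos = int(np.nonzero(ext == N)[0][0])
    safe = np.minimum(ext, N - 1)
    coords[m] = np.where(ext < N, x[safe], _SENTINEL)
    return coords, inv_pos


@njit(cache=True, fastmath=True)
def _phi_pair_m2(c1q, c2q, c1t, c2t, lo, hi, r, inv_pos, n_m, n_m1):
    """Phi sums for m=2 and m=3 in one pass (query templates vs targets).

    Returns (phi_m, phi_m1, n_zero_m, n_zero_m1): averages of
    ln(count / n) over query templates with at least one match, plus the
    zero-match template counts at each level. For self-matching (ApEn) the
    query and target arrays are the same and zero matches cannot occur.
    """
    phi_m = 0.0
    phi_m1 = 0.0
    n_zero_m = 0
    n_zero_m1 = 0
    nq = c1q.shape[0]
    for a in range(nq):
        x1 = c1q[a]
        x2 = c2q[a]
        ca = 0
        ca1 = 0
        for b in range(lo[a], hi[a]):
            d1 = x1 - c1t[b]
            hit = 1 if (d1 <= r and d1 >= -r) else 0
            d2 = x2 - c2t[b]
            hit1 = 1 if (d2 <= r and d2 >= -r) else 0
            ca += hit
            ca1 += hit * hit1
        if ca > 0:
            phi_m += np.log(ca / n_m)
        else:
            n_zero_m += 1
        if a != inv_pos:
            if ca1 > 0:
                phi_m1 += np.log(ca1 / n_m1)
            else:
                n_zero_m1 += 1
    n_used_m = nq - n_zero_m
    n_used_m1 = nq - 1 - n_zero_m1
    if n_used_m > 0:
        phi_m = phi_m / n_used_m
    if n_used_m1 > 0:
        phi_m1 = phi_m1 / n_used_m1
    return phi_m, phi_m1, n_zero_m, n_zero_m1


@njit(cache=True, fastmath=True)
def _phi_pair_generic(cq, ct, lo, hi, r, inv_pos, m, n_m, n_m1):
    """Generic-m version of :func:`_phi_pair_m2` (coords as (m+1, n) arrays)."""
    phi_m = 0.0
    phi_m1 = 0.0
    n_zero_m = 0
    n_zero_m1 = 0
    nq = cq.shape[1]
    for a in range(nq):
        ca = 0
        ca1 = 0
        for b in range(lo[a], hi[a]):
            hit = 1
            for k in range(1, m):
                d = cq[k, a] - ct[k, b]
                if d > r or d < -r:
                    hit = 0
                    break
            if hit == 0:
                continue
            ca += 1
            d = cq[m, a] - ct[m, b]
            if -r <= d <= r:
                ca1 += 1
        if ca > 0:
            phi_m += np.log(ca / n_m)
        else:
            n_zero_m += 1
        if a != inv_pos:
            if ca1 > 0:
                phi_m1 += np.log(ca1 / n_m1)
            else:
                n_zero_m1 += 1
    n_used_m = nq - n_zero_m
    n_used_m1 = nq - 1 - n_zero_m1
    if n_used_m > 0:
        phi_m = phi_m / n_used_m
    if n_used_m1 > 0:
        phi_m1 = phi_m1 / n_used_m1
    return phi_m, phi_m1, n_zero_m, n_zero_m1


def phi_terms(u: np.ndarray, v: np.ndarray | None, m: int, r: float):
    """Phi^m, Phi^{m+1} and zero-match counts for one series or a pair.

    ``v is None`` gives the self-matching (ApEn) case. For a pair, templates
    are taken from ``u`` and match targets from ``v``; both series must have
    equal length. The sorted-window candidate sets are found with
    ``searchsorted`` on the target first coordinates.
    """
    N = u.shape[0]
    n_m = N - m + 1
    n_m1 = N - m
    cq, inv_pos = _embed_sorted(u, m)
    if v is None:
        ct = cq
    else:
        ct, _ = _embed_sorted(v, m)
    lo = np.searchsorted(ct[0], cq[0] - r, side="left")
    hi = np.searchsorted(ct[0], cq[0] + r, side="right")
    lo = lo.astype(np.int64)
    hi = hi.astype(np.int64)
    if m == 2:
        return _phi_pair_m2(cq[1], cq[2], ct[1], ct[2], lo, hi, r,
                            inv_pos, n_m, n_m1)
    return _phi_pair_generic(cq, ct, lo, hi, r, inv_pos, m, n_m, n_m1)
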