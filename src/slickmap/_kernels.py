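"""Numba-accelerated inner loops for the EHH/iHS and IBS scans.

These kernels mirror the pure-Python reference implementations in
:mod:`slickmap.selscan` and :mod:`slickmap.ibs` exactly (same truncation
rules, same exclusion of missing-containing chromosomes); the reference
paths remain in place and are used when numba is unavailable.
"""

from __future__ import annotations

import numpy as np

try:
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        if args and callable(args[0]):
            return args[0]
        return wrap


@njit(cache=True)
def _ihh_side_kernel(
    H: np.ndarray,  # (n_chrom, m) int8, -1 missing
    core: int,
    allele: int,
    positions: np.ndarray,  # float64
    direction: int,
    max_extend_bp: float,
    ehh_cutoff: float,
):
    """One-sided iHH integral; returns (ihh, reason) with reason codes
    0 = chromosome end / carriers exhausted, 1 = max extension, 2 = EHH cutoff."""
    n, m = H.shape
    n_car = 0
    for i in range(n):
        if H[i, core] == allele:
            n_car += 1
    carriers = np.empty(n_car, np.int64)
    k = 0
    for i in range(n):
        if H[i, core] == allele:
            carriers[k] = i
            k += 1
    gid = np.zeros(n_car, np.int64)
    valid = np.ones(n_car, np.bool_)
    limit = positions[core] + direction * max_extend_bp
    ihh = 0.0
    reason = 0
    prev_pos = positions[core]
    prev_ehh = -1.0
    x = core
    # scratch for relabelling
    keys = np.empty(n_car, np.int64)
    counts = np.empty(n_car, np.int64)
    while 0 <= x < m:
        if (direction == 1 and positions[x] > limit) or (
            direction == -1 and positions[x] < limit
        ):
            reason = 1
            break
        nv = 0
        for i in range(n_car):
            if valid[i] and H[carriers[i], x] == -1:
                valid[i] = False
        for i in range(n_car):
            if valid[i]:
                nv += 1
        if nv < 2:
            reason = 0
            break
        # relabel combined (gid, allele) pairs and count group sizes
        nk = 0
        hom_pairs = 0.0
        for i in range(n_car):
            if not valid[i]:
                continue
            comb = gid[i] * 2 + H[carriers[i], x]
            found = -1
            for j in range(nk):
                if keys[j] == comb:
                    found = j
                    break
            if found == -1:
                keys[nk] = comb
                counts[nk] = 1
                gid[i] = nk
                nk += 1
            else:
                counts[found] += 1
                gid[i] = found
        for j in range(nk):
            hom_pairs += counts[j] * (counts[j] - 1)
        ehh_val = hom_pairs / (nv * (nv - 1))
        if prev_ehh >= 0.0:
            ihh += (
                (prev_ehh + ehh_val)
                / 2.0
                * (abs(positions[x] - positions[core]) - abs(prev_pos - positions[core]))
            )
        prev_ehh = ehh_val
        prev_pos = positions[x]
        if ehh_val < ehh_cutoff:
            reason = 2
            break
        x += direction
    return ihh, reason


@njit(cache=True)
def _ibs_window_kernel(
    codes: np.ndarray,  # (n_chrom, n_win) int64 window bit-codes
    nmiss: np.ndarray,  # (n_chrom, n_win) int32 missing calls per window
    in_rows: np.ndarray,
    out_rows: np.ndarray,
    f_in_min: float,
    f_out_max: float,
    mode: int,  # 0: consensus (in >= f_in_min AND out <= f_out_max)
    #             1: shared (freq >= f_in_min in both groups for one pattern)
):
    """Per-window pattern-frequency tests.

    Returns (pass mask, best in-group freq, out-group freq of the best
    in-group pattern) per window start.
    """
    n_win = codes.shape[1]
    ok = np.zeros(n_win, np.bool_)
    best_in = np.zeros(n_win)
    best_out = np.zeros(n_win)
    ni_max = len(in_rows)
    keys = np.empty(ni_max, np.int64)
    counts = np.empty(ni_max, np.int64)
    for s in range(n_win):
        nk = 0
        n_vi = 0
        for r in in_rows:
            if nmiss[r, s] != 0:
                continue
            n_vi += 1
            c = codes[r, s]
            found = -1
            for j in range(nk):
                if keys[j] == c:
                    found = j
                    break
            if found == -1:
                keys[nk] = c
                counts[nk] = 1
                nk += 1
            else:
                counts[found] += 1
        if n_vi == 0:
            continue
        n_vo = 0
        for r in out_rows:
            if nmiss[r, s] == 0:
                n_vo += 1
        top = -1.0
        top_out = 0.0
        passed = False
        for j in range(nk):
            fi = counts[j] / n_vi
            n_match = 0
            for r in out_rows:
                if nmiss[r, s] == 0 and codes[r, s] == keys[j]:
                    n_match += 1
            fo = n_match / n_vo if n_vo > 0 else 0.0
            if fi > top:
                top = fi
                top_out = fo
            if mode == 0:
                if fi >= f_in_min and fo <= f_out_max:
                    passed = True
            else:
                if fi >= f_in_min and fo >= f_in_min:
                    passed = True
        ok[s] = passed
        best_in[s] = top
        best_out[s] = top_out
    return ok, best_in, best_out


def window_codes(H: np.ndarray, w: int):
    """Int64 bit-codes and missing counts for all windows of size w.

    Window codes are exact binary encodings (w <= 62); missing calls are
    encoded as 0 in the code and tracked separately so callers can exclude
    those chromosomes.
    """
    if w > 62:
        raise ValueError("window size > 62 not supported by the bit-code kernel")
    B = (H == 1).astype(np.int64)
    miss = (H == -1).astype(np.int32)
    m = H.shape[1]
    codes = B[:, : m - w + 1].copy()
    nmiss = miss[:, : m - w + 1].copy()
    for k in range(1, w):
        codes = codes * 2 + B[:, k : m - w + 1 + k]
        nmiss = nmiss + miss[:, k : m - w + 1 + k]
    return codes, nmiss
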