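"""Numba kernels for affine-gap local alignment in converted base space.

Scoring (fixed scheme): match +1, mismatch -1, gap open -3, gap extend -1;
a gap of length k costs open + k*extend.  Base codes: A=0 C=1 G=2 T=3,
anything else 4 (never matches).  ``mode`` selects the reference-side
wildcard: mode 0 lets reference C match read C or T (C->T collapse),
mode 1 lets reference G match read G or A (the complementary collapse).
"""

from __future__ import annotations

import numpy as np
from numba import njit

MATCH = 1
MISMATCH = -1
GAP_OPEN = 3  # positive costs
GAP_EXTEND = 1
_GO = GAP_OPEN + GAP_EXTEND  # opening a gap of length 1 costs open+extend

NEG = -(10**6)

_CODE_TABLE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE_TABLE[_b] = _i
    _CODE_TABLE[ord(chr(_b).lower())] = _i


def encode(seq: str) -> np.ndarray:
    return _CODE_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


@njit(cache=True, inline="always")
def _subst(r: np.int8, q: np.int8, mode: np.int8) -> np.int64:
    if r == q and r != 4:
        return MATCH
    if mode == 0 and r == 1 and q == 3:  # ref C vs read T
        return MATCH
    if mode == 1 and r == 2 and q == 0:  # ref G vs read A
        return MATCH
    return MISMATCH


@njit(cache=True)
def _score_one(q, r, mode, H, E, F):
    """Best local score of query ``q`` vs reference ``r`` (rolling rows).

    ``H``/``E``/``F`` are scratch rows of length >= len(r)+1.
    """
    n = r.shape[0]
    for j in range(n + 1):
        H[j] = 0
        F[j] = NEG
    best = 0
    for i in range(q.shape[0]):
        diag = H[0]  # H[i-1, j-1]
        H[0] = 0
        e = NEG
        for j in range(1, n + 1):
            f = max(H[j] - _GO, F[j] - GAP_EXTEND)
            F[j] = f
            e = max(H[j - 1] - _GO, e - GAP_EXTEND)
            h = diag + _subst(r[j - 1], q[i], mode)
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = H[j]
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def score_matrix(q_flat, q_off, q_len, r_flat, r_off, r_len, modes):
    """Best local score for every (read, candidate reference) pair."""
    n_reads = q_off.shape[0]
    n_refs = r_off.shape[0]
    out = np.zeros((n_reads, n_refs), dtype=np.int32)
    max_n = 0
    for c in range(n_refs):
        if r_len[c] > max_n:
            max_n = r_len[c]
    H = np.empty(max_n + 1, dtype=np.int32)
    E = np.empty(max_n + 1, dtype=np.int32)
    F = np.empty(max_n + 1, dtype=np.int32)
    for i in range(n_reads):
        q = q_flat[q_off[i] : q_off[i] + q_len[i]]
        for c in range(n_refs):
            r = r_flat[r_off[c] : r_off[c] + r_len[c]]
            out[i, c] = _score_one(q, r, modes[c], H, E, F)
    return out


@njit(cache=True)
def full_dp(q, r, mode):
    """Full H/E/F matrices for traceback; H[i, j] uses 1-based i (query), j (ref)."""
    m = q.shape[0]
    n = r.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    F = np.full((m + 1, n + 1), NEG, dtype=np.int32)
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            E[i, j] = max(H[i, j - 1] - _GO, E[i, j - 1] - GAP_EXTEND)
            F[i, j] = max(H[i - 1, j] - _GO, F[i - 1, j] - GAP_EXTEND)
            h = H[i - 1, j - 1] + _subst(r[j - 1], q[i - 1], mode)
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = 0
            H[i, j] = h
    return H, E, F


@njit(cache=True)
def traceback(q, r, mode, H, E, F, end_i, end_j):
    """Trace one optimal path from (end_i, end_j) back to its start.

    Deterministic priority: diagonal, then gap-in-query (E), then gap-in-
    reference (F); inside a gap chain, closing the gap (open) is preferred
    over extending it.  Returns parallel arrays (ref_j, q_i), 1-based, with
    -1 marking a gap on that side, ordered from alignment start to end.
    """
    max_len = q.shape[0] + r.shape[0]
    ref_col = np.empty(max_len, dtype=np.int32)
    q_col = np.empty(max_len, dtype=np.int32)
    k = max_len
    i, j = end_i, end_j
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h == 0:
                break
            if h == H[i - 1, j - 1] + _subst(r[j - 1], q[i - 1], mode):
                k -= 1
                ref_col[k] = j
                q_col[k] = i
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            k -= 1
            ref_col[k] = j
            q_col[k] = -1
            if E[i, j] == H[i, j - 1] - _GO:
                state = 0
            j -= 1
        else:
            k -= 1
            ref_col[k] = -1
            q_col[k] = i
            if F[i, j] == H[i - 1, j] - _GO:
                state = 0
            i -= 1
    return ref_col[k:], q_col[k:]
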