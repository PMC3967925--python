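"""Three-state alignment lattice kernels.

States: 0 = M (match, consumes one column of each family), 1 = I_T
(insertion in T, consumes a T column), 2 = I_S (insertion in S, consumes an
S column).  Paths run from the (0,0) dummy vertex to (nT, nS).  The direct
transition I_S -> I_T is disallowed (canonical ordering: between two
matches, unaligned T columns precede unaligned S columns); all other
transitions are allowed and carry an additive bias.

Emission layout (0-based consumed-column indexing):
  match[i-1, j-1] for an M vertex at lattice position (i, j)
  ins_t[i-1, j]   for an I_T vertex at (i, j)   -- shape (nT, nS+1)
  ins_s[i, j-1]   for an I_S vertex at (i, j)   -- shape (nT+1, nS)

Viterbi tie-break: states are scanned M, I_T, I_S with strict improvement,
so on equal scores M is preferred, then I_T, then I_S.
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30

M, I_T, I_S = 0, 1, 2


def make_transitions(bias: np.ndarray | None = None) -> np.ndarray:
    """3x3 transition score matrix with the I_S->I_T ban baked in."""
    trans = np.zeros((3, 3)) if bias is None else np.array(bias, dtype=float)
    trans[I_S, I_T] = NEG
    return trans


@njit(cache=True)
def viterbi_kernel(match, ins_t, ins_s, trans):  # pragma: no cover - numba
    nT = match.shape[0]
    nS = match.shape[1]
    V = np.full((3, nT + 1, nS + 1), NEG)
    ptr = np.full((3, nT + 1, nS + 1), -1, dtype=np.int8)
    for i in range(nT + 1):
        for j in range(nS + 1):
            if i > 0 and j > 0:
                best = NEG
                arg = -1
                if i == 1 and j == 1:
                    best = 0.0
                    arg = 3
                for u in range(3):
                    s = V[u, i - 1, j - 1] + trans[u, M]
                    if s > best:
                        best = s
                        arg = u
                V[M, i, j] = best + match[i - 1, j - 1]
                ptr[M, i, j] = arg
            if i > 0:
                best = NEG
                arg = -1
                if i == 1 and j == 0:
                    best = 0.0
                    arg = 3
                for u in range(3):
                    s = V[u, i - 1, j] + trans[u, I_T]
                    if s > best:
                        best = s
                        arg = u
                V[I_T, i, j] = best + ins_t[i - 1, j]
                ptr[I_T, i, j] = arg
            if j > 0:
                best = NEG
                arg = -1
                if i == 0 and j == 1:
                    best = 0.0
                    arg = 3
                for u in range(3):
                    s = V[u, i, j - 1] + trans[u, I_S]
                    if s > best:
                        best = s
                        arg = u
                V[I_S, i, j] = best + ins_s[i, j - 1]
                ptr[I_S, i, j] = arg
    best = NEG
    end_state = 0
    for u in range(3):
        if V[u, nT, nS] > best:
            best = V[u, nT, nS]
            end_state = u
    # traceback
    maxlen = nT + nS
    path = np.empty((maxlen, 3), dtype=np.int64)
    pos = maxlen
    i, j, u = nT, nS, end_state
    while True:
        pos -= 1
        path[pos, 0] = i
        path[pos, 1] = j
        path[pos, 2] = u
        p = ptr[u, i, j]
        if u == M:
            i -= 1
            j -= 1
        elif u == I_T:
            i -= 1
        else:
            j -= 1
        if p == 3:
            break
        u = p
    return best, path[pos:]


@njit(cache=True)
def _lse3(a, b, c):  # pragma: no cover - numba
    m = a
    if b > m:
        m = b
    if c > m:
        m = c
    if m <= NEG:
        return NEG
    return m + np.log(np.exp(a - m) + np.exp(b - m) + np.exp(c - m))


@njit(cache=True)
def forward_kernel(match, ins_t, ins_s, trans):  # pragma: no cover - numba
    """Log-space forward sums; returns (logZ, alpha[3, nT+1, nS+1])."""
    nT = match.shape[0]
    nS = match.shape[1]
    A = np.full((3, nT + 1, nS + 1), NEG)
    for i in range(nT + 1):
        for j in range(nS + 1):
            if i > 0 and j > 0:
                s = _lse3(
                    A[M, i - 1, j - 1] + trans[M, M],
                    A[I_T, i - 1, j - 1] + trans[I_T, M],
                    A[I_S, i - 1, j - 1] + trans[I_S, M],
                )
                if i == 1 and j == 1:
                    s = 0.0
                A[M, i, j] = s + match[i - 1, j - 1]
            if i > 0:
                s = _lse3(
                    A[M, i - 1, j] + trans[M, I_T],
                    A[I_T, i - 1, j] + trans[I_T, I_T],
                    A[I_S, i - 1, j] + trans[I_S, I_T],
                )
                if i == 1 and j == 0:
                    s = 0.0
                A[I_T, i, j] = s + ins_t[i - 1, j]
            if j > 0:
                s = _lse3(
                    A[M, i, j - 1] + trans[M, I_S],
                    A[I_T, i, j - 1] + trans[I_T, I_S],
                    A[I_S, i, j - 1] + trans[I_S, I_S],
                )
                if i == 0 and j == 1:
                    s = 0.0
                A[I_S, i, j] = s + ins_s[i, j - 1]
    logZ = _lse3(A[M, nT, nS], A[I_T, nT, nS], A[I_S, nT, nS])
    return logZ, A


@njit(cache=True)
def backward_kernel(match, ins_t, ins_s, trans):  # pragma: no cover - numba
    """Log-space suffix sums beta[u, i, j] (emission at (i,j,u) excluded)."""
    nT = match.shape[0]
    nS = match.shape[1]
    B = np.full((3, nT + 1, nS + 1), NEG)
    for u in range(3):
        B[u, nT, nS] = 0.0
    for i in range(nT, -1, -1):
        for j in range(nS, -1, -1):
            if i == nT and j == nS:
                continue
            for u in range(3):
                a = NEG
                b = NEG
                c = NEG
                if i < nT and j < nS:
                    a = trans[u, M] + match[i, j] + B[M, i + 1, j + 1]
                if i < nT:
                    b = trans[u, I_T] + ins_t[i, j] + B[I_T, i + 1, j]
                if j < nS:
                    c = trans[u, I_S] + ins_s[i, j] + B[I_S, i, j + 1]
                B[u, i, j] = _lse3(a, b, c)
    return B


@njit(cache=True)
def posterior_kernel(match, ins_t, ins_s, trans):  # pragma: no cover - numba
    """Vertex posteriors and expected transition counts.

    Returns (logZ, post[3, nT+1, nS+1], expected_trans[3, 3]).
    post[u, i, j] is the probability that a path passes vertex (i, j, u).
    """
    nT = match.shape[0]
    nS = match.shape[1]
    logZ, A = forward_kernel(match, ins_t, ins_s, trans)
    B = backward_kernel(match, ins_t, ins_s, trans)
    post = np.zeros((3, nT + 1, nS + 1))
    et = np.zeros((3, 3))
    for i in range(nT + 1):
        for j in range(nS + 1):
            for u in range(3):
                if A[u, i, j] > NEG / 2 and B[u, i, j] > NEG / 2:
                    post[u, i, j] = np.exp(A[u, i, j] + B[u, i, j] - logZ)
            for u in range(3):
                if A[u, i, j] <= NEG / 2:
                    continue
                if i < nT and j < nS and B[M, i + 1, j + 1] > NEG / 2:
                    et[u, M] += np.exp(
                        A[u, i, j] + trans[u, M] + match[i, j] + B[M, i + 1, j + 1] - logZ
                    )
                if i < nT and B[I_T, i + 1, j] > NEG / 2 and trans[u, I_T] > NEG / 2:
                    et[u, I_T] += np.exp(
                        A[u, i, j] + trans[u, I_T] + ins_t[i, j] + B[I_T, i + 1, j] - logZ
                    )
                if j < nS and B[I_S, i, j + 1] > NEG / 2 and trans[u, I_S] > NEG / 2:
                    et[u, I_S] += np.exp(
                        A[u, i, j] + trans[u, I_S] + ins_s[i, j] + B[I_S, i, j + 1] - logZ
                    )
    return logZ, post, et
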