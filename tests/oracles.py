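"""Independent brute-force oracles used by the test suite only.

Everything here is deliberately naive (explicit loops, exhaustive
enumeration) and shares no code with the package's DP/linear-algebra
paths.
"""

from __future__ import annotations

import math

import numpy as np

STATES = ("M", "I_T", "I_S")


def enumerate_paths(nT: int, nS: int):
    """All valid alignment paths as lists of (i, j, state) triples.

    A path runs from the (0,0) dummy to (nT, nS); M consumes one column of
    each family, I_T one of T, I_S one of S; the direct I_S -> I_T
    transition is forbidden.
    """
    results = []

    def step(i, j, prev, acc):
        if i == nT and j == nS:
            results.append(list(acc))
            return
        if i < nT and j < nS:
            acc.append((i + 1, j + 1, "M"))
            step(i + 1, j + 1, "M", acc)
            acc.pop()
        if i < nT and prev != "I_S":
            acc.append((i + 1, j, "I_T"))
            step(i + 1, j, "I_T", acc)
            acc.pop()
        if j < nS:
            acc.append((i, j + 1, "I_S"))
            step(i, j + 1, "I_S", acc)
            acc.pop()

    step(0, 0, None, [])
    return results


def path_score(triples, match, ins_t, ins_s, trans):
    """Emissions plus transition biases; layout as ScoreBundle.grids()."""
    idx = {"M": 0, "I_T": 1, "I_S": 2}
    total = 0.0
    prev = None
    for i, j, u in triples:
        if u == "M":
            total += match[i - 1][j - 1]
        elif u == "I_T":
            total += ins_t[i - 1][j]
        else:
            total += ins_s[i][j - 1]
        if prev is not None:
            total += trans[idx[prev]][idx[u]]
        prev = u
    return total


def brute_best(match, ins_t, ins_s, trans):
    """(best score, best path) by exhaustive enumeration."""
    nT, nS = len(match), len(match[0])
    best, best_path = -math.inf, None
    for triples in enumerate_paths(nT, nS):
        s = path_score(triples, match, ins_t, ins_s, trans)
        if s > best:
            best, best_path = s, triples
    return best, best_path


def brute_logz(match, ins_t, ins_s, trans):
    """log of the explicit sum over all alignment paths."""
    nT, nS = len(match), len(match[0])
    scores = [
        path_score(p, match, ins_t, ins_s, trans)
        for p in enumerate_paths(nT, nS)
    ]
    m = max(scores)
    return m + math.log(sum(math.exp(s - m) for s in scores))


def match_cells(triples):
    return [(i - 1, j - 1) for i, j, u in triples if u == "M"]


def brute_p1_optimum(match, ins_t, ins_s, trans, theta, L_mode, edge_weight=1.0):
    """Exhaustive optimum of the quadratic objective over all paths.

    ``theta(u_cell, v_cell)`` gives the edge potential of two match cells;
    the edge term sums over ordered pairs of distinct cells and is scaled
    by edge_weight / L with L the path's own length (L_mode='path') or a
    fixed integer L.
    """
    nT, nS = len(match), len(match[0])
    best, best_path = -math.inf, None
    for triples in enumerate_paths(nT, nS):
        node = path_score(triples, match, ins_t, ins_s, trans)
        cells = match_cells(triples)
        edge = 0.0
        for a in range(len(cells)):
            for b in range(len(cells)):
                if a != b:
                    edge += theta(cells[a], cells[b])
        L = len(triples) if L_mode == "path" else L_mode
        total = node + (edge_weight / L) * edge
        if total > best:
            best, best_path = total, triples
    return best, best_path


def naive_matmul(a, b):
    n, m, p = len(a), len(b[0]), len(b)
    out = [[0.0] * m for _ in range(n)]
    for i in range(n):
        for j in range(m):
            s = 0.0
            for k in range(p):
                s += a[i][k] * b[k][j]
            out[i][j] = s
    return np.array(out)


def naive_mi_pair(codes_i, codes_k, weights, pc, nsym=21):
    """MI of two integer-coded columns by direct joint counting.

    Codes must be < nsym (no unknown-residue codes).
    """
    joint = np.zeros((nsym, nsym))
    for a, b, w in zip(codes_i, codes_k, weights):
        joint[a, b] += w
    joint = (joint + pc / nsym**2) / (sum(weights) + pc)
    pi = joint.sum(axis=1)
    pk = joint.sum(axis=0)
    mi = 0.0
    for a in range(nsym):
        for b in range(nsym):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log(joint[a, b] / (pi[a] * pk[b]))
    return mi


def naive_edge_potential(p, q, kernel):
    total = 0.0
    for a in range(len(p)):
        for b in range(len(q)):
            total += p[a] * q[b] * kernel[a][b]
    return total


class DictEdgeTable:
    """Hand-settable edge table exposing the EdgePotentialTable accessors.

    ``theta`` maps ((i, k), (j, l)) to a value; missing keys score 0; both
    orientations are looked up so tests can specify either.
    """

    def __init__(self, theta: dict, shape: tuple[int, int], min_separation: int = 1):
        self.theta = dict(theta)
        self._shape = shape
        self.min_separation = min_separation

    @property
    def shape(self):
        return self._shape

    def potential(self, i, k, j, l):
        sep = self.min_separation
        if abs(i - k) < sep or abs(j - l) < sep:
            return 0.0
        return self.theta.get(((i, k), (j, l)), self.theta.get(((k, i), (l, j)), 0.0))

    def interaction_from(self, i, j):
        nT, nS = self._shape
        out = np.zeros((nT, nS))
        for k in range(nT):
            for l in range(nS):
                out[k, l] = self.potential(i, k, j, l)
        return out

    def interaction_sum(self, cells):
        nT, nS = self._shape
        out = np.zeros((nT, nS))
        for i, j in cells:
            out += self.interaction_from(i, j)
        return out

    def path_edge_score(self, cells):
        total = 0.0
        for a in range(len(cells)):
            for b in range(a + 1, len(cells)):
                i, j = cells[a]
                k, l = cells[b]
                total += self.potential(i, k, j, l)
        return total

    def cross_score(self, cells_a, cells_b):
        total = 0.0
        for i, j in cells_a:
            for k, l in cells_b:
                total += self.potential(i, k, j, l)
        return total


def random_dict_table(nT, nS, rng, scale=1.0, min_separation=1):
    """Dense random symmetric edge potentials for toy instances."""
    theta = {}
    for i in range(nT):
        for k in range(nT):
            for j in range(nS):
                for l in range(nS):
                    if abs(i - k) >= min_separation and abs(j - l) >= min_separation:
                        key = ((i, k), (j, l))
                        mirror = ((k, i), (l, j))
                        if mirror in theta:
                            theta[key] = theta[mirror]
                        else:
                            theta[key] = float(rng.normal(0.0, scale))
    return DictEdgeTable(theta, (nT, nS), min_separation)
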