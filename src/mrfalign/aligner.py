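"""Aligning two family models.

The alignment objective (referred to as P1 throughout) is

    max over valid paths z:
        sum of vertex potentials along z
        + (edge_weight / L) * sum over ordered pairs of distinct match
                              cells of their edge potential,

with L the alignment length.  The quadratic term makes the problem
intractable, so it is split by duplicating the path indicators (z, y),
augmenting with a quadratic penalty rho/2 * ||z - y||^2, and alternating
two dynamic-programming subproblems (solve y with z fixed, then z with y
fixed) coupled by Lagrange multipliers updated by lambda += rho * (z - y).
Because the indicators are binary, every term of the augmented Lagrangian
is linear in the free variable, so each subproblem is a plain 3-state
Viterbi pass over adjusted vertex scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._dp import I_S, I_T, M, NEG, viterbi_kernel
from .node_potential import STATES, ScoreBundle

STATE_NAMES = {M: "M", I_T: "I_T", I_S: "I_S"}


@dataclass
class AlignmentPath:
    """Monotone path of (i, j, state) triples over the alignment lattice.

    Positions are 1-based consumed-column counters, as in the lattice: an
    M triple (i, j, 'M') aligns T column i-1 with S column j-1 (0-based).
    """

    triples: list[tuple[int, int, str]]
    score: float | None = None

    @property
    def L(self) -> int:
        return len(self.triples)

    @property
    def aligned_pairs(self) -> list[tuple[int, int]]:
        """0-based matched column pairs."""
        return [(i - 1, j - 1) for i, j, u in self.triples if u == "M"]

    def validate(self, nT: int, nS: int) -> None:
        pi, pj = 0, 0
        prev = None
        for i, j, u in self.triples:
            if u == "M":
                ok = i == pi + 1 and j == pj + 1
            elif u == "I_T":
                ok = i == pi + 1 and j == pj
            elif u == "I_S":
                ok = i == pi and j == pj + 1
            else:
                raise ValueError(f"unknown state {u!r}")
            if not ok:
                raise ValueError(f"non-monotone step to ({i}, {j}, {u})")
            if prev == "I_S" and u == "I_T":
                raise ValueError("I_S -> I_T transition is not allowed")
            pi, pj, prev = i, j, u
        if (pi, pj) != (nT, nS):
            raise ValueError(f"path ends at ({pi}, {pj}), expected ({nT}, {nS})")


@dataclass
class Indicators:
    """Binary indicator arrays of one path over all lattice vertices."""

    zm: np.ndarray  # (nT, nS)     match cell (i-1, j-1)
    zt: np.ndarray  # (nT, nS+1)   I_T vertex at lattice (i, j)
    zs: np.ndarray  # (nT+1, nS)   I_S vertex at lattice (i, j)
    cells: list[tuple[int, int]] = field(default_factory=list)

    def l1_diff(self, other: "Indicators") -> int:
        return int(
            np.abs(self.zm - other.zm).sum()
            + np.abs(self.zt - other.zt).sum()
            + np.abs(self.zs - other.zs).sum()
        )


def path_to_indicators(path: AlignmentPath, nT: int, nS: int) -> Indicators:
    zm = np.zeros((nT, nS))
    zt = np.zeros((nT, nS + 1))
    zs = np.zeros((nT + 1, nS))
    cells = []
    for i, j, u in path.triples:
        if u == "M":
            zm[i - 1, j - 1] = 1.0
            cells.append((i - 1, j - 1))
        elif u == "I_T":
            zt[i - 1, j] = 1.0
        else:
            zs[i, j - 1] = 1.0
    return Indicators(zm=zm, zt=zt, zs=zs, cells=cells)


def _run_viterbi(bundle: ScoreBundle) -> AlignmentPath:
    match, ins_t, ins_s, trans = bundle.grids()
    score, raw = viterbi_kernel(match, ins_t, ins_s, trans)
    triples = [(int(i), int(j), STATE_NAMES[int(u)]) for i, j, u in raw]
    return AlignmentPath(triples=triples, score=float(score))


def viterbi_align(bundle: ScoreBundle) -> AlignmentPath:
    """Maximum-score 3-state alignment without edge terms.

    Ties prefer M over I_T over I_S (the kernel's scan order).
    """
    for arr in (bundle.match, bundle.ins_t, bundle.ins_s):
        if not np.all(np.isfinite(arr)):
            raise ValueError("node scores must be finite")
    return _run_viterbi(bundle)


def path_node_score(path: AlignmentPath, bundle: ScoreBundle) -> float:
    """Vertex emissions plus transition biases along a path."""
    match, ins_t, ins_s, trans = bundle.grids()
    total = 0.0
    prev = None
    for i, j, u in path.triples:
        s = {"M": M, "I_T": I_T, "I_S": I_S}[u]
        if u == "M":
            total += match[i - 1, j - 1]
        elif u == "I_T":
            total += ins_t[i - 1, j]
        else:
            total += ins_s[i, j - 1]
        if prev is not None:
            total += trans[prev, s]
        prev = s
    return float(total)


def objective_p1(
    path: AlignmentPath,
    bundle: ScoreBundle,
    edge_table=None,
    L: int | None = None,
    edge_weight: float = 1.0,
) -> float:
    """Evaluate the quadratic alignment objective on a feasible path."""
    nT, nS = bundle.shape
    path.validate(nT, nS)
    if L is None:
        L = path.L
    if L < 1:
        raise ValueError("L must be >= 1")
    total = path_node_score(path, bundle)
    if edge_table is not None:
        # ordered-pair edge sum = twice the unordered sum (theta symmetric)
        total += (2.0 * edge_weight / L) * edge_table.path_edge_score(
            path.aligned_pairs
        )
    return float(total)


def _half_trans(trans: np.ndarray) -> np.ndarray:
    return np.where(trans > NEG / 2, 0.5 * trans, NEG)


def linearized_dp_scores(
    fixed: Indicators,
    lam: Indicators,
    rho: float,
    bundle: ScoreBundle,
    edge_table,
    L: int,
    lam_sign: float,
    edge_weight: float = 1.0,
) -> ScoreBundle:
    """Per-vertex effective scores for one subproblem.

    With the other copy fixed, every term of the augmented Lagrangian is
    linear in the free indicators: half the node score, the (1/L)-scaled
    edge interaction with the fixed match cells, the multiplier term
    (lam_sign -1 for the y-solve, +1 for the z-solve), and the expanded
    quadratic penalty rho * fixed - rho/2 per active vertex.
    """
    match, ins_t, ins_s, trans = bundle.grids()
    inter = (
        edge_table.interaction_sum(fixed.cells)
        if edge_table is not None
        else np.zeros_like(match)
    )
    eff_match = (
        0.5 * match
        + (edge_weight / L) * inter
        + rho * fixed.zm
        - rho / 2.0
        + lam_sign * lam.zm
    )
    eff_t = 0.5 * ins_t + rho * fixed.zt - rho / 2.0 + lam_sign * lam.zt
    eff_s = 0.5 * ins_s + rho * fixed.zs - rho / 2.0 + lam_sign * lam.zs
    return ScoreBundle(match=eff_match, ins_t=eff_t, ins_s=eff_s,
                       trans=_half_trans(trans))


@dataclass
class ADMMResult:
    alignment: AlignmentPath
    objective: float
    iterations: int
    converged: bool
    converged_at: int | None
    trace: list[dict]
    viterbi_objective: float


def _zero_indicators(nT: int, nS: int) -> Indicators:
    return Indicators(
        zm=np.zeros((nT, nS)), zt=np.zeros((nT, nS + 1)), zs=np.zeros((nT + 1, nS))
    )


def admm_align_scores(
    bundle: ScoreBundle,
    edge_table=None,
    rho: float = 0.5,
    max_iter: int = 50,
    edge_weight: float = 1.0,
) -> ADMMResult:
    """ADMM alignment given precomputed vertex scores.

    Initialization is the edge-free Viterbi alignment; each iteration
    solves the y-subproblem then the z-subproblem by DP, checks z == y,
    and otherwise refreshes L from the newest z alignment and takes a
    multiplier step lambda += rho * (z - y).  Returns the best feasible
    objective seen (initialization included), so the result never falls
    below the edge-free alignment's P1 value.
    """
    nT, nS = bundle.shape
    init = viterbi_align(bundle)
    viterbi_obj = objective_p1(init, bundle, edge_table, edge_weight=edge_weight)

    z = path_to_indicators(init, nT, nS)
    z_path = init
    L = init.L
    lam = _zero_indicators(nT, nS)
    best_path, best_obj = init, viterbi_obj
    trace: list[dict] = []
    converged = False
    converged_at: int | None = None
    iterations = 0

    for it in range(1, max_iter + 1):
        iterations = it
        y_bundle = linearized_dp_scores(
            z, lam, rho, bundle, edge_table, L, lam_sign=-1.0, edge_weight=edge_weight
        )
        y_path = _run_viterbi(y_bundle)
        y = path_to_indicators(y_path, nT, nS)

        z_bundle = linearized_dp_scores(
            y, lam, rho, bundle, edge_table, L, lam_sign=+1.0, edge_weight=edge_weight
        )
        z_path = _run_viterbi(z_bundle)
        z_new = path_to_indicators(z_path, nT, nS)

        for cand_path in (y_path, z_path):
            obj = objective_p1(cand_path, bundle, edge_table, edge_weight=edge_weight)
            if obj > best_obj:
                best_obj, best_path = obj, cand_path

        cross = (
            edge_table.cross_score(z_new.cells, y.cells) if edge_table is not None else 0.0
        )
        diff = z_new.l1_diff(y)
        lam_dot = float(
            (lam.zm * (z_new.zm - y.zm)).sum()
            + (lam.zt * (z_new.zt - y.zt)).sum()
            + (lam.zs * (z_new.zs - y.zs)).sum()
        )
        dual = (
            0.5 * path_node_score(z_path, bundle)
            + 0.5 * path_node_score(y_path, bundle)
            + (edge_weight / L) * cross
            + lam_dot
            - (rho / 2.0) * diff
        )
        trace.append(
            {"iteration": it, "objective": best_obj, "dual": dual,
             "disagreement": diff, "L": L}
        )
        z = z_new
        if diff == 0:
            converged = True
            converged_at = it
            break
        L = z_path.L
        lam.zm = lam.zm + rho * (z.zm - y.zm)
        lam.zt = lam.zt + rho * (z.zt - y.zt)
        lam.zs = lam.zs + rho * (z.zs - y.zs)

    # a converged pair (z == y) is itself feasible; prefer it if better
    if converged:
        obj = objective_p1(z_path, bundle, edge_table, edge_weight=edge_weight)
        if obj > best_obj:
            best_obj, best_path = obj, z_path

    best_path.validate(nT, nS)
    return ADMMResult(
        alignment=best_path,
        objective=best_obj,
        iterations=iterations,
        converged=converged,
        converged_at=converged_at,
        trace=trace,
        viterbi_objective=viterbi_obj,
    )


def admm_align(
    T,
    S,
    scorer,
    edge_table=None,
    rho: float = 0.5,
    max_iter: int = 50,
    edge_weight: float = 1.0,
) -> ADMMResult:
    """Align two family models with the ADMM procedure."""
    bundle = scorer.score_bundle(T, S)
    return admm_align_scores(
        bundle, edge_table=edge_table, rho=rho, max_iter=max_iter,
        edge_weight=edge_weight,
    )
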