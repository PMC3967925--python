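"""Edge alignment potential.

The potential of matching edge (i, k) of family T to edge (j, l) of family
S is the expectation, under the two predicted distance distributions, of
the log-odds kernel

    kernel[d1, d2] = log( p_aligned[d1, d2] / (p_bg[d1] * p_bg[d2]) ).

Smoothing in the statistics keeps the kernel finite everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceStats


def edge_kernel(stats: DistanceStats, center: bool = False) -> np.ndarray:
    """nbins x nbins log-ratio kernel from aligned and background stats.

    With ``center=True`` the scalar expectation of the kernel under the
    background distributions is subtracted, so two background-distributed
    edges score exactly 0 instead of a negative constant (the same
    offset-the-background idea the node potential applies).
    """
    if np.any(stats.p_background <= 0) or np.any(stats.p_aligned <= 0):
        raise ValueError("stats must be strictly positive (smoothed)")
    kernel = np.log(
        stats.p_aligned / np.outer(stats.p_background, stats.p_background)
    )
    if center:
        kernel = kernel - stats.p_background @ kernel @ stats.p_background
    return kernel


def edge_potential(pt_ik: np.ndarray, ps_jl: np.ndarray, kernel: np.ndarray) -> float:
    """Expected kernel value under the two edge distance distributions."""
    pt_ik = np.asarray(pt_ik, dtype=float)
    ps_jl = np.asarray(ps_jl, dtype=float)
    if pt_ik.shape[0] != kernel.shape[0] or ps_jl.shape[0] != kernel.shape[1]:
        raise ValueError("distribution/kernel shape mismatch")
    return float(pt_ik @ kernel @ ps_jl)


@dataclass
class EdgePotentialTable:
    """Edge potentials for one family pair, with vectorized accessors.

    ``pt`` and ``ps`` are (n, n, nbins) predicted distance distributions
    for families T and S.  Interaction rows (the (nT, nS) matrix of
    potentials from one fixed match cell to all others, separation mask
    applied) are memoized because the ADMM inner loop revisits them.
    """

    pt: np.ndarray
    ps: np.ndarray
    kernel: np.ndarray
    min_separation: int = 6
    _row_cache: dict = field(default_factory=dict, repr=False)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pt.shape[0], self.ps.shape[0]

    def potential(self, i: int, k: int, j: int, l: int) -> float:
        """Potential of matching edge (i, k) in T with edge (j, l) in S."""
        return edge_potential(self.pt[i, k], self.ps[j, l], self.kernel)

    def interaction_from(self, i: int, j: int) -> np.ndarray:
        """(nT, nS) matrix m[k, l] = potential(i, k, j, l), zero where
        either side is closer than min_separation."""
        key = (i, j)
        cached = self._row_cache.get(key)
        if cached is not None:
            return cached
        nT, nS = self.shape
        m = (self.pt[i] @ self.kernel) @ self.ps[j].transpose(1, 0)
        sep = self.min_separation
        ti = np.abs(np.arange(nT) - i) >= sep
        sj = np.abs(np.arange(nS) - j) >= sep
        m = m * ti[:, None] * sj[None, :]
        self._row_cache[key] = m
        return m

    def interaction_sum(self, cells: list[tuple[int, int]]) -> np.ndarray:
        """(nT, nS) matrix of summed potentials to a set of match cells."""
        nT, nS = self.shape
        total = np.zeros((nT, nS))
        for i, j in cells:
            total += self.interaction_from(i, j)
        return total

    def path_edge_score(self, cells: list[tuple[int, int]]) -> float:
        """Sum of potentials over unordered pairs of match cells."""
        total = 0.0
        for a, (i, j) in enumerate(cells):
            row = self.interaction_from(i, j)
            for k, l in cells[a + 1 :]:
                total += row[k, l]
        return total

    def cross_score(self, cells_a: list[tuple[int, int]],
                    cells_b: list[tuple[int, int]]) -> float:
        """Sum over ordered pairs (u in a, v in b) of potentials."""
        total = 0.0
        for i, j in cells_a:
            row = self.interaction_from(i, j)
            for k, l in cells_b:
                total += row[k, l]
        return total


def build_edge_table(
    model_t, model_s, predictor, stats: DistanceStats, center: bool = True,
) -> EdgePotentialTable:
    """Predict per-edge distance distributions and assemble the table.

    The kernel is background-centered by default: otherwise the large
    shared negative offset of near-background predictions penalizes every
    match pair uniformly and drowns the discriminative part.
    """
    from .distances import predict_edge_tensor

    return EdgePotentialTable(
        pt=predict_edge_tensor(model_t, predictor),
        ps=predict_edge_tensor(model_s, predictor),
        kernel=edge_kernel(stats, center=center),
        min_separation=max(model_t.min_separation, model_s.min_separation),
    )
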