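"""Markov random field family models.

A family model keeps, per node (MSA column), the empirical marginal over
the 21-letter alphabet, and, per node pair, interaction-strength features:
the mutual-information matrix and its matrix powers.  Explicit pairwise
potential fitting is not performed; the MI power series stands in for
interaction strength.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator

import numpy as np

from .alphabet import NSYM, onehot_rows
from .msa_io import MSA, ColumnMarginals, column_marginals, henikoff_weights

FORMAT_VERSION = 1

DEFAULT_MAX_POWER = 11
DEFAULT_MIN_SEPARATION = 6
DEFAULT_CONTEXT_WINDOW = 5


@dataclass
class ProfileContext:
    """Marginal rows for columns i-w..i+w; out-of-range rows are all zero."""

    matrix: np.ndarray  # (2w+1, 21)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != NSYM:
            raise ValueError("context must be (2w+1, 21)")
        if self.matrix.shape[0] % 2 != 1:
            raise ValueError("context must have an odd number of rows")

    @property
    def window(self) -> int:
        return (self.matrix.shape[0] - 1) // 2

    def flat(self) -> np.ndarray:
        return self.matrix.ravel()


def mutual_information(
    msa: MSA,
    weights: np.ndarray | None = None,
    pseudocount_weight: float = 1.0,
) -> np.ndarray:
    """Column-pair mutual information over the 21-letter alphabet.

    Joint distributions get the same pseudocount mass as the marginals,
    spread uniformly over the 21x21 joint; marginals are obtained by
    marginalizing the (smoothed) joint so MI >= 0 holds exactly up to
    floating point.  The diagonal is set to 0 by convention.
    """
    codes = msa.codes()
    nseq, ncol = codes.shape
    if weights is None:
        weights = np.ones(nseq)
    weights = np.asarray(weights, dtype=float)

    onehot = onehot_rows(codes)  # (nseq, ncol, 21)
    flat = (onehot * weights[:, None, None]).reshape(nseq, ncol * NSYM)
    # joint[i, a, k, b] = sum_s w_s * onehot[s,i,a] * onehot[s,k,b]
    joint = (flat.T @ onehot.reshape(nseq, ncol * NSYM)).reshape(
        ncol, NSYM, ncol, NSYM
    )
    wsum = weights.sum()
    pc = pseudocount_weight
    joint = (joint + pc / (NSYM * NSYM)) / (wsum + pc)

    pi = joint.sum(axis=3)  # (ncol, 21, ncol): marginal of i within pair (i,k)
    pk = joint.sum(axis=1)  # (ncol, ncol, 21): marginal of k within pair (i,k)
    outer = pi[:, :, :, None] * pk[:, None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        term = joint * np.log(joint / outer)
    term[joint <= 0] = 0.0
    mi = term.sum(axis=(1, 3))
    mi = 0.5 * (mi + mi.T)
    np.fill_diagonal(mi, 0.0)
    return mi


def mi_power_series(mi: np.ndarray, max_power: int = DEFAULT_MAX_POWER) -> list[np.ndarray]:
    """[MI^1, MI^2, ..., MI^max_power] by repeated matrix multiplication."""
    if max_power < 1:
        raise ValueError("max_power must be >= 1")
    mi = np.asarray(mi, dtype=float)
    if mi.ndim != 2 or mi.shape[0] != mi.shape[1]:
        raise ValueError("mi must be square")
    powers = [mi.copy()]
    for _ in range(max_power - 1):
        powers.append(powers[-1] @ mi)
    return powers


@dataclass
class MRFModel:
    """One family's MRF: node marginals plus MI-power interaction features."""

    marginals: ColumnMarginals
    mi_powers: list[np.ndarray]
    min_separation: int = DEFAULT_MIN_SEPARATION
    context_window: int = DEFAULT_CONTEXT_WINDOW
    name: str = ""

    @property
    def ncol(self) -> int:
        return self.marginals.ncol

    @property
    def mi(self) -> np.ndarray:
        return self.mi_powers[0]

    def profile_context(self, i: int, w: int | None = None) -> ProfileContext:
        if w is None:
            w = self.context_window
        n = self.ncol
        if not 0 <= i < n:
            raise IndexError(f"column {i} out of range 0..{n - 1}")
        mat = np.zeros((2 * w + 1, NSYM))
        lo, hi = max(0, i - w), min(n, i + w + 1)
        mat[lo - (i - w) : hi - (i - w)] = self.marginals.probs[lo:hi]
        return ProfileContext(matrix=mat)

    def context_features(self, w: int | None = None) -> np.ndarray:
        """All flattened profile contexts stacked, shape (ncol, (2w+1)*21)."""
        if w is None:
            w = self.context_window
        return np.stack([self.profile_context(i, w).flat() for i in range(self.ncol)])

    def edge_iter(self) -> Iterator[tuple[int, int]]:
        """Node pairs (i, k), i < k, with separation >= min_separation."""
        for i in range(self.ncol):
            for k in range(i + self.min_separation, self.ncol):
                yield i, k

    def mi_features(self, i: int, k: int, normalized: bool = False) -> np.ndarray:
        """Interaction-strength feature vector (MI^1..MI^K)[i, k].

        Higher matrix powers grow geometrically; ``normalized=True``
        z-scores each power against its family-wide off-diagonal
        distribution, so the features are O(1), comparable across
        families, and measure how exceptional a pair's interaction is
        within its own family.
        """
        v = np.array([p[i, k] for p in self.mi_powers])
        if normalized:
            mean, std = self.mi_feature_scales()
            v = (v - mean) / std
        return v

    def mi_feature_scales(self) -> tuple[np.ndarray, np.ndarray]:
        """Off-diagonal mean and std of each MI power (cached)."""
        if not hasattr(self, "_mi_scales"):
            n = self.ncol
            mask = ~np.eye(n, dtype=bool)
            mean = np.array([p[mask].mean() for p in self.mi_powers])
            std = np.array([max(p[mask].std(), 1e-12) for p in self.mi_powers])
            self._mi_scales = (mean, std)
        return self._mi_scales


def build_mrf(
    msa: MSA,
    w: int = DEFAULT_CONTEXT_WINDOW,
    max_power: int = DEFAULT_MAX_POWER,
    min_separation: int = DEFAULT_MIN_SEPARATION,
    pc: float = 1.0,
    seq_weighting: str = "henikoff",
    name: str = "",
) -> MRFModel:
    """Build the family model from an aligned MSA."""
    marginals = column_marginals(msa, pseudocount_weight=pc, seq_weighting=seq_weighting)
    if seq_weighting == "henikoff" and msa.nseq > 1:
        weights = henikoff_weights(msa.codes())
    else:
        weights = np.ones(msa.nseq)
    mi = mutual_information(msa, weights=weights, pseudocount_weight=pc)
    powers = mi_power_series(mi, max_power)
    return MRFModel(
        marginals=marginals,
        mi_powers=powers,
        min_separation=min_separation,
        context_window=w,
        name=name,
    )


def save_mrf(model: MRFModel, path: str | Path) -> None:
    np.savez_compressed(
        path,
        format_version=FORMAT_VERSION,
        probs=model.marginals.probs,
        neff=model.marginals.neff,
        mi_powers=np.stack(model.mi_powers),
        min_separation=model.min_separation,
        context_window=model.context_window,
        name=model.name,
    )


def load_mrf(path: str | Path) -> MRFModel:
    with np.load(path, allow_pickle=False) as data:
        version = int(data["format_version"])
        if version > FORMAT_VERSION:
            raise ValueError(f"unsupported model format version {version}")
        marginals = ColumnMarginals(probs=data["probs"], neff=float(data["neff"]))
        return MRFModel(
            marginals=marginals,
            mi_powers=list(data["mi_powers"]),
            min_separation=int(data["min_separation"]),
            context_window=int(data["context_window"]),
            name=str(data["name"]),
        )
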