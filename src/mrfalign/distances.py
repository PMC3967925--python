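"""Inter-residue distance discretization, reference statistics, and the
per-edge distance-distribution predictor.

Distances are binned into the intervals <4, [4,5), [5,6), ..., [14,15),
>=15 Angstrom (13 bins with the default boundaries; left-closed).  The
representative atom when reading coordinates from PDB is C-beta, falling
back to C-alpha for glycine or when C-beta is absent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import NSYM
from .mrf import MRFModel, ProfileContext

FORMAT_VERSION = 1

DEFAULT_EDGES = tuple(float(x) for x in range(4, 16))  # 4..15 -> 13 bins


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class DistanceBins:
    """Ordered boundaries; bin 0 is open below, the last bin open above."""

    edges: tuple[float, ...] = DEFAULT_EDGES

    def __post_init__(self) -> None:
        if len(self.edges) < 1 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("bin boundaries must be strictly increasing")

    @property
    def nbins(self) -> int:
        return len(self.edges) + 1

    def labels(self) -> list[str]:
        labels = [f"<{self.edges[0]:g}"]
        labels += [f"[{a:g},{b:g})" for a, b in zip(self.edges, self.edges[1:])]
        labels.append(f">={self.edges[-1]:g}")
        return labels


def bin_of(distance, bins: DistanceBins = DistanceBins()):
    """Bin index of a distance (scalar or array); intervals are [lo, hi)."""
    arr = np.asarray(distance, dtype=float)
    if np.any(arr < 0):
        raise ValueError("distance must be >= 0")
    idx = np.searchsorted(np.asarray(bins.edges), arr, side="right")
    return idx if arr.ndim else int(idx)


@dataclass
class DistanceStats:
    """Background P(d) and aligned-pair P(d1, d2) over distance bins."""

    p_background: np.ndarray
    p_aligned: np.ndarray
    bins: DistanceBins = field(default_factory=DistanceBins)
    background_counts: np.ndarray | None = None
    aligned_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.p_background = np.asarray(self.p_background, dtype=float)
        self.p_aligned = np.asarray(self.p_aligned, dtype=float)
        n = self.bins.nbins
        if self.p_background.shape != (n,) or self.p_aligned.shape != (n, n):
            raise ValueError("stats shapes do not match the bin schema")
        if abs(self.p_background.sum() - 1.0) > 1e-9 or abs(self.p_aligned.sum() - 1.0) > 1e-9:
            raise ValueError("distance statistics must be normalized")
        if np.any(self.p_background <= 0) or np.any(self.p_aligned <= 0):
            raise ValueError("smoothed statistics must be strictly positive")


def pairwise_distances(coords: np.ndarray) -> np.ndarray:
    coords = np.asarray(coords, dtype=float)
    diff = coords[:, None, :] - coords[None, :, :]
    return np.sqrt((diff**2).sum(axis=2))


def count_background(
    structures: list[np.ndarray],
    bins: DistanceBins = DistanceBins(),
    min_separation: int = 6,
    alpha: float = 1.0,
) -> DistanceStats:
    """Binned distance histogram over all pairs with |i-k| >= min_separation.

    Laplace-smoothed with ``alpha`` and normalized.  The aligned table of
    the returned stats is a placeholder (outer product); use
    :func:`count_aligned` to fill it from reference alignments.
    """
    if not structures:
        raise DataError("empty structure set")
    counts = np.zeros(bins.nbins)
    for coords in structures:
        coords = np.asarray(coords, dtype=float)
        n = len(coords)
        d = pairwise_distances(coords)
        iu, ku = np.triu_indices(n, k=max(min_separation, 1))
        np.add.at(counts, bin_of(d[iu, ku], bins), 1.0)
    p = counts + alpha
    p /= p.sum()
    aligned = np.outer(p, p)
    return DistanceStats(
        p_background=p, p_aligned=aligned / aligned.sum(), bins=bins,
        background_counts=counts,
    )


def count_aligned(
    reference_pairs: list[tuple[np.ndarray, np.ndarray, "ReferenceAlignment"]],
    bins: DistanceBins = DistanceBins(),
    min_separation: int = 6,
    alpha: float = 1.0,
) -> np.ndarray:
    """Joint histogram P(d_T, d_S) over co-aligned residue pairs.

    For aligned positions i<->j and k<->l with both-side separation at
    least ``min_separation``, cell (bin(d_ik), bin(d_jl)) is incremented
    (rows index the first family's bin, columns the second's).
    """
    counts = np.zeros((bins.nbins, bins.nbins))
    for coords_t, coords_s, ref in reference_pairs:
        coords_t = np.asarray(coords_t, dtype=float)
        coords_s = np.asarray(coords_s, dtype=float)
        pairs = ref.pairs
        for i, j in pairs:
            if i >= len(coords_t) or j >= len(coords_s):
                raise DataError("alignment index outside structure")
        for a, (i, j) in enumerate(pairs):
            for k, l in pairs[a + 1 :]:
                if abs(i - k) < min_separation or abs(j - l) < min_separation:
                    continue
                b1 = bin_of(float(np.linalg.norm(coords_t[i] - coords_t[k])), bins)
                b2 = bin_of(float(np.linalg.norm(coords_s[j] - coords_s[l])), bins)
                counts[b1, b2] += 1.0
    p = counts + alpha
    return p / p.sum()


def build_distance_stats(
    structures: list[np.ndarray],
    reference_pairs: list[tuple[np.ndarray, np.ndarray, "ReferenceAlignment"]],
    bins: DistanceBins = DistanceBins(),
    min_separation: int = 6,
    alpha: float = 1.0,
) -> DistanceStats:
    stats = count_background(structures, bins, min_separation, alpha)
    aligned = count_aligned(reference_pairs, bins, min_separation, alpha)
    return DistanceStats(
        p_background=stats.p_background,
        p_aligned=aligned,
        bins=bins,
        background_counts=stats.background_counts,
    )


# -- predictor ---------------------------------------------------------


@dataclass
class DistancePredictor:
    """Softmax net mapping (context_i, context_k, MI features) to a
    distance-bin distribution for the node pair (i, k)."""

    window: int = 5
    n_mi_features: int = 11
    hidden: int = 16
    nbins: int = DistanceBins().nbins
    W1: np.ndarray | None = None
    b1: np.ndarray | None = None
    W2: np.ndarray | None = None
    b2: np.ndarray | None = None
    use_mi: bool = True

    def __post_init__(self) -> None:
        d = self.input_dim
        if self.W1 is None:
            self.W1 = np.zeros((self.hidden, d))
        if self.b1 is None:
            self.b1 = np.zeros(self.hidden)
        if self.W2 is None:
            self.W2 = np.zeros((self.nbins, self.hidden))
        if self.b2 is None:
            self.b2 = np.zeros(self.nbins)

    @property
    def context_dim(self) -> int:
        return (2 * self.window + 1) * NSYM

    @property
    def input_dim(self) -> int:
        # contexts + center-column co-occurrence cross + MI features
        # + log sequence separation
        return 2 * self.context_dim + NSYM + self.n_mi_features + 1

    def predict_batch(self, X: np.ndarray) -> np.ndarray:
        if not self.use_mi and self.n_mi_features:
            X = X.copy()
            X[:, -(self.n_mi_features + 1) : -1] = 0.0
        h = np.tanh(X @ self.W1.T + self.b1)
        logits = h @ self.W2.T + self.b2
        logits -= logits.max(axis=1, keepdims=True)
        p = np.exp(logits)
        p /= p.sum(axis=1, keepdims=True)
        if not np.all(np.isfinite(p)):
            raise FloatingPointError("unnormalizable predictor output")
        return p


def _cross_term(ctx_i: np.ndarray, ctx_k: np.ndarray, window: int) -> np.ndarray:
    """Elementwise product of the two focal-column marginals: makes letter
    co-occurrence (e.g. paired marker residues) linearly readable."""
    center = window * NSYM
    return ctx_i[center : center + NSYM] * ctx_k[center : center + NSYM]


def edge_feature_vector(model: MRFModel, i: int, k: int,
                        window: int, n_mi_features: int) -> np.ndarray:
    """Predictor input for node pair (i, k): two contexts, the focal-column
    co-occurrence cross, normalized MI features, and log separation."""
    ctx_i = model.profile_context(i, window).flat()
    ctx_k = model.profile_context(k, window).flat()
    cross = _cross_term(ctx_i, ctx_k, window)
    mi = model.mi_features(i, k, normalized=True)[:n_mi_features]
    sep = np.array([np.log1p(abs(k - i))])
    return np.concatenate([ctx_i, ctx_k, cross, mi, sep])


def edge_features(model: MRFModel, i: int, k: int,
                  predictor: DistancePredictor) -> np.ndarray:
    return edge_feature_vector(model, i, k, predictor.window,
                               predictor.n_mi_features)


def predict_edge_distribution(
    model: DistancePredictor,
    context_i: ProfileContext,
    context_k: ProfileContext,
    mi_features: np.ndarray,
    separation: int = 0,
) -> np.ndarray:
    """Normalized distance-bin distribution for one node pair."""
    ci, ck = context_i.flat(), context_k.flat()
    x = np.concatenate(
        [ci, ck, _cross_term(ci, ck, model.window),
         np.asarray(mi_features, dtype=float)[: model.n_mi_features],
         [np.log1p(abs(separation))]]
    )
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite predictor features")
    return model.predict_batch(x[None, :])[0]


def predict_edge_tensor(model: MRFModel, predictor: DistancePredictor) -> np.ndarray:
    """Distributions for every node pair, shape (n, n, nbins).

    Computed once per unordered pair (i < k) and mirrored, so the tensor is
    exactly symmetric in its first two axes.  Pairs closer than the model's
    min_separation get the uniform distribution (they never enter edge
    scoring).
    """
    n = model.ncol
    C = model.context_features(predictor.window)
    out = np.full((n, n, predictor.nbins), 1.0 / predictor.nbins)
    pairs = [(i, k) for i in range(n)
             for k in range(i + model.min_separation, n)]
    if not pairs:
        return out
    K = predictor.n_mi_features
    mi_feats = np.stack(
        [model.mi_features(i, k, normalized=True)[:K] for i, k in pairs]
    )
    seps = np.array([[np.log1p(k - i)] for i, k in pairs])
    Ci = C[[i for i, _ in pairs]]
    Ck = C[[k for _, k in pairs]]
    center = predictor.window * NSYM
    cross = Ci[:, center : center + NSYM] * Ck[:, center : center + NSYM]
    X = np.concatenate([Ci, Ck, cross, mi_feats, seps], axis=1)
    probs = predictor.predict_batch(X)
    for (i, k), p in zip(pairs, probs):
        out[i, k] = p
        out[k, i] = p
    return out


def train_distance_predictor(
    X: np.ndarray,
    y_bins: np.ndarray,
    window: int = 5,
    n_mi_features: int = 11,
    hidden: int = 16,
    nbins: int = DistanceBins().nbins,
    epochs: int = 200,
    lr: float = 0.5,
    l2: float = 1e-4,
    seed: int = 0,
    use_mi: bool = True,
) -> DistancePredictor:
    """Cross-entropy fit of the distance predictor on (features, bin) data."""
    rng = np.random.default_rng(seed)
    pred = DistancePredictor(
        window=window, n_mi_features=n_mi_features, hidden=hidden,
        nbins=nbins, use_mi=use_mi,
    )
    d = pred.input_dim
    pred.W1 = rng.normal(0.0, 0.05, size=(hidden, d))
    pred.W2 = rng.normal(0.0, 0.05, size=(nbins, hidden))
    X = np.asarray(X, dtype=float)
    if not use_mi and n_mi_features:
        X = X.copy()
        X[:, -(n_mi_features + 1) : -1] = 0.0
    y = np.asarray(y_bins, dtype=int)
    n = len(X)
    onehot = np.zeros((n, nbins))
    onehot[np.arange(n), y] = 1.0

    def loss_and_grad(p: DistancePredictor):
        h = np.tanh(X @ p.W1.T + p.b1)
        logits = h @ p.W2.T + p.b2
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
        loss = -np.mean(np.log(probs[np.arange(n), y] + 1e-300))
        loss += l2 * (np.sum(p.W1**2) + np.sum(p.W2**2))
        dlogits = (probs - onehot) / n
        gW2 = dlogits.T @ h + 2 * l2 * p.W2
        gb2 = dlogits.sum(axis=0)
        dh = (dlogits @ p.W2) * (1.0 - h**2)
        gW1 = dh.T @ X + 2 * l2 * p.W1
        gb1 = dh.sum(axis=0)
        return loss, (gW1, gb1, gW2, gb2)

    loss, grad = loss_and_grad(pred)
    for _ in range(epochs):
        step = lr
        for _try in range(30):
            cand = DistancePredictor(
                window=window, n_mi_features=n_mi_features, hidden=hidden,
                nbins=nbins, use_mi=use_mi,
                W1=pred.W1 - step * grad[0], b1=pred.b1 - step * grad[1],
                W2=pred.W2 - step * grad[2], b2=pred.b2 - step * grad[3],
            )
            cand_loss, cand_grad = loss_and_grad(cand)
            if np.isfinite(cand_loss) and cand_loss <= loss:
                pred, loss, grad = cand, cand_loss, cand_grad
                lr = step * 1.2
                break
            step *= 0.5
        else:
            break
    return pred


# -- PDB / TSV plumbing ------------------------------------------------


def read_structure(path: str | Path, chain: str | None = None) -> np.ndarray:
    """One representative coordinate per residue from a PDB file.

    Uses C-beta where present, otherwise C-alpha (glycine has no C-beta).
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("s", str(path))
    model = next(structure.get_models())
    chains = list(model.get_chains())
    if chain is not None:
        chains = [c for c in chains if c.id == chain]
        if not chains:
            raise DataError(f"chain {chain!r} not found in {path}")
    coords = []
    for residue in chains[0].get_residues():
        if residue.id[0] != " ":
            continue
        atom = residue["CB"] if "CB" in residue else (
            residue["CA"] if "CA" in residue else None
        )
        if atom is not None:
            coords.append(atom.coord)
    if not coords:
        raise DataError(f"no usable residues in {path}")
    return np.asarray(coords, dtype=float)


def write_stats_tsv(stats: DistanceStats, path: str | Path) -> None:
    labels = stats.bins.labels()
    with open(path, "w") as fh:
        fh.write("# edges\t" + "\t".join(f"{e:g}" for e in stats.bins.edges) + "\n")
        fh.write("# background\n")
        fh.write("\t".join(f"{p:.12g}" for p in stats.p_background) + "\n")
        fh.write("# aligned (rows = T bin, cols = S bin); labels: "
                 + ",".join(labels) + "\n")
        for row in stats.p_aligned:
            fh.write("\t".join(f"{p:.12g}" for p in row) + "\n")


def read_stats_tsv(path: str | Path) -> DistanceStats:
    edges = None
    rows: list[list[float]] = []
    background = None
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# edges"):
                edges = tuple(float(x) for x in line.split("\t")[1:])
                continue
            if line.startswith("#"):
                continue
            values = [float(x) for x in line.split("\t")]
            if background is None:
                background = values
            else:
                rows.append(values)
    if edges is None or background is None or not rows:
        raise DataError(f"malformed stats file {path}")
    return DistanceStats(
        p_background=np.array(background),
        p_aligned=np.array(rows),
        bins=DistanceBins(edges=edges),
    )


def save_predictor(pred: DistancePredictor, path: str | Path) -> None:
    np.savez_compressed(
        path, format_version=FORMAT_VERSION, window=pred.window,
        n_mi_features=pred.n_mi_features, hidden=pred.hidden,
        nbins=pred.nbins, W1=pred.W1, b1=pred.b1, W2=pred.W2, b2=pred.b2,
        use_mi=pred.use_mi,
    )


def load_predictor(path: str | Path) -> DistancePredictor:
    with np.load(path, allow_pickle=False) as data:
        return DistancePredictor(
            window=int(data["window"]), n_mi_features=int(data["n_mi_features"]),
            hidden=int(data["hidden"]), nbins=int(data["nbins"]),
            W1=data["W1"], b1=data["b1"], W2=data["W2"], b2=data["b2"],
            use_mi=bool(data["use_mi"]),
        )
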