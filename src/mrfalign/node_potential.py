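"""Node alignment potential: neural vertex scorer trained on reference
alignments, offset by sampled background expectations.

The scorer assigns a log-likelihood to every lattice vertex: a match net
reads the concatenated profile contexts of the two candidate columns, and
two insertion nets read a single context each.  Training maximizes the
log-probability of reference alignments under the globally normalized
3-state lattice model (partition function by the forward algorithm), with
an L2 penalty.  After training, per-state background constants are set to
the mean net output over randomly sampled contexts and subtracted from
every potential.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from ._dp import I_S, I_T, M, forward_kernel, make_transitions, posterior_kernel
from .alphabet import GAP_INDEX, NSYM
from .mrf import MRFModel, ProfileContext

FORMAT_VERSION = 1

STATES = ("M", "I_T", "I_S")
STATE_INDEX = {"M": M, "I_T": I_T, "I_S": I_S}


class TrainingError(RuntimeError):
    pass


@dataclass
class ReferenceAlignment:
    """Matched column pairs (0-based), strictly increasing in both indices."""

    pairs: list[tuple[int, int]]
    len_t: int
    len_s: int

    def __post_init__(self) -> None:
        prev_i, prev_j = -1, -1
        for i, j in self.pairs:
            if not (0 <= i < self.len_t and 0 <= j < self.len_s):
                raise ValueError(f"pair ({i}, {j}) out of range")
            if i <= prev_i or j <= prev_j:
                raise ValueError("reference pairs must be strictly increasing")
            prev_i, prev_j = i, j

    def to_triples(self) -> list[tuple[int, int, str]]:
        """Full path: unaligned T columns precede unaligned S columns
        between consecutive matches (canonical gap ordering)."""
        triples: list[tuple[int, int, str]] = []
        ti, sj = 0, 0
        for i, j in self.pairs:
            while ti < i:
                ti += 1
                triples.append((ti, sj, "I_T"))
            while sj < j:
                sj += 1
                triples.append((ti, sj, "I_S"))
            ti, sj = i + 1, j + 1
            triples.append((ti, sj, "M"))
        while ti < self.len_t:
            ti += 1
            triples.append((ti, sj, "I_T"))
        while sj < self.len_s:
            sj += 1
            triples.append((ti, sj, "I_S"))
        return triples


@dataclass
class ScoreBundle:
    """Precomputed vertex scores for one family pair.

    ``match`` is (nT, nS); insertion scores may be per-column vectors or
    full lattice grids ((nT, nS+1) / (nT+1, nS)).
    """

    match: np.ndarray
    ins_t: np.ndarray
    ins_s: np.ndarray
    trans: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.match.shape

    def grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
        """Expand insertion scores to full (nT, nS+1) / (nT+1, nS) grids."""
        nT, nS = self.match.shape
        ins_t = self.ins_t
        ins_s = self.ins_s
        if ins_t.ndim == 1:
            ins_t = np.broadcast_to(ins_t[:, None], (nT, nS + 1)).copy()
        if ins_s.ndim == 1:
            ins_s = np.broadcast_to(ins_s[None, :], (nT + 1, nS)).copy()
        return (
            np.ascontiguousarray(self.match, dtype=np.float64),
            np.ascontiguousarray(ins_t, dtype=np.float64),
            np.ascontiguousarray(ins_s, dtype=np.float64),
            np.ascontiguousarray(self.trans, dtype=np.float64),
        )


def log_partition(bundle: ScoreBundle) -> float:
    """log Z over all alignment paths (forward algorithm)."""
    match, ins_t, ins_s, trans = bundle.grids()
    logz, _ = forward_kernel(match, ins_t, ins_s, trans)
    return float(logz)


def _net_forward(W1, b1, W2, b2, X):
    h = np.tanh(X @ W1.T + b1)
    return h @ W2 + b2, h


def _zeros_net(hidden: int, dim: int, rng: np.random.Generator | None, scale: float):
    if rng is None:
        W1 = np.zeros((hidden, dim))
        W2 = np.zeros(hidden)
    else:
        W1 = rng.normal(0.0, scale, size=(hidden, dim))
        W2 = rng.normal(0.0, scale, size=hidden)
    return {"W1": W1, "b1": np.zeros(hidden), "W2": W2, "b2": np.zeros(1)}


@dataclass
class NodeScorer:
    """One-hidden-layer vertex scorer (tanh hidden, linear output)."""

    window: int = 5
    hidden: int = 20
    match_net: dict = field(default_factory=dict)
    ins_t_net: dict = field(default_factory=dict)
    ins_s_net: dict = field(default_factory=dict)
    trans_bias: np.ndarray = field(default_factory=lambda: np.zeros((3, 3)))
    background: np.ndarray = field(default_factory=lambda: np.zeros(3))
    l2_lambda: float = 0.1

    def __post_init__(self) -> None:
        d = self.context_dim
        if not self.match_net:
            self.match_net = _zeros_net(self.hidden, 2 * d, None, 0.0)
        if not self.ins_t_net:
            self.ins_t_net = _zeros_net(self.hidden, d, None, 0.0)
        if not self.ins_s_net:
            self.ins_s_net = _zeros_net(self.hidden, d, None, 0.0)

    @property
    def context_dim(self) -> int:
        return (2 * self.window + 1) * NSYM

    @classmethod
    def random_init(cls, window: int = 5, hidden: int = 20, seed: int = 0,
                    scale: float = 0.05, l2_lambda: float = 0.1) -> "NodeScorer":
        rng = np.random.default_rng(seed)
        d = (2 * window + 1) * NSYM
        return cls(
            window=window,
            hidden=hidden,
            match_net=_zeros_net(hidden, 2 * d, rng, scale),
            ins_t_net=_zeros_net(hidden, d, rng, scale),
            ins_s_net=_zeros_net(hidden, d, rng, scale),
            l2_lambda=l2_lambda,
        )

    # -- raw network outputs (no background offset) --------------------

    def raw_match(self, CT: np.ndarray, CS: np.ndarray) -> np.ndarray:
        """Match-net outputs for all column pairs; CT (nT,d), CS (nS,d)."""
        net = self.match_net
        d = self.context_dim
        hT = CT @ net["W1"][:, :d].T
        hS = CS @ net["W1"][:, d:].T
        h = np.tanh(hT[:, None, :] + hS[None, :, :] + net["b1"])
        return h @ net["W2"] + net["b2"][0]

    def raw_insert(self, C: np.ndarray, which: str) -> np.ndarray:
        net = self.ins_t_net if which == "I_T" else self.ins_s_net
        out, _ = _net_forward(net["W1"], net["b1"], net["W2"], net["b2"][0], C)
        return out

    # -- public scoring -------------------------------------------------

    def score_vertex(
        self,
        context_t: ProfileContext | None,
        context_s: ProfileContext | None,
        state: str,
    ) -> float:
        """Background-offset potential of a single vertex."""
        if state == "M":
            if context_t is None or context_s is None:
                raise ValueError("match state requires both contexts")
            out = self.raw_match(context_t.flat()[None, :], context_s.flat()[None, :])
            return float(out[0, 0] - self.background[M])
        if state == "I_T":
            if context_t is None:
                raise ValueError("I_T requires the T context")
            return float(self.raw_insert(context_t.flat()[None, :], "I_T")[0]
                         - self.background[I_T])
        if state == "I_S":
            if context_s is None:
                raise ValueError("I_S requires the S context")
            return float(self.raw_insert(context_s.flat()[None, :], "I_S")[0]
                         - self.background[I_S])
        raise ValueError(f"unknown state {state!r}")

    def score_bundle(self, T: MRFModel, S: MRFModel) -> ScoreBundle:
        CT = T.context_features(self.window)
        CS = S.context_features(self.window)
        return ScoreBundle(
            match=self.raw_match(CT, CS) - self.background[M],
            ins_t=self.raw_insert(CT, "I_T") - self.background[I_T],
            ins_s=self.raw_insert(CS, "I_S") - self.background[I_S],
            trans=make_transitions(self.trans_bias),
        )


@dataclass
class ProfileScorer:
    """Untrained fallback: log-average-odds of the two marginal columns.

    Not the trained scorer: it ignores context beyond the focal column and
    uses fixed gap costs.  It exists so alignment and search work without a
    training step.
    """

    gap_score: float = -1.0

    def score_bundle(self, T: MRFModel, S: MRFModel) -> ScoreBundle:
        bg = 1.0 / (NSYM - 1)
        pT = T.marginals.probs[:, :GAP_INDEX]
        pS = S.marginals.probs[:, :GAP_INDEX]
        pT = pT / pT.sum(axis=1, keepdims=True)
        pS = pS / pS.sum(axis=1, keepdims=True)
        match = np.log((pT @ pS.T) / bg)
        return ScoreBundle(
            match=match,
            ins_t=np.full(T.ncol, self.gap_score),
            ins_s=np.full(S.ncol, self.gap_score),
            trans=make_transitions(),
        )


# -- training ----------------------------------------------------------


def _ref_indicators(ref: ReferenceAlignment, nT: int, nS: int):
    """Vertex indicator arrays and transition counts of the reference path."""
    ind_m = np.zeros((nT, nS))
    ind_t = np.zeros(nT)
    ind_s = np.zeros(nS)
    tc = np.zeros((3, 3))
    prev = None
    for i, j, state in ref.to_triples():
        u = STATE_INDEX[state]
        if state == "M":
            ind_m[i - 1, j - 1] = 1.0
        elif state == "I_T":
            ind_t[i - 1] += 1.0
        else:
            ind_s[j - 1] += 1.0
        if prev is not None:
            tc[prev, u] += 1.0
        prev = u
    return ind_m, ind_t, ind_s, tc


def _pair_grad(scorer: NodeScorer, T: MRFModel, S: MRFModel,
               ref: ReferenceAlignment):
    """Log-likelihood of one reference alignment and its gradient."""
    d = scorer.context_dim
    CT = T.context_features(scorer.window)
    CS = S.context_features(scorer.window)
    nT, nS = T.ncol, S.ncol

    mnet, tnet, snet = scorer.match_net, scorer.ins_t_net, scorer.ins_s_net
    hT = CT @ mnet["W1"][:, :d].T
    hS = CS @ mnet["W1"][:, d:].T
    h_m = np.tanh(hT[:, None, :] + hS[None, :, :] + mnet["b1"])
    g_m = h_m @ mnet["W2"] + mnet["b2"][0]
    out_t, h_t = _net_forward(tnet["W1"], tnet["b1"], tnet["W2"], tnet["b2"][0], CT)
    out_s, h_s = _net_forward(snet["W1"], snet["b1"], snet["W2"], snet["b2"][0], CS)

    trans = make_transitions(scorer.trans_bias)
    bundle = ScoreBundle(match=g_m, ins_t=out_t, ins_s=out_s, trans=trans)
    match, grid_t, grid_s, trans64 = bundle.grids()
    logz, post, et = posterior_kernel(match, grid_t, grid_s, trans64)

    ind_m, ind_t, ind_s, tc = _ref_indicators(ref, nT, nS)
    ref_score = (
        float((ind_m * g_m).sum() + (ind_t * out_t).sum() + (ind_s * out_s).sum())
        + float((tc * np.where(np.isfinite(trans), trans, 0.0)).sum())
    )
    loglik = ref_score - float(logz)

    r_m = ind_m - post[M, 1:, 1:]
    r_t = ind_t - post[I_T, 1:, :].sum(axis=1)
    r_s = ind_s - post[I_S, :, 1:].sum(axis=0)
    grads = {}
    # match net
    dW2 = np.einsum("ij,ijh->h", r_m, h_m)
    dA = r_m[:, :, None] * (1.0 - h_m**2) * mnet["W2"]
    grads["match_net"] = {
        "W2": dW2,
        "b2": np.array([r_m.sum()]),
        "b1": dA.sum(axis=(0, 1)),
        "W1": np.concatenate(
            [np.einsum("ijh,id->hd", dA, CT), np.einsum("ijh,jd->hd", dA, CS)],
            axis=1,
        ),
    }
    for key, net, hid, X, r in (
        ("ins_t_net", tnet, h_t, CT, r_t),
        ("ins_s_net", snet, h_s, CS, r_s),
    ):
        dA1 = r[:, None] * (1.0 - hid**2) * net["W2"]
        grads[key] = {
            "W2": hid.T @ r,
            "b2": np.array([r.sum()]),
            "b1": dA1.sum(axis=0),
            "W1": dA1.T @ X,
        }
    grads["trans_bias"] = tc - et
    return loglik, grads


def _param_items(scorer: NodeScorer):
    for net_name in ("match_net", "ins_t_net", "ins_s_net"):
        net = getattr(scorer, net_name)
        for k in ("W1", "b1", "W2", "b2"):
            yield (net_name, k), net[k]
    yield ("trans_bias", None), scorer.trans_bias


def _objective_and_grad(scorer, training_pairs, l2):
    total = 0.0
    acc: dict = {}
    for T, S, ref in training_pairs:
        ll, grads = _pair_grad(scorer, T, S, ref)
        total += ll
        for net_name, g in grads.items():
            if net_name == "trans_bias":
                acc.setdefault(("trans_bias", None), np.zeros((3, 3)))
                acc[("trans_bias", None)] += g
            else:
                for k, v in g.items():
                    key = (net_name, k)
                    acc.setdefault(key, np.zeros_like(v))
                    acc[key] += v
    # L2 on all parameters
    for key, p in _param_items(scorer):
        total -= l2 * float(np.sum(p**2))
        acc[key] = acc.get(key, np.zeros_like(p)) - 2.0 * l2 * p
    return total, acc


def _apply_step(scorer: NodeScorer, grads: dict, lr: float) -> NodeScorer:
    new = copy.deepcopy(scorer)
    for net_name in ("match_net", "ins_t_net", "ins_s_net"):
        net = getattr(new, net_name)
        for k in ("W1", "b1", "W2", "b2"):
            net[k] = net[k] + lr * grads[(net_name, k)]
    new.trans_bias = new.trans_bias + lr * grads[("trans_bias", None)]
    # disallowed transition never trained
    new.trans_bias[I_S, I_T] = 0.0
    return new


def train_scorer(
    training_pairs: list[tuple[MRFModel, MRFModel, ReferenceAlignment]],
    l2_lambda: float = 0.1,
    epochs: int = 60,
    seed: int = 0,
    hidden: int = 20,
    lr: float = 0.5,
    n_background_samples: int = 10000,
    history: list | None = None,
) -> NodeScorer:
    """Fit the vertex scorer by maximizing reference-alignment likelihood.

    Full-batch gradient ascent with step halving, so the regularized loss
    is non-increasing epoch to epoch.  Backgrounds are sampled afterwards.
    """
    if not training_pairs:
        raise ValueError("need at least one training pair")
    window = training_pairs[0][0].context_window
    scorer = NodeScorer.random_init(
        window=window, hidden=hidden, seed=seed, l2_lambda=l2_lambda
    )
    obj, grads = _objective_and_grad(scorer, training_pairs, l2_lambda)
    if not np.isfinite(obj):
        raise TrainingError(f"non-finite initial loss: {obj}")
    if history is not None:
        history.append(-obj)
    for _ in range(epochs):
        step = lr
        for _try in range(40):
            cand = _apply_step(scorer, grads, step)
            cand_obj, cand_grads = _objective_and_grad(cand, training_pairs, l2_lambda)
            if np.isfinite(cand_obj) and cand_obj >= obj:
                scorer, obj, grads = cand, cand_obj, cand_grads
                lr = step * 1.2
                break
            step *= 0.5
        else:
            break  # no improving step at any size: converged
        if history is not None:
            history.append(-obj)
    if not np.isfinite(obj):
        raise TrainingError(f"non-finite training loss: {obj}")

    pool = [m.profile_context(i, window)
            for T, S, _ in training_pairs
            for m in (T, S)
            for i in range(m.ncol)]
    return estimate_background(scorer, pool, n_samples=n_background_samples, seed=seed)


def estimate_background(
    scorer: NodeScorer,
    pool: list[ProfileContext],
    n_samples: int = 10000,
    seed: int = 0,
) -> NodeScorer:
    """Set per-state backgrounds to mean net output over sampled contexts."""
    if not pool:
        raise ValueError("context pool is empty")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = np.random.default_rng(seed)
    X = np.stack([c.flat() for c in pool])
    idx_a = rng.integers(0, len(pool), size=n_samples)
    idx_b = rng.integers(0, len(pool), size=n_samples)
    new = copy.deepcopy(scorer)
    d = scorer.context_dim
    mnet = scorer.match_net
    pair_in = np.concatenate([X[idx_a], X[idx_b]], axis=1)
    out_m, _ = _net_forward(mnet["W1"], mnet["b1"], mnet["W2"], mnet["b2"][0], pair_in)
    idx_t = rng.integers(0, len(pool), size=n_samples)
    idx_s = rng.integers(0, len(pool), size=n_samples)
    new.background = np.array(
        [
            float(out_m.mean()),
            float(scorer.raw_insert(X[idx_t], "I_T").mean()),
            float(scorer.raw_insert(X[idx_s], "I_S").mean()),
        ]
    )
    return new


def alignment_posteriors(scorer: NodeScorer, T: MRFModel, S: MRFModel) -> np.ndarray:
    """Posterior P(column i of T matched to column j of S), shape (nT, nS)."""
    CT = T.context_features(scorer.window)
    CS = S.context_features(scorer.window)
    bundle = ScoreBundle(
        match=scorer.raw_match(CT, CS),
        ins_t=scorer.raw_insert(CT, "I_T"),
        ins_s=scorer.raw_insert(CS, "I_S"),
        trans=make_transitions(scorer.trans_bias),
    )
    match, grid_t, grid_s, trans = bundle.grids()
    _, post, _ = posterior_kernel(match, grid_t, grid_s, trans)
    return post[M, 1:, 1:]


def save_scorer(scorer: NodeScorer, path: str | Path) -> None:
    arrays = {"format_version": FORMAT_VERSION, "window": scorer.window,
              "hidden": scorer.hidden, "trans_bias": scorer.trans_bias,
              "background": scorer.background, "l2_lambda": scorer.l2_lambda}
    for name in ("match_net", "ins_t_net", "ins_s_net"):
        for k, v in getattr(scorer, name).items():
            arrays[f"{name}.{k}"] = v
    np.savez_compressed(path, **arrays)


def load_scorer(path: str | Path) -> NodeScorer:
    with np.load(path, allow_pickle=False) as data:
        nets = {}
        for name in ("match_net", "ins_t_net", "ins_s_net"):
            nets[name] = {k: data[f"{name}.{k}"] for k in ("W1", "b1", "W2", "b2")}
        return NodeScorer(
            window=int(data["window"]),
            hidden=int(data["hidden"]),
            match_net=nets["match_net"],
            ins_t_net=nets["ins_t_net"],
            ins_s_net=nets["ins_s_net"],
            trans_bias=data["trans_bias"],
            background=data["background"],
            l2_lambda=float(data["l2_lambda"]),
        )
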