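"""End-to-end assembly helpers on top of the synthetic generator.

These wire the modules together for benchmarking: train the distance
predictor and collect distance statistics from a held-out set of synthetic
pairs, then align and score an evaluation set.  Used by the ablation
harness, the acceptance checks, and the CLI.
"""

from __future__ import annotations

import numpy as np

from .aligner import admm_align
from .distances import (
    DistanceBins,
    DistanceStats,
    bin_of,
    build_distance_stats,
    edge_feature_vector,
    pairwise_distances,
    train_distance_predictor,
)
from .edge_potential import build_edge_table
from .evaluate import compare_alignments
from .mrf import MRFModel, build_mrf
from .node_potential import ProfileScorer
from .synthetic import SyntheticFamilyPair, generate_benchmark


def predictor_training_data(
    pairs: list[SyntheticFamilyPair],
    mrfs: list[tuple[MRFModel, MRFModel]],
    bins: DistanceBins = DistanceBins(),
    max_edges_per_family: int = 400,
    n_mi_features: int = 11,
    seed: int = 0,
):
    """(features, bin label) examples for the distance predictor.

    Features come from the family MRFs, labels from the true scaffold
    distances; edges are subsampled per family to bound the set size.
    """
    rng = np.random.default_rng(seed)
    X, y = [], []
    for pair, (mt, ms) in zip(pairs, mrfs):
        for model, coords in ((mt, pair.scaffold_t), (ms, pair.scaffold_s)):
            d = pairwise_distances(coords)
            edges = list(model.edge_iter())
            if len(edges) > max_edges_per_family:
                sel = rng.choice(len(edges), size=max_edges_per_family, replace=False)
                edges = [edges[a] for a in sel]
            for i, k in edges:
                X.append(
                    edge_feature_vector(
                        model, i, k, model.context_window, n_mi_features
                    )
                )
                y.append(bin_of(float(d[i, k]), bins))
    return np.stack(X), np.asarray(y)


def build_benchmark_assets(
    train_pairs: list[SyntheticFamilyPair],
    bins: DistanceBins = DistanceBins(),
    min_separation: int = 6,
    hidden: int = 24,
    epochs: int = 300,
    seed: int = 0,
    n_mi_features: int = 11,
    use_mi: bool = True,
):
    """Train the distance predictor and count distance statistics."""
    mrfs = [(build_mrf(p.msa_t), build_mrf(p.msa_s)) for p in train_pairs]
    X, y = predictor_training_data(
        train_pairs, mrfs, bins=bins, n_mi_features=n_mi_features, seed=seed
    )
    window = mrfs[0][0].context_window
    predictor = train_distance_predictor(
        X, y, window=window, n_mi_features=n_mi_features, hidden=hidden,
        nbins=bins.nbins, epochs=epochs, seed=seed, use_mi=use_mi,
    )
    structures = [c for p in train_pairs for c in (p.scaffold_t, p.scaffold_s)]
    refs = [(p.scaffold_t, p.scaffold_s, p.true_alignment) for p in train_pairs]
    stats = build_distance_stats(
        structures, refs, bins=bins, min_separation=min_separation
    )
    return predictor, stats


def align_pair(
    pair: SyntheticFamilyPair,
    scorer,
    predictor=None,
    stats: DistanceStats | None = None,
    rho: float = 0.5,
    max_iter: int = 50,
    edge_weight: float = 10.0,
    mrfs: tuple[MRFModel, MRFModel] | None = None,
):
    """Build the pair's MRFs, align, and score against the truth."""
    T, S = mrfs if mrfs is not None else (build_mrf(pair.msa_t), build_mrf(pair.msa_s))
    table = None
    if predictor is not None and stats is not None:
        table = build_edge_table(T, S, predictor, stats)
    result = admm_align(
        T, S, scorer, edge_table=table, rho=rho, max_iter=max_iter,
        edge_weight=edge_weight,
    )
    comparison = {
        k: compare_alignments(result.alignment, pair.true_alignment, offset=k)
        for k in (0, 4)
    }
    return result, comparison


def convergence_study(
    n_pairs: int = 100,
    seed: int = 42,
    rho: float = 0.5,
    max_iter: int = 50,
    params: dict | None = None,
    n_train: int = 8,
    scorer=None,
):
    """Convergence behavior of the ADMM aligner on a seeded benchmark.

    The first ``n_train`` generated pairs train the distance predictor and
    statistics; the remaining ``n_pairs`` are aligned with the full
    objective.  Returns per-pair records with the iteration at which the
    two indicator copies agreed (None when max_iter was exhausted).
    """
    defaults = {"n_seqs": 40, "indel_rate": 0.1,
                "coupling_strength": 0.6, "mutation_rate": 0.72}
    defaults.update(params or {})
    # family lengths spread over 40..80 via the parent length
    ss = np.random.SeedSequence(seed)
    total = n_pairs + n_train
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(total)]
    lengths = np.random.default_rng(seed).integers(45, 79, size=total)
    from .synthetic import generate_pair

    pairs = [
        generate_pair(n_parent=int(n), seed=s, **defaults)
        for n, s in zip(lengths, child_seeds)
    ]
    manifest = {"master_seed": seed, "n_pairs": total, "params": defaults,
                "pair_seeds": child_seeds, "parent_lengths": lengths.tolist()}
    train, eval_pairs = pairs[:n_train], pairs[n_train:]
    predictor, stats = build_benchmark_assets(train, seed=seed)
    scorer = scorer or ProfileScorer()
    records = []
    for pair in eval_pairs:
        result, comparison = align_pair(
            pair, scorer, predictor=predictor, stats=stats, rho=rho,
            max_iter=max_iter,
        )
        records.append(
            {
                "seed": pair.seed,
                "len_t": pair.msa_t.ncol,
                "len_s": pair.msa_s.ncol,
                "converged": result.converged,
                "converged_at": result.converged_at,
                "iterations": result.iterations,
                "objective": result.objective,
                "recall": comparison[0].recall,
            }
        )
    return records, manifest
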