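"""Reference-based alignment accuracy.

Precision is the fraction of predicted aligned positions that are correct;
recall is the fraction of reference-alignable positions recovered.  At
offset k, a predicted pair (i, j) counts as correct if the reference
aligns i to some j' with |j - j'| <= k (query-centric offset).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .node_potential import ReferenceAlignment


@dataclass
class AlignmentComparison:
    n_aligned: int
    n_alignable: int
    n_correct: int
    offset: int
    precision: float
    recall: float


def _as_pairs(predicted) -> list[tuple[int, int]]:
    if hasattr(predicted, "aligned_pairs"):
        return list(predicted.aligned_pairs)
    return list(predicted)


def compare_alignments(
    predicted,
    reference: ReferenceAlignment,
    offset: int = 0,
    symmetric: bool = False,
) -> AlignmentComparison:
    """Score predicted matched pairs against the reference.

    ``predicted`` may be an AlignmentPath or a list of 0-based (i, j)
    pairs.  With ``symmetric=True`` a hit within offset on either
    coordinate counts.
    """
    pairs = _as_pairs(predicted)
    ref_by_i = {i: j for i, j in reference.pairs}
    ref_by_j = {j: i for i, j in reference.pairs}
    for i, j in pairs:
        if not (0 <= i < reference.len_t and 0 <= j < reference.len_s):
            raise ValueError(f"predicted pair ({i}, {j}) outside family lengths")
    n_correct = 0
    for i, j in pairs:
        ok = i in ref_by_i and abs(j - ref_by_i[i]) <= offset
        if not ok and symmetric:
            ok = j in ref_by_j and abs(i - ref_by_j[j]) <= offset
        n_correct += bool(ok)
    n_aligned = len(pairs)
    n_alignable = len(reference.pairs)
    return AlignmentComparison(
        n_aligned=n_aligned,
        n_alignable=n_alignable,
        n_correct=n_correct,
        offset=offset,
        precision=n_correct / n_aligned if n_aligned else 0.0,
        recall=n_correct / n_alignable if n_alignable else 0.0,
    )


def ablation(
    configs,
    dataset,
    scorer,
    stats=None,
    predictor=None,
    rho: float = 0.5,
    max_iter: int = 50,
    edge_weight: float = 10.0,
    offsets=(0, 4),
) -> dict:
    """Mean alignment recall per configuration over a synthetic dataset.

    Configurations: ``node_only`` (no edge potential), ``node_edge`` (edge
    potential with the predictor's MI inputs zeroed), ``node_edge_mi``
    (full edge potential).  Returns per-config mean recall at each offset
    plus deltas against node_only.
    """
    import copy

    from .aligner import admm_align
    from .edge_potential import build_edge_table
    from .mrf import build_mrf

    results: dict = {}
    mrf_cache = [
        (build_mrf(p.msa_t), build_mrf(p.msa_s), p.true_alignment) for p in dataset
    ]
    for config in configs:
        if config not in ("node_only", "node_edge", "node_edge_mi"):
            raise ValueError(f"unknown config {config!r}")
        recalls = {k: [] for k in offsets}
        for T, S, ref in mrf_cache:
            if config == "node_only":
                table = None
            else:
                pred = predictor
                if config == "node_edge":
                    pred = copy.deepcopy(predictor)
                    pred.use_mi = False
                table = build_edge_table(T, S, pred, stats)
            res = admm_align(
                T, S, scorer, edge_table=table, rho=rho,
                max_iter=max_iter, edge_weight=edge_weight,
            )
            for k in offsets:
                recalls[k].append(compare_alignments(res.alignment, ref, offset=k).recall)
        results[config] = {f"recall_offset{k}": float(np.mean(v))
                           for k, v in recalls.items()}
    if "node_only" in results:
        base = results["node_only"]
        for config, row in results.items():
            for k in offsets:
                row[f"delta_offset{k}"] = (
                    row[f"recall_offset{k}"] - base[f"recall_offset{k}"]
                )
    return results
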