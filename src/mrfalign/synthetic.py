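"""Synthetic family-pair generator.

Stands in for all external data: a shared parent scaffold (self-avoiding
3D chain, 3.8 A steps) is perturbed into two family scaffolds with planted
insertions/deletions; sequences are sampled so that positions in spatial
contact mutate with coupled amino-acid preferences, planting mutual
information on contact pairs; the alignment induced by the shared parent
is the ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .alphabet import AMINO_ACIDS
from .msa_io import MSA, write_msa
from .node_potential import ReferenceAlignment

HYDROPHOBIC = [AMINO_ACIDS.index(c) for c in "ACFILMVW"]
POLAR = [a for a in range(20) if a not in HYDROPHOBIC]
# amino acids ordered from core-preferring to surface-preferring; burial
# depth is coded along this axis when assigning position preferences
BURIAL_ORDER = [AMINO_ACIDS.index(c) for c in "FILVWMACYQTHSGPRNDEK"]
# residues marking "interaction zones" (disulfide/salt-bridge-like):
# same-zone positions are pulled together during chain growth
ZONE_AA = [AMINO_ACIDS.index(c) for c in "CHWPGK"]


class GenerationError(RuntimeError):
    pass


@dataclass
class SyntheticFamilyPair:
    scaffold_t: np.ndarray
    scaffold_s: np.ndarray
    contacts_t: list[tuple[int, int]]
    contacts_s: list[tuple[int, int]]
    msa_t: MSA
    msa_s: MSA
    true_alignment: ReferenceAlignment
    seed: int
    params: dict = field(default_factory=dict)


def self_avoiding_chain(
    n: int,
    rng: np.random.Generator,
    step: float = 3.8,
    min_dist: float = 3.4,
    compactness: float = 0.6,
    zones: np.ndarray | None = None,
    zone_attraction: float = 1.2,
    max_restarts: int = 200,
    max_step_tries: int = 120,
) -> np.ndarray:
    """Random 3D chain with fixed step length and a hard-sphere clash rule.

    ``compactness`` biases each step toward the running centroid, giving
    globule-like chains with many long-range contacts (0 = pure random
    walk).  ``zones`` optionally labels positions (-1 = no zone); a
    position is additionally pulled toward the centroid of already-placed
    positions sharing its zone, planting sharp spatial clusters.
    """
    for _restart in range(max_restarts):
        coords = np.zeros((n, 3))
        failed = False
        for i in range(1, n):
            centroid = coords[:i].mean(axis=0)
            zone_centroid = None
            if zones is not None and zones[i] >= 0:
                mates = [p for p in range(i) if zones[p] == zones[i]]
                if mates:
                    zone_centroid = coords[mates].mean(axis=0)
            for _try in range(max_step_tries):
                # soften the bias as tries fail so a clash-free direction
                # always remains reachable
                soften = max(0.0, 1.0 - _try / 40.0)
                v = rng.normal(size=3)
                v /= np.linalg.norm(v)
                pull = centroid - coords[i - 1]
                norm = np.linalg.norm(pull)
                if norm > 1e-9:
                    v = v + soften * compactness * pull / norm
                if zone_centroid is not None:
                    zp = zone_centroid - coords[i - 1]
                    zn = np.linalg.norm(zp)
                    if zn > 1e-9:
                        v = v + soften * zone_attraction * zp / zn
                v *= step / np.linalg.norm(v)
                cand = coords[i - 1] + v
                d = np.linalg.norm(coords[: i - 1] - cand, axis=1) if i > 1 else None
                if d is None or d.min() >= min_dist:
                    coords[i] = cand
                    break
            else:
                failed = True
                break
        if not failed:
            return coords
    raise GenerationError(f"chain growth failed after {max_restarts} restarts")


def relax_zone_clusters(
    coords: np.ndarray,
    zones: np.ndarray,
    n_steps: int = 150,
    lr: float = 0.08,
    bond_length: float = 3.8,
    zone_target: float = 5.5,
    min_dist: float = 3.4,
) -> np.ndarray:
    """Gradient relaxation pulling same-zone positions into contact.

    Energy terms: harmonic bonds at ``bond_length`` between chain
    neighbors, attraction of same-zone pairs toward ``zone_target``, and
    soft excluded-volume repulsion below ``min_dist``.  Bond lengths are
    approximately preserved; the result is a chain with sharp spatial
    clusters of same-zone positions.
    """
    x = coords.copy()
    n = len(x)
    zone_pairs = [
        (i, k)
        for i in range(n)
        for k in range(i + 1, n)
        if zones[i] >= 0 and zones[i] == zones[k]
    ]
    for _ in range(n_steps):
        f = np.zeros_like(x)
        # chain bonds
        d = x[1:] - x[:-1]
        dist = np.linalg.norm(d, axis=1, keepdims=True)
        pull = (dist - bond_length) * d / np.maximum(dist, 1e-9)
        f[:-1] += pull
        f[1:] -= pull
        # zone attraction
        for i, k in zone_pairs:
            v = x[k] - x[i]
            dd = np.linalg.norm(v)
            if dd > zone_target:
                g = 0.4 * (dd - zone_target) * v / dd
                f[i] += g
                f[k] -= g
        # excluded volume
        diff = x[:, None, :] - x[None, :, :]
        dm = np.linalg.norm(diff, axis=2)
        np.fill_diagonal(dm, np.inf)
        close = dm < min_dist
        if close.any():
            with np.errstate(invalid="ignore"):
                rep = np.where(
                    close, (min_dist - dm) / np.maximum(dm, 1e-9), 0.0
                )
            f += (diff * rep[:, :, None]).sum(axis=1)
        x = x + lr * np.clip(f, -5.0, 5.0)
    return x


def _contacts(coords: np.ndarray, threshold: float, min_separation: int):
    n = len(coords)
    out = []
    for i in range(n):
        for k in range(i + min_separation, n):
            if np.linalg.norm(coords[i] - coords[k]) < threshold:
                out.append((i, k))
    return out


def _indel_plan(n_parent: int, indel_rate: float, rng: np.random.Generator):
    """Kept parent positions and insertion counts after each kept position."""
    kept = [p for p in range(n_parent) if rng.random() >= indel_rate / 2.0]
    if len(kept) < 2:
        kept = list(range(n_parent))
    inserts = [int(rng.random() < indel_rate / 2.0) for _ in kept]
    return kept, inserts


def _family_layout(kept, inserts, parent_coords, rng, jitter):
    """Column list (parent index or None for insertions) and coordinates."""
    columns: list[int | None] = []
    coords: list[np.ndarray] = []
    for idx, p in enumerate(kept):
        columns.append(p)
        coords.append(parent_coords[p] + rng.normal(0.0, jitter, size=3))
        for _ in range(inserts[idx]):
            columns.append(None)
            base = parent_coords[min(p + 1, len(parent_coords) - 1)]
            coords.append(0.5 * (parent_coords[p] + base) + rng.normal(0.0, jitter, size=3))
    return columns, np.asarray(coords)


def _sample_family_msa(
    columns: list[int | None],
    coupled_pairs: list[tuple[int, int]],
    preferred: dict[int, int],
    perm: np.ndarray,
    n_seqs: int,
    mutation_rate: float,
    coupling_strength: float,
    gap_rate: float,
    rng: np.random.Generator,
    gibbs_sweeps: int = 4,
) -> MSA:
    """Sample sequences from a pairwise model on the contact graph.

    Each position has a single-site preference (the preferred amino acid
    with probability 1 - mutation_rate, uniform otherwise); every coupled
    pair (i, k) contributes a compatibility bonus when letter_k = perm
    (letter_i) or vice versa.  Sequences are drawn by Gibbs sweeps from
    independent initialization, so covariation is planted on all coupled
    edges simultaneously.  coupling_strength scales the pair energy
    (0 = fully independent sampling).
    """
    ncol = len(columns)
    prefs = np.empty(ncol, dtype=int)
    for c, p in enumerate(columns):
        prefs[c] = preferred[p] if p is not None else rng.integers(0, 20)
    site = np.full((ncol, 20), mutation_rate / 20.0)
    site[np.arange(ncol), prefs] += 1.0 - mutation_rate
    log_site = np.log(site)

    neighbors: list[list[tuple[int, bool]]] = [[] for _ in range(ncol)]
    for i, k in coupled_pairs:
        neighbors[k].append((i, True))   # bonus when l_k == perm[l_i]
        neighbors[i].append((k, False))  # bonus when perm[l_i] == l_k
    inv_perm = np.argsort(perm)
    beta = 6.0 * coupling_strength

    rows = []
    for _s in range(n_seqs):
        # Gumbel-max sampling avoids per-site normalization
        letters = np.argmax(
            log_site + rng.gumbel(size=(ncol, 20)), axis=1
        )
        # sweeps run even at beta = 0 so different coupling strengths
        # differ only in the pair energy, not in the sampling schedule
        for _sweep in range(gibbs_sweeps):
            for c in range(ncol):
                logp = log_site[c].copy()
                for other, downstream in neighbors[c]:
                    if downstream:
                        logp[perm[letters[other]]] += beta
                    else:
                        logp[inv_perm[letters[other]]] += beta
                letters[c] = np.argmax(logp + rng.gumbel(size=20))
        seq = "".join(AMINO_ACIDS[a] for a in letters)
        if gap_rate > 0:
            gaps = rng.random(ncol) < gap_rate
            seq = "".join("-" if g else c for c, g in zip(seq, gaps))
        rows.append(seq)
    return MSA(sequences=rows)


def generate_pair(
    n_parent: int = 60,
    n_seqs: int = 50,
    indel_rate: float = 0.1,
    coupling_strength: float = 0.6,
    mutation_rate: float = 0.5,
    seed: int = 0,
    contact_threshold: float = 8.0,
    min_separation: int = 6,
    jitter: float = 0.5,
    gap_rate: float = 0.0,
    zone_frac: float = 0.0,
    compactness: float = 0.6,
    coupling_degree_cap: int = 999,
) -> SyntheticFamilyPair:
    """Generate two related families with a known true alignment."""
    if n_parent < 10:
        raise ValueError("n_parent must be >= 10")
    if n_seqs < 5:
        raise ValueError("n_seqs must be >= 5")
    rng = np.random.default_rng(seed)
    # interaction zones: a fraction of positions carry a zone label; the
    # chain generator pulls same-zone positions together and the zone is
    # coded by a dedicated marker residue, so sequence context predicts
    # proximity sharply (high-frequency along the chain)
    zones = np.where(
        rng.random(n_parent) < zone_frac,
        rng.integers(0, len(ZONE_AA), size=n_parent),
        -1,
    )
    parent = self_avoiding_chain(n_parent, rng, zones=zones,
                                 compactness=compactness)
    if (zones >= 0).any():
        parent = relax_zone_clusters(parent, zones)
    # burial coding: each position's preferred residue reflects its burial
    # percentile along BURIAL_ORDER (noisy), so profile contexts carry
    # genuine distance information (two core-coded positions are close)
    radius = np.linalg.norm(parent - parent.mean(axis=0), axis=1)
    pct = np.argsort(np.argsort(radius)) / max(n_parent - 1, 1)
    idx = np.clip(
        np.rint(pct * 19 + rng.normal(0.0, 1.5, size=n_parent)), 0, 19
    ).astype(int)
    preferred = {
        p: int(ZONE_AA[zones[p]]) if zones[p] >= 0 else int(BURIAL_ORDER[idx[p]])
        for p in range(n_parent)
    }
    # coupling permutation: cyclic shift along the burial axis, so planted
    # covariation perturbs but does not scramble the burial code
    perm = np.arange(20)
    for t, a in enumerate(BURIAL_ORDER):
        perm[a] = BURIAL_ORDER[(t + 1) % 20]

    kept_t, ins_t = _indel_plan(n_parent, indel_rate, rng)
    kept_s, ins_s = _indel_plan(n_parent, indel_rate, rng)
    cols_t, coords_t = _family_layout(kept_t, ins_t, parent, rng, jitter)
    cols_s, coords_s = _family_layout(kept_s, ins_s, parent, rng, jitter)

    contacts_t = _contacts(coords_t, contact_threshold, min_separation)
    contacts_s = _contacts(coords_s, contact_threshold, min_separation)

    # couple PARENT contact pairs, shared by both families, so the planted
    # covariation is homologous across them; degree-capped so the pair
    # energies do not drown the single-site preferences
    parent_contacts = _contacts(parent, contact_threshold, min_separation)
    coupled_parent = []
    degree = np.zeros(n_parent, dtype=int)
    for idx_p in rng.permutation(len(parent_contacts)):
        i, k = parent_contacts[idx_p]
        if degree[i] < coupling_degree_cap and degree[k] < coupling_degree_cap:
            coupled_parent.append((i, k))
            degree[i] += 1
            degree[k] += 1
    pos_t = {p: c for c, p in enumerate(cols_t) if p is not None}
    pos_s = {p: c for c, p in enumerate(cols_s) if p is not None}
    coupled_t = [(pos_t[p], pos_t[q]) for p, q in coupled_parent
                 if p in pos_t and q in pos_t]
    coupled_s = [(pos_s[p], pos_s[q]) for p, q in coupled_parent
                 if p in pos_s and q in pos_s]

    msa_t = _sample_family_msa(
        cols_t, coupled_t, preferred, perm, n_seqs,
        mutation_rate, coupling_strength, gap_rate, rng,
    )
    msa_s = _sample_family_msa(
        cols_s, coupled_s, preferred, perm, n_seqs,
        mutation_rate, coupling_strength, gap_rate, rng,
    )
    pairs = [(pos_t[p], pos_s[p]) for p in range(n_parent)
             if p in pos_t and p in pos_s]
    ref = ReferenceAlignment(pairs=pairs, len_t=len(cols_t), len_s=len(cols_s))

    return SyntheticFamilyPair(
        scaffold_t=coords_t, scaffold_s=coords_s,
        contacts_t=contacts_t, contacts_s=contacts_s,
        msa_t=msa_t, msa_s=msa_s, true_alignment=ref, seed=seed,
        params={
            "zones": zones.tolist(),
            "preferred": [preferred[p] for p in range(n_parent)],
            "cols_t": [(-1 if c is None else c) for c in cols_t],
            "cols_s": [(-1 if c is None else c) for c in cols_s],
            "n_parent": n_parent, "n_seqs": n_seqs, "indel_rate": indel_rate,
            "coupling_strength": coupling_strength, "mutation_rate": mutation_rate,
            "contact_threshold": contact_threshold, "min_separation": min_separation,
            "jitter": jitter, "gap_rate": gap_rate, "zone_frac": zone_frac,
            "compactness": compactness,
            "coupling_degree_cap": coupling_degree_cap,
        },
    )


def generate_homolog_group(
    n_members: int,
    n_parent: int = 60,
    n_seqs: int = 30,
    indel_rate: float = 0.1,
    coupling_strength: float = 0.6,
    mutation_rate: float = 0.5,
    seed: int = 0,
    contact_threshold: float = 8.0,
    min_separation: int = 6,
    jitter: float = 0.5,
    compactness: float = 0.6,
) -> list[MSA]:
    """Several homologous families sharing one parent scaffold.

    Used to build search libraries: all members descend from the same
    parent (same preferences and coupling graph), so every member is a
    true homolog of every other.
    """
    rng = np.random.default_rng(seed)
    parent = self_avoiding_chain(n_parent, rng, compactness=compactness)
    radius = np.linalg.norm(parent - parent.mean(axis=0), axis=1)
    pct = np.argsort(np.argsort(radius)) / max(n_parent - 1, 1)
    idx = np.clip(
        np.rint(pct * 19 + rng.normal(0.0, 1.5, size=n_parent)), 0, 19
    ).astype(int)
    preferred = {p: int(BURIAL_ORDER[idx[p]]) for p in range(n_parent)}
    perm = np.arange(20)
    for t, a in enumerate(BURIAL_ORDER):
        perm[a] = BURIAL_ORDER[(t + 1) % 20]
    coupled_parent = _contacts(parent, contact_threshold, min_separation)

    members = []
    for _m in range(n_members):
        kept, ins = _indel_plan(n_parent, indel_rate, rng)
        cols, _coords = _family_layout(kept, ins, parent, rng, jitter)
        pos = {p: c for c, p in enumerate(cols) if p is not None}
        coupled = [(pos[p], pos[q]) for p, q in coupled_parent
                   if p in pos and q in pos]
        members.append(
            _sample_family_msa(cols, coupled, preferred, perm, n_seqs,
                               mutation_rate, coupling_strength, 0.0, rng)
        )
    return members


def generate_benchmark(
    n_pairs: int = 100,
    params: dict | None = None,
    seed: int = 42,
) -> tuple[list[SyntheticFamilyPair], dict]:
    """A list of independent family pairs plus a regeneration manifest.

    Per-pair seeds are spawned from the master seed so the streams are
    independent and the manifest alone suffices to regenerate the set.
    """
    params = dict(params or {})
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0]) for s in ss.spawn(n_pairs)]
    pairs = [generate_pair(seed=s, **params) for s in child_seeds]
    manifest = {"master_seed": seed, "n_pairs": n_pairs, "params": params,
                "pair_seeds": child_seeds}
    return pairs, manifest


def write_pdb(coords: np.ndarray, path: str | Path, chain: str = "A") -> None:
    """Minimal CA-trace PDB file for a coordinate chain."""
    with open(path, "w") as fh:
        for i, (x, y, z) in enumerate(coords, start=1):
            fh.write(
                f"ATOM  {i:5d}  CA  ALA {chain}{i:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00           C\n"
            )
        fh.write("END\n")


def write_reference_tsv(ref: ReferenceAlignment, path: str | Path) -> None:
    """Matched column pairs, 1-based, with family lengths in the header."""
    with open(path, "w") as fh:
        fh.write(f"# len_t={ref.len_t}\tlen_s={ref.len_s}\n")
        fh.write("col_t\tcol_s\n")
        for i, j in ref.pairs:
            fh.write(f"{i + 1}\t{j + 1}\n")


def read_reference_tsv(path: str | Path) -> ReferenceAlignment:
    len_t = len_s = None
    pairs = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith("#"):
                for tok in line[1:].split():
                    if tok.startswith("len_t="):
                        len_t = int(tok[6:])
                    elif tok.startswith("len_s="):
                        len_s = int(tok[6:])
                continue
            if not line or line.startswith("col_t"):
                continue
            i, j = line.split("\t")[:2]
            pairs.append((int(i) - 1, int(j) - 1))
    if len_t is None or len_s is None:
        len_t = max(i for i, _ in pairs) + 1 if pairs else 1
        len_s = max(j for _, j in pairs) + 1 if pairs else 1
    return ReferenceAlignment(pairs=pairs, len_t=len_t, len_s=len_s)


def write_pair_to_dir(pair: SyntheticFamilyPair, outdir: str | Path, name: str) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_msa(pair.msa_t, outdir / f"{name}_T.fasta")
    write_msa(pair.msa_s, outdir / f"{name}_S.fasta")
    write_pdb(pair.scaffold_t, outdir / f"{name}_T.pdb")
    write_pdb(pair.scaffold_s, outdir / f"{name}_S.pdb")
    write_reference_tsv(pair.true_alignment, outdir / f"{name}_ref.tsv")
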