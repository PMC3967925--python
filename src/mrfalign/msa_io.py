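"""Reading and writing multiple sequence alignments, and column marginals.

Columns are 0-based everywhere inside the library; any user-facing output
(CLI tables, alignment TSVs) is 1-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .alphabet import ALPHABET, GAP_INDEX, NSYM, encode_sequence, onehot_rows


class MSAFormatError(ValueError):
    """Raised when an alignment file cannot be parsed into equal-length rows."""


class EmptyInputError(ValueError):
    """Raised for empty alignment files or zero-length sequences."""


@dataclass
class MSA:
    """An aligned protein family: equal-length rows over 20 aa + gap (+X)."""

    sequences: list[str]
    ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.sequences:
            raise EmptyInputError("alignment has no sequences")
        lengths = {len(s) for s in self.sequences}
        if lengths == {0}:
            raise EmptyInputError("alignment has zero columns")
        if len(lengths) != 1:
            raise MSAFormatError(f"unequal sequence lengths: {sorted(lengths)}")
        if not self.ids:
            self.ids = [f"seq{i + 1}" for i in range(len(self.sequences))]
        if len(self.ids) != len(self.sequences):
            raise MSAFormatError("ids and sequences differ in number")

    @property
    def ncol(self) -> int:
        return len(self.sequences[0])

    @property
    def nseq(self) -> int:
        return len(self.sequences)

    def codes(self) -> np.ndarray:
        """Integer-encoded alignment, shape (nseq, ncol)."""
        return np.stack([encode_sequence(s) for s in self.sequences])


@dataclass
class ColumnMarginals:
    """Per-column distributions over the 21-letter alphabet.

    ``probs`` has shape (ncol, 21); each row sums to 1.  ``neff`` is the
    effective number of sequences behind the estimate.
    """

    probs: np.ndarray
    neff: float

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.ndim != 2 or self.probs.shape[1] != NSYM:
            raise ValueError("probs must be (ncol, 21)")
        if np.any(self.probs < 0):
            raise ValueError("negative marginal probability")
        rowsums = self.probs.sum(axis=1)
        if np.any(np.abs(rowsums - 1.0) > 1e-9):
            raise ValueError("marginal rows must sum to 1")

    @property
    def ncol(self) -> int:
        return self.probs.shape[0]


def _read_records(path: Path) -> list[tuple[str, str]]:
    records: list[tuple[str, str]] = []
    header: str | None = None
    chunks: list[str] = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#") and header is None:
                continue  # a3m/HHsuite comment preamble
            if line.startswith(">"):
                if header is not None:
                    records.append((header, "".join(chunks)))
                header = line[1:].split()[0] or f"seq{len(records) + 1}"
                chunks = []
            elif line and header is not None:
                chunks.append(line.strip())
    if header is not None:
        records.append((header, "".join(chunks)))
    return records


def read_msa(path: str | Path, format: str = "fasta") -> MSA:
    """Read an aligned FASTA or A3M file.

    In A3M, lowercase letters mark insertion columns relative to the master
    sequence and are removed; the retained (uppercase/gap) columns must then
    agree in length across sequences.
    """
    path = Path(path)
    if format not in ("fasta", "a3m"):
        raise ValueError(f"unknown alignment format: {format!r}")
    records = _read_records(path)
    if not records:
        raise EmptyInputError(f"no sequences in {path}")
    ids, seqs = [], []
    for name, seq in records:
        if format == "a3m":
            seq = "".join(c for c in seq if not c.islower())
        ids.append(name)
        seqs.append(seq)
    return MSA(sequences=seqs, ids=ids)


def write_msa(msa: MSA, path: str | Path) -> None:
    """Write an aligned FASTA file (60-column wrapping)."""
    with open(path, "w") as fh:
        for name, seq in zip(msa.ids, msa.sequences):
            fh.write(f">{name}\n")
            for start in range(0, len(seq), 60):
                fh.write(seq[start : start + 60] + "\n")


def henikoff_weights(codes: np.ndarray) -> np.ndarray:
    """Position-based sequence weights, normalized to sum to nseq."""
    nseq, ncol = codes.shape
    w = np.zeros(nseq)
    for j in range(ncol):
        col = codes[:, j]
        vals, inverse, counts = np.unique(col, return_inverse=True, return_counts=True)
        r = len(vals)
        w += 1.0 / (r * counts[inverse])
    total = w.sum()
    if total <= 0:
        return np.ones(nseq)
    return w * (nseq / total)


def column_marginals(
    msa: MSA,
    pseudocount_weight: float = 1.0,
    seq_weighting: str = "henikoff",
    background: np.ndarray | None = None,
) -> ColumnMarginals:
    """Weighted column frequencies with additive background pseudocounts.

    probs[i, a] = (sum_s w_s * 1[row s has a at column i]
                   + pc * background[a]) / (sum_s w_s + pc)
    """
    if pseudocount_weight < 0:
        raise ValueError("pseudocount_weight must be >= 0")
    if seq_weighting not in ("none", "henikoff"):
        raise ValueError(f"unknown seq_weighting: {seq_weighting!r}")
    if background is None:
        background = np.full(NSYM, 1.0 / NSYM)
    background = np.asarray(background, dtype=float)

    codes = msa.codes()
    if seq_weighting == "henikoff" and msa.nseq > 1:
        weights = henikoff_weights(codes)
    else:
        weights = np.ones(msa.nseq)

    onehot = onehot_rows(codes)  # (nseq, ncol, 21)
    counts = np.einsum("s,sca->ca", weights, onehot)
    wsum = weights.sum()
    probs = (counts + pseudocount_weight * background) / (
        wsum + pseudocount_weight
    )
    probs /= probs.sum(axis=1, keepdims=True)
    neff = float(wsum**2 / np.sum(weights**2))
    return ColumnMarginals(probs=probs, neff=max(neff, 1.0))


def write_profile_tsv(marginals: ColumnMarginals, path: str | Path) -> None:
    """Profile table: one row per column (1-based), one column per symbol."""
    with open(path, "w") as fh:
        fh.write("col\t" + "\t".join(ALPHABET[:GAP_INDEX]) + "\tgap\n")
        for i, row in enumerate(marginals.probs, start=1):
            fh.write(f"{i}\t" + "\t".join(f"{p:.6g}" for p in row) + "\n")
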