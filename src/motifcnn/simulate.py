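"""Synthetic multi-label motif-occupancy sequences.

Each sequence is i.i.d. uniform random DNA of length L (default 200 nt)
into which k ~ Uniform{1..5} binding sites are embedded.  Sites are drawn
with replacement from the 24-member strand-motif pool (12 TFs x 2 strands)
and realised by sampling each position from the motif's probability matrix.
Placements keep a buffer of at least one background nucleotide between
sites and from both sequence ends.  The label is a 12-bit presence vector
per TF class (either strand).  Chance look-alikes arising in the random
background are deliberately *not* labelled, so the labels carry a small
false-negative rate, as in real peak-calling data.

Coordinates are 0-based, half-open everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .motifs import ALPHABET, MotifPool, Strand

_BASES = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)


@dataclass(frozen=True)
class EmbeddingRecord:
    """Ground truth for one embedded site (0-based, half-open)."""

    sequence_id: int
    motif_name: str
    strand: Strand
    start: int
    end: int


@dataclass
class SyntheticDataset:
    """One-hot sequences, binary labels, per-site ground truth and the split."""

    sequences: np.ndarray            # (N, 4, L) one-hot, float32, rows A,C,G,T
    labels: np.ndarray               # (N, n_classes) uint8
    embeddings: list[EmbeddingRecord]
    split: dict[str, np.ndarray]     # {"train","validation","test"} -> index arrays
    seed: int
    class_names: list[str] = field(default_factory=list)

    @property
    def n_sequences(self) -> int:
        return self.sequences.shape[0]

    @property
    def length(self) -> int:
        return self.sequences.shape[2]

    def subset(self, split: str) -> tuple[np.ndarray, np.ndarray]:
        idx = self.split[split]
        return self.sequences[idx], self.labels[idx]


def one_hot_encode(seq: str) -> np.ndarray:
    """Encode an ACGT string as a (4, L) binary matrix, rows A, C, G, T."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    code = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate(_BASES):
        code[b] = i
    idx = code[arr]
    if np.any(idx < 0):
        bad = seq[int(np.argmax(idx < 0))]
        raise ValueError(f"cannot one-hot encode character {bad!r}")
    out = np.zeros((4, len(seq)), dtype=np.float32)
    out[idx, np.arange(len(seq))] = 1.0
    return out


def one_hot_decode(mat: np.ndarray) -> str:
    """Inverse of :func:`one_hot_encode`."""
    mat = np.asarray(mat)
    if mat.shape[0] != 4 or not np.allclose(mat.sum(axis=0), 1.0):
        raise ValueError("not a valid one-hot matrix")
    return "".join(ALPHABET[i] for i in mat.argmax(axis=0))


class GenerationError(RuntimeError):
    pass


def _place(widths: Sequence[int], length: int, rng: np.random.Generator,
           max_tries: int = 1000) -> list[int]:
    """Sample non-overlapping start positions with >=1-nt buffers.

    Rejection sampling: draw all starts jointly, accept when every site
    keeps >= 1 nt from both ends and from every other site; after
    ``max_tries`` failures the draw is declared infeasible.
    """
    k = len(widths)
    for _ in range(max_tries):
        starts = [int(rng.integers(1, length - w)) for w in widths]
        order = np.argsort(starts)
        ok = True
        prev_end = 0
        for j in order:
            s, e = starts[j], starts[j] + widths[j]
            if s < prev_end + 1 or e > length - 1:
                ok = False
                break
            prev_end = e
        if ok:
            return starts
    raise GenerationError(
        f"could not place {k} sites of widths {list(widths)} in {length} nt"
    )


def generate_sequence(pool: MotifPool, length: int, rng: np.random.Generator,
                      min_motifs: int = 1, max_motifs: int = 5,
                      sequence_id: int = 0,
                      ) -> tuple[str, list[EmbeddingRecord], np.ndarray]:
    """Simulate one sequence; returns (DNA string, ground truth, label vector)."""
    if length < max_motifs * (pool.max_width + 1) + 1:
        raise ValueError("sequence too short to guarantee placement")
    k = int(rng.integers(min_motifs, max_motifs + 1))
    picks = [pool.motifs[int(i)] for i in rng.integers(0, len(pool), size=k)]
    starts = _place([m.width for m in picks], length, rng)

    bases = _BASES[rng.integers(0, 4, size=length)].tobytes().decode()
    seq = list(bases)
    records = []
    label = np.zeros(pool.n_classes, dtype=np.uint8)
    for m, s in zip(picks, starts):
        site = m.sample_site(rng)
        seq[s:s + m.width] = site
        records.append(EmbeddingRecord(sequence_id, m.name, m.strand, s, s + m.width))
        label[pool.class_index[m.name]] = 1
    return "".join(seq), records, label


def _split_indices(n: int, fractions: tuple[float, float, float],
                   rng: np.random.Generator) -> dict[str, np.ndarray]:
    if any(f <= 0 for f in fractions) or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    perm = rng.permutation(n)
    n_train = int(np.floor(fractions[0] * n))
    n_val = int(np.floor(fractions[1] * n))
    return {
        "train": np.sort(perm[:n_train]),
        "validation": np.sort(perm[n_train:n_train + n_val]),
        "test": np.sort(perm[n_train + n_val:]),
    }


def generate_dataset(pool: MotifPool, n_sequences: int = 25000, length: int = 200,
                     fractions: tuple[float, float, float] = (0.7, 0.1, 0.2),
                     seed: int = 0, min_motifs: int = 1, max_motifs: int = 5,
                     ) -> SyntheticDataset:
    """Simulate the full benchmark dataset and split it train/validation/test.

    Defaults follow the benchmark conditions: 25,000 sequences of 200 nt,
    1-5 embedded sites each, split 0.7/0.1/0.2 by a seeded permutation.
    """
    rng = np.random.default_rng(seed)
    X = np.zeros((n_sequences, 4, length), dtype=np.float32)
    y = np.zeros((n_sequences, pool.n_classes), dtype=np.uint8)
    embeddings: list[EmbeddingRecord] = []
    for i in range(n_sequences):
        seq, recs, label = generate_sequence(
            pool, length, rng, min_motifs, max_motifs, sequence_id=i)
        X[i] = one_hot_encode(seq)
        y[i] = label
        embeddings.extend(recs)
    split = _split_indices(n_sequences, fractions, rng)
    return SyntheticDataset(X, y, embeddings, split, seed, list(pool.class_index))


def labels_from_embeddings(ds: SyntheticDataset) -> np.ndarray:
    """Recompute the label matrix from the ground-truth records (audit path)."""
    cls = {n: i for i, n in enumerate(ds.class_names)}
    y = np.zeros_like(ds.labels)
    for r in ds.embeddings:
        y[r.sequence_id, cls[r.motif_name]] = 1
    return y


# ---------------------------------------------------------------- persistence

def save_hdf5(ds: SyntheticDataset, path: str | Path) -> None:
    """Write sequences/labels/split to HDF5 (seed kept as a root attribute)."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["seed"] = ds.seed
        f.attrs["class_names"] = ds.class_names
        f.create_dataset("sequences", data=ds.sequences, compression="gzip")
        f.create_dataset("labels", data=ds.labels)
        for name, idx in ds.split.items():
            f.create_dataset(f"split/{name}", data=idx)


def load_hdf5(path: str | Path) -> SyntheticDataset:
    import h5py

    with h5py.File(path, "r") as f:
        return SyntheticDataset(
            sequences=f["sequences"][...],
            labels=f["labels"][...],
            embeddings=[],
            split={k: f[f"split/{k}"][...] for k in f["split"]},
            seed=int(f.attrs["seed"]),
            class_names=[str(s) for s in f.attrs["class_names"]],
        )


def write_fasta(ds: SyntheticDataset, path: str | Path) -> None:
    with open(path, "w") as fh:
        for i in range(ds.n_sequences):
            fh.write(f">seq_{i}\n{one_hot_decode(ds.sequences[i])}\n")


def write_embeddings_bed(ds: SyntheticDataset, path: str | Path) -> None:
    """BED-like TSV of ground-truth sites: sequence_id, start, end, name, strand.

    Coordinates are 0-based, half-open.
    """
    with open(path, "w") as fh:
        fh.write("sequence_id\tstart\tend\tmotif_name\tstrand\n")
        for r in ds.embeddings:
            fh.write(f"seq_{r.sequence_id}\t{r.start}\t{r.end}\t"
                     f"{r.motif_name}\t{r.strand}\n")
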