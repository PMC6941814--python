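"""Ground-truth transcription-factor motif models.

A motif is a position probability matrix (PPM/PWM) over the DNA alphabet
A, C, G, T.  Matrices are stored as ``(W, 4)`` arrays: one row per motif
position, columns ordered A, C, G, T.  A :class:`MotifPool` holds the 12
ground-truth motifs of the synthetic benchmark together with their reverse
complements (24 strand-motifs in total) and assigns each transcription
factor a stable class index used for the multi-label targets.

JASPAR PFM files are parsed with :mod:`Bio.motifs`; MEME minimal motif
files are read and written directly (the probability matrices must survive
a round trip at print precision).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Literal

import numpy as np

ALPHABET = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(ALPHABET)}
# A<->T, C<->G realised as a column permutation of the (W, 4) matrix.
_COMPLEMENT_PERM = np.array([3, 2, 1, 0])

Strand = Literal["forward", "reverse_complement"]


class MotifParseError(ValueError):
    """Raised when a motif file is malformed (names the motif and column)."""


@dataclass(frozen=True)
class MotifPWM:
    """A named position probability matrix on one strand.

    Parameters
    ----------
    name:
        Transcription-factor identifier, e.g. ``"CEBPB"``.
    matrix:
        ``(W, 4)`` array of probabilities; each row sums to 1.
    strand:
        ``"forward"`` for the database orientation, ``"reverse_complement"``
        for the flipped strand.
    """

    name: str
    matrix: np.ndarray
    strand: Strand = "forward"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != 4 or m.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: matrix must be (W, 4) with W >= 1")
        if np.any(m < 0) or np.any(m > 1):
            raise ValueError(f"motif {self.name!r}: probabilities outside [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0, atol=1e-6):
            bad = int(np.argmax(np.abs(m.sum(axis=1) - 1.0)))
            raise ValueError(f"motif {self.name!r}: column {bad} does not sum to 1")
        object.__setattr__(self, "matrix", m)

    @property
    def width(self) -> int:
        return self.matrix.shape[0]

    def reverse_complement(self) -> "MotifPWM":
        """Flip the motif to the other strand (reverse positions, swap A<->T, C<->G)."""
        flipped = self.matrix[::-1][:, _COMPLEMENT_PERM]
        other: Strand = (
            "reverse_complement" if self.strand == "forward" else "forward"
        )
        return MotifPWM(self.name, flipped, other)

    def sample_site(self, rng: np.random.Generator) -> str:
        """Draw one realised binding site, position-independently from each row."""
        return self.sample_sites(rng, 1)[0]

    def sample_sites(self, rng: np.random.Generator, n: int) -> list[str]:
        """Draw ``n`` independent sites (vectorised over sites and positions)."""
        cum = np.cumsum(self.matrix, axis=1)
        # guard against rounding: force the last cumulative edge to 1
        cum[:, -1] = 1.0
        u = rng.random((n, self.width))
        idx = (u[:, :, None] > cum[None]).sum(axis=2)
        flat = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)[idx]
        return [row.tobytes().decode() for row in flat]

    def information_content(self) -> np.ndarray:
        """Per-position information content in bits (0 at uniform, 2 at certainty)."""
        p = self.matrix
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(p > 0, p * np.log2(p), 0.0)
        return 2.0 + plogp.sum(axis=1)


@dataclass
class MotifPool:
    """The 24-member strand-motif pool (12 TFs, forward + reverse complement)."""

    motifs: list[MotifPWM]
    class_index: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.class_index:
            names: list[str] = []
            for m in self.motifs:
                if m.name not in names:
                    names.append(m.name)
            self.class_index = {n: i for i, n in enumerate(names)}

    def __iter__(self) -> Iterator[MotifPWM]:
        return iter(self.motifs)

    def __len__(self) -> int:
        return len(self.motifs)

    @property
    def n_classes(self) -> int:
        return len(self.class_index)

    @property
    def names(self) -> list[str]:
        return list(self.class_index)

    @property
    def max_width(self) -> int:
        return max(m.width for m in self.motifs)

    def get(self, name: str, strand: Strand = "forward") -> MotifPWM:
        for m in self.motifs:
            if m.name == name and m.strand == strand:
                return m
        raise KeyError(f"no motif {name!r} on strand {strand!r}")

    def forward_motifs(self) -> list[MotifPWM]:
        return [m for m in self.motifs if m.strand == "forward"]

    def subset(self, names: Iterable[str]) -> "MotifPool":
        keep = set(names)
        return MotifPool(
            [m for m in self.motifs if m.name in keep],
            {n: i for i, n in enumerate(k for k in self.class_index if k in keep)},
        )


def _with_reverse_complements(forward: list[MotifPWM]) -> list[MotifPWM]:
    return forward + [m.reverse_complement() for m in forward]


def _check_counts(name: str, counts: np.ndarray) -> np.ndarray:
    if not np.all(np.isfinite(counts)):
        raise MotifParseError(f"motif {name!r}: non-numeric matrix entry")
    totals = counts.sum(axis=1)
    if np.any(totals <= 0):
        bad = int(np.argmax(totals <= 0))
        raise MotifParseError(f"motif {name!r}: column {bad} sums to zero")
    return counts / totals[:, None]


def _load_jaspar(path: Path) -> list[MotifPWM]:
    from Bio import motifs as bio_motifs

    out: list[MotifPWM] = []
    with open(path) as fh:
        try:
            parsed = bio_motifs.parse(fh, "jaspar")
            records = [(m.name or m.matrix_id, m) for m in parsed]
        except Exception as exc:  # malformed at the Bio layer
            raise MotifParseError(f"cannot parse JASPAR file {path}: {exc}") from exc
    for name, m in records:
        counts = np.array([list(m.counts[b]) for b in ALPHABET], dtype=float).T
        out.append(MotifPWM(name, _check_counts(name, counts)))
    if not out:
        raise MotifParseError(f"no motifs found in {path}")
    return out


_MEME_MOTIF_RE = re.compile(r"^MOTIF\s+(\S+)(?:\s+(\S+))?")
_MEME_MATRIX_RE = re.compile(r"letter-probability matrix:.*w=\s*(\d+)(?:.*nsites=\s*(\S+))?")


def _load_meme(path: Path) -> list[MotifPWM]:
    out: list[MotifPWM] = []
    lines = Path(path).read_text().splitlines()
    i = 0
    while i < len(lines):
        mo = _MEME_MOTIF_RE.match(lines[i])
        if not mo:
            i += 1
            continue
        name = mo.group(1)
        i += 1
        while i < len(lines) and "letter-probability matrix" not in lines[i]:
            if _MEME_MOTIF_RE.match(lines[i]):
                raise MotifParseError(f"motif {name!r}: missing probability matrix")
            i += 1
        if i == len(lines):
            raise MotifParseError(f"motif {name!r}: missing probability matrix")
        hdr = _MEME_MATRIX_RE.search(lines[i])
        if hdr is None:
            raise MotifParseError(f"motif {name!r}: bad matrix header")
        width = int(hdr.group(1))
        i += 1
        rows = []
        for w in range(width):
            if i >= len(lines):
                raise MotifParseError(f"motif {name!r}: truncated at column {w}")
            fields = lines[i].split()
            if len(fields) != 4:
                raise MotifParseError(f"motif {name!r}: column {w} has {len(fields)} fields")
            try:
                rows.append([float(x) for x in fields])
            except ValueError as exc:
                raise MotifParseError(f"motif {name!r}: column {w} non-numeric") from exc
            i += 1
        probs = _check_counts(name, np.array(rows))
        out.append(MotifPWM(name, probs))
    if not out:
        raise MotifParseError(f"no motifs found in {path}")
    return out


def load_motifs(path: str | Path, format: str = "meme") -> MotifPool:
    """Load a motif file and expand it into a 2x-strand :class:`MotifPool`.

    Parameters
    ----------
    path:
        Motif file.
    format:
        ``"meme"`` (MEME minimal, probability matrices) or ``"jaspar_pfm"``
        (JASPAR count matrices; converted to probabilities by straight
        column normalisation, no pseudocount — sites are *sampled* from the
        matrix, never log-odds scored, so zero-probability bases simply
        never occur).

    Returns
    -------
    MotifPool
        Forward motifs in file order followed by their reverse complements;
        class indices follow file order.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "meme":
        forward = _load_meme(path)
    elif format == "jaspar_pfm":
        forward = _load_jaspar(path)
    else:
        raise ValueError(f"unknown motif format {format!r}")
    return MotifPool(_with_reverse_complements(forward))


def write_meme(motifs: Iterable[MotifPWM], path: str | Path,
               nsites: Iterable[int] | None = None) -> None:
    """Write motifs in MEME minimal format (forward entries as given)."""
    motifs = list(motifs)
    ns = list(nsites) if nsites is not None else [20] * len(motifs)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\n")
        fh.write("Background letter frequencies\nA 0.25 C 0.25 G 0.25 T 0.25\n\n")
        for m, n in zip(motifs, ns):
            fh.write(f"MOTIF {m.name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} nsites= {n} E= 0\n"
            )
            for row in m.matrix:
                fh.write(" ".join(f"{p:.6f}" for p in row) + "\n")
            fh.write("\n")


def load_default_pool() -> MotifPool:
    """Load the bundled 12-TF ground-truth pool (synthetic stand-in matrices).

    The matrices are synthetic stand-ins for the JASPAR versions of the 12
    factors (Arid3, CEBPB, FOSL1, Gabpa, MAFK, MAX, MEF2A, NFYB, SP1, SRF,
    STAT1, YY1): same names, realistic widths and information content, with
    consensus cores taken from the literature.  See the packaged file
    ``data/synthetic_tf_motifs.meme``.
    """
    ref = resources.files("motifcnn.data").joinpath("synthetic_tf_motifs.meme")
    with resources.as_file(ref) as p:
        return load_motifs(p, format="meme")
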