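"""Tomtom-style comparison of filter PPMs against a motif pool.

A query PPM slides across each target motif (both strands); every offset
with at least ``min_overlap`` aligned columns is scored by the sum of
column-wise Pearson correlations over the overlap.  Significance comes
from a permutation null — the query's columns are shuffled (seeded) and
the best achievable score over all offsets/strands is recomputed for each
shuffle — and the resulting p-value is scaled by the number of distinct
motifs in the pool, mimicking a database E-value.  The E-value cutoff of
0.1 follows the benchmark convention.

This is a deliberate stand-in for the MEME-suite Tomtom statistic (whose
exact p-value needs the full dynamic program); for a 12-motif ground-truth
pool the headline matched fractions are contrasts that are robust to the
choice of comparison statistic.  The real Tomtom remains available through
:func:`run_tomtom` when the binary is installed.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .interpret import FilterPPM
from .motifs import MotifPool, MotifPWM

logger = logging.getLogger(__name__)


@dataclass
class MatchResult:
    filter_index: int
    best_motif: str | None
    best_strand: str | None
    best_offset: int | None
    score: float
    significance: float          # E-value-like quantity
    is_match: bool


@dataclass
class MatchReport:
    results: list[MatchResult]
    frac_any: float
    frac_relevant: float
    n_filters: int
    e_cutoff: float = 0.1
    per_filter_relevant: list[MatchResult] = field(default_factory=list)


def _normalize_columns(m: np.ndarray) -> np.ndarray:
    """Centre and scale each (4-entry) column; zero-variance columns -> 0."""
    c = m - m.mean(axis=1, keepdims=True)
    norm = np.linalg.norm(c, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(norm > 1e-12, c / norm, 0.0)
    return out


def _offset_stack(tn: np.ndarray, wq: int, min_overlap: int
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Zero-padded target slices for every admissible query offset.

    Returns ``(T, offsets)`` with ``T[o, j] = tn[j + offsets[o]]`` where
    defined and 0 elsewhere; zero padding contributes nothing to the
    correlation sum, so a single tensor contraction scores all offsets.
    """
    wt = tn.shape[0]
    mo = min(min_overlap, wq, wt)
    offsets = np.arange(-(wq - mo), wt - mo + 1)
    T = np.zeros((len(offsets), wq, 4), dtype=tn.dtype)
    for o, off in enumerate(offsets):
        j0 = max(0, -off)
        j1 = min(wq, wt - off)
        T[o, j0:j1] = tn[j0 + off:j1 + off]
    return T, offsets


def _shuffled_stack(qn: np.ndarray, n_shuffles: int,
                    rng: np.random.Generator) -> np.ndarray:
    """(n_shuffles+1, Wq, 4) stack: the query first, column shuffles after."""
    wq = qn.shape[0]
    idx = np.tile(np.arange(wq), (n_shuffles, 1))
    idx = rng.permuted(idx, axis=1)
    return np.concatenate([qn[None], qn[idx]], axis=0)


def compare(query: FilterPPM | np.ndarray, target: MotifPWM,
            rng: np.random.Generator | None = None, n_shuffles: int = 1000,
            min_overlap: int = 4, n_targets: int = 1,
            _stack: np.ndarray | None = None
            ) -> tuple[int, str, float, float]:
    """Best alignment of ``query`` against one target motif (both strands).

    Returns ``(best offset, best strand, score, significance)`` where the
    offset is the position of the query's first column relative to the
    target's first column and significance is the permutation p-value
    scaled by ``n_targets``.
    """
    q = query.matrix if isinstance(query, FilterPPM) else np.asarray(query)
    qn = _normalize_columns(q)
    if not np.any(qn):
        return 0, "forward", 0.0, float(n_targets)  # degenerate: no match
    if _stack is None:
        rng = rng or np.random.default_rng(0)
        stack = _shuffled_stack(qn, n_shuffles, rng)
    else:
        stack = _stack
    best_score = -np.inf
    best = (0, "forward")
    null_best = np.full(stack.shape[0] - 1, -np.inf)
    for strand, tgt in (("forward", target),
                        ("reverse_complement", target.reverse_complement())):
        tn = _normalize_columns(tgt.matrix)
        T, offsets = _offset_stack(tn, qn.shape[0], min_overlap)
        scores = np.einsum("swc,owc->so", stack, T)
        obs = scores[0]
        o = int(np.argmax(obs))
        if obs[o] > best_score:
            best_score = float(obs[o])
            best = (int(offsets[o]), strand)
        null_best = np.maximum(null_best, scores[1:].max(axis=1))
    p = (1 + int((null_best >= best_score).sum())) / (1 + len(null_best))
    return best[0], best[1], best_score, p * n_targets


def best_match(query: FilterPPM | np.ndarray, pool: MotifPool,
               rng: np.random.Generator | None = None, n_shuffles: int = 1000,
               min_overlap: int = 4, e_cutoff: float = 0.1) -> MatchResult:
    """Best-matching pool motif for one query at the E-value cutoff.

    Only forward pool members are enumerated (the reverse strand is
    explored inside :func:`compare`); the E-value scale factor is the
    number of distinct motif names.  Ties are broken by smaller
    significance, then higher score, then motif name.
    """
    fidx = query.filter_index if isinstance(query, FilterPPM) else -1
    q = query.matrix if isinstance(query, FilterPPM) else np.asarray(query)
    if isinstance(query, FilterPPM) and query.empty:
        return MatchResult(fidx, None, None, None, 0.0, np.inf, False)
    qn = _normalize_columns(q)
    if not np.any(qn):
        return MatchResult(fidx, None, None, None, 0.0, np.inf, False)
    rng = rng or np.random.default_rng(0)
    stack = _shuffled_stack(qn, n_shuffles, rng)
    n_names = len(pool.class_index)
    # The null is pooled over the whole database search: for each shuffled
    # query, the best score over all offsets, strands and targets.  This
    # mirrors what a chance query could achieve against the database and
    # keeps the false-positive rate at an E cutoff well below the cutoff.
    null_best = np.full(stack.shape[0] - 1, -np.inf)
    per_target: list[tuple[float, str, int, str]] = []
    for m in pool.forward_motifs():
        for strand, tgt in (("forward", m), ("reverse_complement",
                                             m.reverse_complement())):
            tn = _normalize_columns(tgt.matrix)
            T, offsets = _offset_stack(tn, qn.shape[0], min_overlap)
            scores = np.einsum("swc,owc->so", stack, T)
            o = int(np.argmax(scores[0]))
            per_target.append((float(scores[0, o]), m.name,
                               int(offsets[o]), strand))
            null_best = np.maximum(null_best, scores[1:].max(axis=1))
    per_target.sort(key=lambda t: (-t[0], t[1]))
    score, name, off, strand = per_target[0]
    p = (1 + int((null_best >= score).sum())) / (1 + len(null_best))
    sig = p * n_names
    matched = sig <= e_cutoff
    return MatchResult(fidx, name if matched else None,
                       strand if matched else None,
                       off if matched else None, score, sig, matched)


def report(ppms: list[FilterPPM], full_pool: MotifPool,
           relevant_pool: MotifPool | None = None, e_cutoff: float = 0.1,
           n_shuffles: int = 1000, seed: int = 0) -> MatchReport:
    """Match every filter PPM and summarise the two headline fractions.

    ``frac_any`` counts filters matching any motif of ``full_pool``;
    ``frac_relevant`` counts matches to ``relevant_pool`` (defaults to the
    full pool).  Empty filters stay in the denominator — they are filters
    that learned nothing.
    """
    if not ppms:
        raise ValueError("no PPMs to match")
    relevant_pool = relevant_pool or full_pool
    rel_names = set(relevant_pool.class_index)
    if not rel_names <= set(full_pool.class_index):
        raise ValueError("relevant pool must be a subset of the full pool")
    master = np.random.SeedSequence(seed)
    results, rel_results = [], []
    for ppm, ss in zip(ppms, master.spawn(len(ppms))):
        rng = np.random.default_rng(ss)
        res = best_match(ppm, full_pool, rng=rng, n_shuffles=n_shuffles,
                         e_cutoff=e_cutoff)
        results.append(res)
        if set(full_pool.class_index) == rel_names:
            rel_results.append(res)
        else:
            rng = np.random.default_rng(np.random.SeedSequence(ss.entropy,
                                                               spawn_key=ss.spawn_key))
            rel_results.append(best_match(ppm, relevant_pool, rng=rng,
                                          n_shuffles=n_shuffles,
                                          e_cutoff=e_cutoff))
    n = len(ppms)
    return MatchReport(
        results=results,
        frac_any=sum(r.is_match for r in results) / n,
        frac_relevant=sum(r.is_match for r in rel_results) / n,
        n_filters=n,
        e_cutoff=e_cutoff,
        per_filter_relevant=rel_results,
    )


# ------------------------------------------------- optional external Tomtom

def tomtom_available() -> bool:
    return shutil.which("tomtom") is not None


def run_tomtom(query_meme: str | Path, target_meme: str | Path,
               out_dir: str | Path, e_cutoff: float = 0.1):
    """Invoke the MEME-suite Tomtom binary and parse its TSV output.

    Returns a pandas DataFrame of matches, or ``None`` (with a logged
    message) when the binary is not installed.
    """
    import pandas as pd

    if not tomtom_available():
        logger.warning("tomtom binary not found on PATH; external motif "
                       "comparison disabled")
        return None
    out_dir = Path(out_dir)
    subprocess.run(
        ["tomtom", "-thresh", str(e_cutoff), "-evalue", "-oc", str(out_dir),
         str(query_meme), str(target_meme)],
        check=True, capture_output=True)
    tsv = out_dir / "tomtom.tsv"
    return pd.read_csv(tsv, sep="\t", comment="#")
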