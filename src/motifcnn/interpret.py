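"""Turn trained convolutional filters into empirical motif models.

The procedure follows the activation-alignment recipe: scan a filter over
every test sequence (post-batch-norm, post-ReLU, *before* pooling), keep
the sequences whose maximum activation reaches at least 70% of the
filter's maximum achievable activation, extract the filter-sized
subsequence under each surviving maximum, and stack those subsequences
into an alignment whose column base frequencies form a position
probability matrix (PPM).  Per-position information content
IC_i = 2 + sum_n p_i(n) log2 p_i(n) (bits) scales logo letter heights.

Deeper layers can be scanned the same way only when no pooling precedes
them (pooling obfuscates activation positions); the scanner enforces this
and maps feature-map positions back to input-space receptive-field
windows.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .architectures import CNN, TrainedModel
from .motifs import ALPHABET, MotifPWM
from .nn.fused import FusedBNReLU

logger = logging.getLogger(__name__)


@dataclass
class FilterPPM:
    """Alignment-derived probability matrix for one filter."""

    filter_index: int
    layer: int
    matrix: np.ndarray          # (W, 4) probabilities; zeros when empty
    n_sites: int
    activation_threshold: float

    @property
    def empty(self) -> bool:
        return self.n_sites == 0

    @property
    def width(self) -> int:
        return self.matrix.shape[0]


@dataclass
class ActivationScan:
    """Max activation value and input-space window start per (sequence, filter)."""

    layer: int
    values: np.ndarray          # (N, F)
    starts: np.ndarray          # (N, F); start of the receptive-field window
    rf_width: int


def _unwrap(model: CNN | TrainedModel) -> CNN:
    return model.model if isinstance(model, TrainedModel) else model


def _check_scannable(cnn: CNN, layer: int) -> None:
    if not 1 <= layer <= len(cnn.spec.conv_layers):
        raise ValueError(f"no convolutional layer {layer}")
    for blk in cnn.spec.conv_layers[:layer - 1]:
        if blk.pool_size > 1 or blk.pool_stride > 1:
            raise ValueError(
                f"layer {layer} is preceded by max-pooling; activation "
                "positions are not alignable")


def receptive_field(cnn: CNN, layer: int) -> int:
    """Input-space receptive-field width of one conv-layer-``layer`` neuron."""
    ks = [blk.filter_size for blk in cnn.spec.conv_layers[:layer]]
    return sum(k - 1 for k in ks) + 1


def scan_activations(model: CNN | TrainedModel, layer: int,
                     sequences: np.ndarray, batch_size: int = 256
                     ) -> ActivationScan:
    """Maximum post-ReLU activation and its (leftmost) position per filter.

    ``sequences`` is the stored one-hot tensor ``(N, 4, L)``.  Positions are
    reported as the 0-based start of the receptive-field window in input
    coordinates (negative or overrunning starts are possible near the
    sequence ends and are discarded later by :func:`build_ppm`).
    """
    cnn = _unwrap(model)
    _check_scannable(cnn, layer)
    X = np.ascontiguousarray(np.transpose(sequences, (0, 2, 1)))
    acts = cnn.conv_activations(X, layer, batch_size=batch_size)  # (N, L, F)
    values = acts.max(axis=1)
    pos = acts.argmax(axis=1)          # leftmost by argmax convention
    # centre-aligned "same" conv: feature-map index i sits over the window
    # starting at i - sum of left pads of the contributing conv layers
    left = sum((blk.filter_size - 1) // 2
               for blk in cnn.spec.conv_layers[:layer])
    return ActivationScan(layer, values, pos - left, receptive_field(cnn, layer))


def max_possible_activation(model: CNN | TrainedModel, layer: int = 1
                            ) -> np.ndarray:
    """Analytic per-filter activation ceiling (first conv layer only).

    Folds the batch-norm affine transform (running statistics) into the
    convolution, then takes the best base at every filter position:
    M_f = relu(scale_f * (b_f + sum_j max_b W[f, j, b] - mean_f) + beta_f).
    Deeper layers have no closed form (inputs are unbounded feature maps),
    so callers use the empirical maximum instead.
    """
    cnn = _unwrap(model)
    if layer != 1:
        raise ValueError("analytic activation ceiling is defined for layer 1 only")
    conv = cnn.layers[cnn.conv_indices[0]]
    bn = cnn.layers[cnn.relu_indices[0]]
    assert isinstance(bn, FusedBNReLU)
    z_max = conv.params["W"].max(axis=2).sum(axis=1) + conv.params["b"]
    scale = (bn.params["gamma"]
             / np.sqrt(bn.running_var + bn.eps))
    z = scale * (z_max - bn.running_mean) + bn.params["beta"]
    return np.maximum(z, 0.0)


def build_ppm(scan: ActivationScan, sequences: np.ndarray,
              threshold_frac: float = 0.7,
              max_activations: np.ndarray | None = None) -> list[FilterPPM]:
    """Alignment PPMs for every filter of a scanned layer.

    ``max_activations`` overrides the per-filter activation ceiling (e.g.
    the analytic ceiling from :func:`max_possible_activation`); by default
    the empirical maximum over all scanned sequences is used.  Windows that
    would overrun either sequence end are dropped; a filter with no
    surviving sequences yields an empty-flagged PPM rather than an error.
    """
    if not 0 < threshold_frac <= 1:
        raise ValueError("threshold_frac must be in (0, 1]")
    N, _, L = sequences.shape
    W = scan.rf_width
    n_filters = scan.values.shape[1]
    ceilings = (scan.values.max(axis=0) if max_activations is None
                else np.asarray(max_activations, dtype=float))
    out: list[FilterPPM] = []
    for f in range(n_filters):
        thr = threshold_frac * ceilings[f]
        keep = scan.values[:, f] >= thr if ceilings[f] > 0 else np.zeros(N, bool)
        starts = scan.starts[keep, f]
        seq_idx = np.nonzero(keep)[0]
        inside = (starts >= 0) & (starts + W <= L)
        starts, seq_idx = starts[inside], seq_idx[inside]
        if len(seq_idx) == 0:
            out.append(FilterPPM(f, scan.layer, np.zeros((W, 4)), 0, float(thr)))
            continue
        counts = np.zeros((W, 4))
        for n, s in zip(seq_idx, starts):
            counts += sequences[n, :, s:s + W].T
        ppm = counts / counts.sum(axis=1, keepdims=True)
        out.append(FilterPPM(f, scan.layer, ppm, len(seq_idx), float(thr)))
    return out


def information_content(ppm: FilterPPM | np.ndarray) -> np.ndarray:
    """Per-position information content in bits: IC_i = 2 + sum p log2 p."""
    p = ppm.matrix if isinstance(ppm, FilterPPM) else np.asarray(ppm)
    if isinstance(ppm, FilterPPM) and ppm.empty:
        raise ValueError("information content of an empty PPM is undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(p), 0.0)
    return 2.0 + plogp.sum(axis=1)


def export_meme(ppms: list[FilterPPM], path: str | Path) -> int:
    """Write non-empty filter PPMs as a MEME minimal file; returns count written."""
    from .motifs import write_meme

    keep = [p for p in ppms if not p.empty]
    for p in ppms:
        if p.empty:
            logger.info("filter %d is empty (no sites above threshold); skipped",
                        p.filter_index)
    if not keep:
        raise ValueError("all PPMs are empty; nothing to export")
    write_meme(
        [MotifPWM(f"filter_{p.filter_index}", p.matrix) for p in keep],
        path, nsites=[p.n_sites for p in keep])
    return len(keep)


# ------------------------------------------------------------------ logos

_LOGO_COLORS = {"A": "#109648", "C": "#255C99", "G": "#F7B32B", "T": "#D62839"}


def render_logo(ppm: FilterPPM | np.ndarray, path: str | Path,
                title: str | None = None) -> None:
    """Render an information-content sequence logo (letter height p * IC)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.font_manager import FontProperties
    from matplotlib.patches import PathPatch
    from matplotlib.textpath import TextPath
    from matplotlib.transforms import Affine2D

    p = ppm.matrix if isinstance(ppm, FilterPPM) else np.asarray(ppm)
    if isinstance(ppm, FilterPPM) and ppm.empty:
        raise ValueError("cannot render an empty PPM")
    ic = information_content(p)
    W = p.shape[0]
    fig, ax = plt.subplots(figsize=(max(2, W * 0.35), 1.8))
    font = FontProperties(family="DejaVu Sans", weight="bold")
    for i in range(W):
        heights = p[i] * ic[i]
        order = np.argsort(heights)
        y = 0.0
        for b in order:
            h = heights[b]
            if h <= 1e-3:
                continue
            letter = ALPHABET[b]
            tp = TextPath((0, 0), letter, size=1.0, prop=font)
            bb = tp.get_extents()
            tr = (Affine2D()
                  .translate(-bb.x0, -bb.y0)
                  .scale(0.9 / bb.width, h / bb.height)
                  .translate(i + 0.05, y))
            ax.add_patch(PathPatch(tr.transform_path(tp),
                                   color=_LOGO_COLORS[letter], lw=0))
            y += h
    ax.set_xlim(0, W)
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xticks([])
    if title:
        ax.set_title(title, fontsize=9)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
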