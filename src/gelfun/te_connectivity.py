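"""Directed effective connectivity from spike rasters via transfer entropy.

An effective connection I -> J is declared when the recent activity of
neuron I improves the prediction of neuron J's next state beyond what J's
own history provides.  The pipeline is:

1. binarize the raster into time bins (default two camera frames, ~0.06 s);
2. estimate the pairwise transfer entropy

   TE(X -> Y) = sum p(y_{t+1}, y_t^{(k)}, x_t^{(k)})
                * log2 [ p(y_{t+1} | y_t^{(k)}, x_t^{(k)})
                       / p(y_{t+1} | y_t^{(k)}) ]

   with a plug-in joint-histogram estimator over Markov order-k binary
   histories (bias is small for binary alphabets and 15-min recordings, and
   the normalization below absorbs what remains);
3. standardize each estimate against the joint distribution of all pair
   estimates of the same recording,

   z(I -> J) = (TE(I -> J) - <TE_joint>) / sigma_joint,

   and keep edges with z strictly greater than the threshold (default 2),
   yielding a binarized directed adjacency matrix.

A surrogate null (source time-shuffling) is available as an alternative to
the pooled-pairs null via ``null="shuffle"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .types import SpikeRaster

__all__ = [
    "TEConfig",
    "EffectiveConnectivity",
    "binarize_raster",
    "transfer_entropy",
    "te_matrix",
    "export_network",
]


@dataclass
class TEConfig:
    """Transfer-entropy estimation settings.

    ``bin_s`` is the raster bin width in seconds (default two frames at
    33 fps); ``markov_order`` the history length k in bins; ``delay_bins``
    the lag of the source history relative to the predicted bin (1 means
    the source history ends in the bin just before the prediction, i.e. no
    instantaneous same-bin term); ``z_threshold`` the significance cut on
    the standardized estimates (strict inequality).  ``null`` selects how
    <TE_joint> and sigma_joint are formed: ``"pooled"`` uses the joint
    distribution of all ordered-pair estimates of the recording,
    ``"shuffle"`` a per-pair circular-shift surrogate ensemble.
    """

    bin_s: float = 2.0 / 33.0
    markov_order: int = 2
    delay_bins: int = 1
    z_threshold: float = 2.0
    null: str = "pooled"
    n_surrogates: int = 20
    seed: int = 0

    def validate(self) -> None:
        if self.bin_s <= 0:
            raise ValueError("bin_s must be positive")
        if self.markov_order < 1:
            raise ValueError("markov_order must be >= 1")
        if self.delay_bins < 1:
            raise ValueError("delay_bins must be >= 1")
        if self.z_threshold <= 0:
            raise ValueError("z_threshold must be positive")
        if self.null not in ("pooled", "shuffle"):
            raise ValueError("null must be 'pooled' or 'shuffle'")


@dataclass
class EffectiveConnectivity:
    """TE matrix, standardized z matrix and binarized adjacency."""

    te: np.ndarray
    z: np.ndarray
    A: np.ndarray
    null_mean: float
    null_sd: float
    config: TEConfig = field(default_factory=TEConfig)

    @property
    def n_neurons(self) -> int:
        return self.te.shape[0]


def binarize_raster(raster: SpikeRaster, bin_s: float) -> np.ndarray:
    """Binary neuron x bin matrix; a bin is 1 iff it contains >= 1 event."""
    if bin_s <= 0:
        raise ValueError("bin_s must be positive")
    n_bins = int(np.ceil(raster.duration / bin_s))
    out = np.zeros((raster.n_neurons, n_bins), dtype=np.uint8)
    for i, ev in enumerate(raster.events):
        idx = np.minimum((ev / bin_s).astype(int), n_bins - 1)
        out[i, idx] = 1
    return out


def _history_words(s: np.ndarray, k: int) -> np.ndarray:
    """word[t] = sum_{a=1..k} s[t-a] * 2^(a-1); valid for t >= k."""
    n = s.shape[-1]
    w = np.zeros(n, dtype=np.int64)
    for a in range(1, k + 1):
        w[a:] |= (s[:-a].astype(np.int64) << (a - 1))
    return w


def _te_from_counts(counts: np.ndarray, k: int) -> float:
    """Plug-in TE (bits) from joint counts indexed (x-hist, y-hist, y-next)."""
    C = counts.reshape(1 << k, 1 << k, 2).astype(float)
    N = C.sum()
    if N == 0:
        return 0.0
    n_yhxh = C.sum(axis=2, keepdims=True)          # (xh, yh, 1)
    n_yyh = C.sum(axis=0, keepdims=True)           # (1, yh, y')
    n_yh = C.sum(axis=(0, 2))[None, :, None]       # (1, yh, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = C * n_yh / (n_yhxh * n_yyh)
        terms = np.where(C > 0, C * np.log2(ratio), 0.0)
    return float(terms.sum() / N)


def _pair_te(y: np.ndarray, x: np.ndarray, k: int, delay: int) -> float:
    start = delay + k - 1
    yh = _history_words(y, k)
    xh = _history_words(x, k)
    t = np.arange(start, y.shape[0])
    code = y[t].astype(np.int64) + 2 * (yh[t] + (xh[t - delay + 1] << k))
    counts = np.bincount(code, minlength=1 << (2 * k + 1))
    return _te_from_counts(counts, k)


def transfer_entropy(x: np.ndarray, y: np.ndarray, cfg: TEConfig | None = None) -> float:
    """TE(X -> Y) in bits between two equal-length binary series.

    Requires at least ``100 * markov_order`` bins so the joint histogram is
    reasonably populated.  Exactly 0 when the source is constant.
    """
    cfg = cfg or TEConfig()
    cfg.validate()
    x = np.asarray(x).astype(np.uint8).ravel()
    y = np.asarray(y).astype(np.uint8).ravel()
    if x.shape != y.shape:
        raise ValueError("series must have equal length")
    if x.size < 100 * cfg.markov_order:
        raise ValueError(f"series too short: need >= {100 * cfg.markov_order} bins")
    return _pair_te(y, x, cfg.markov_order, cfg.delay_bins)


def te_matrix(bins: np.ndarray, cfg: TEConfig | None = None,
              exclude_bins: np.ndarray | None = None) -> EffectiveConnectivity:
    """All ordered-pair TEs, z-standardization and binarization.

    ``bins`` is the neuron x bin binary matrix.  ``exclude_bins`` optionally
    marks time bins (e.g. network-burst windows) whose predictions are
    dropped from every pair's histogram — the "generalized" burst
    conditioning of calcium-imaging TE.  The null statistics <TE_joint> and
    sigma_joint are taken over the pooled off-diagonal pair estimates
    (default) or a circular-shift surrogate ensemble; edges require
    z > z_threshold strictly.  When sigma_joint is 0 (e.g. an all-silent
    recording) no edge is significant and a warning is emitted.
    """
    cfg = cfg or TEConfig()
    cfg.validate()
    bins = np.asarray(bins).astype(np.uint8)
    n, L = bins.shape
    if n < 2:
        raise ValueError("need at least 2 neurons")
    k, delay = cfg.markov_order, cfg.delay_bins
    start = delay + k - 1

    t = np.arange(start, L)
    if exclude_bins is not None:
        keep = ~np.asarray(exclude_bins, dtype=bool)[t]
        t = t[keep]

    words = np.stack([_history_words(bins[i], k) for i in range(n)])
    # per-target part of the joint code; source word is shifted by delay-1
    tgt_code = [bins[j, t].astype(np.int64) + 2 * words[j][t] for j in range(n)]
    src_word = [words[i][t - delay + 1] << (k + 1) for i in range(n)]

    te = np.zeros((n, n))
    for j in range(n):
        base = tgt_code[j]
        for i in range(n):
            if i == j:
                continue
            counts = np.bincount(base + src_word[i], minlength=1 << (2 * k + 1))
            # counts indexed y' + 2*yh + 2^(k+1)*xh == (xh, yh, y') reshape
            te[i, j] = _te_from_counts(counts, k)

    off = ~np.eye(n, dtype=bool)
    if cfg.null == "pooled":
        null_mean = float(te[off].mean())
        null_sd = float(te[off].std(ddof=1))
    else:
        rng = np.random.default_rng(cfg.seed)
        sur = []
        for _ in range(cfg.n_surrogates):
            shifts = rng.integers(L // 4, 3 * L // 4, size=n)
            rolled = np.stack([np.roll(bins[i], s) for i, s in enumerate(shifts)])
            rw = np.stack([_history_words(rolled[i], k) for i in range(n)])
            for j in range(min(n, 10)):  # subsample targets for the ensemble
                base = tgt_code[j]
                for i in range(n):
                    if i == j:
                        continue
                    counts = np.bincount(
                        base + (rw[i][t - delay + 1] << (k + 1)),
                        minlength=1 << (2 * k + 1))
                    sur.append(_te_from_counts(counts, k))
        sur = np.asarray(sur)
        null_mean = float(sur.mean())
        null_sd = float(sur.std(ddof=1))

    z = np.zeros((n, n))
    if null_sd == 0:
        warnings.warn("sigma_joint is zero; no connection can be significant",
                      stacklevel=2)
        A = np.zeros((n, n), dtype=int)
    else:
        z[off] = (te[off] - null_mean) / null_sd
        A = ((z > cfg.z_threshold) & off).astype(int)
    return EffectiveConnectivity(te=te, z=z, A=A, null_mean=null_mean,
                                 null_sd=null_sd, config=cfg)


def export_network(ec_or_A, path: str, positions: np.ndarray | None = None,
                   communities: np.ndarray | None = None) -> nx.DiGraph:
    """Write the binarized network to GraphML or GEXF (by file extension).

    Nodes carry position (x, y, z in um), community label, in/out/total
    degree; edges are directed.  The written file loads in standard graph
    tools (Gephi reads both formats).  Returns the graph object.
    """
    A = ec_or_A.A if isinstance(ec_or_A, EffectiveConnectivity) else np.asarray(ec_or_A)
    n = A.shape[0]
    G = nx.DiGraph()
    for i in range(n):
        attrs: dict = {
            "out_degree": int(A[i].sum()),
            "in_degree": int(A[:, i].sum()),
            "degree": int(A[i].sum() + A[:, i].sum()),
        }
        if positions is not None:
            attrs["x"], attrs["y"] = float(positions[i][0]), float(positions[i][1])
            if len(positions[i]) > 2:
                attrs["z"] = float(positions[i][2])
        if communities is not None:
            attrs["community"] = int(communities[i])
        G.add_node(i, **attrs)
    src, dst = np.nonzero(A)
    G.add_edges_from(zip(src.tolist(), dst.tolist()))
    path = str(path)
    if path.endswith(".gexf"):
        nx.write_gexf(G, path)
    elif path.endswith(".graphml"):
        nx.write_graphml(G, path)
    else:
        raise ValueError("unsupported export format: use .graphml or .gexf")
    return G
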