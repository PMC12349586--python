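"""Polarization-pair collaborative-filtering denoiser for quad-polarization video.

The algorithm extends BM3D-style collaborative filtering to the four
channels of a polarization filter array:

1. *Polarization pairs.*  Total-intensity conservation
   ``I0 + I90 = I45 + I135`` makes each channel virtually re-measurable from
   the other three (e.g. ``I'0 = I45 + I135 - I90``); these virtual frames
   carry the same signal with independent noise of variance ``3 sigma^2``
   and are stacked with the measured frames.
2. *Shared block matching.*  Similar 8x8 patches are searched in a 40x40
   window on the 0-degree channel only (the channel carrying the full
   interference signal), with the patch distance averaged over that
   channel's stacked frame-layers; the matched coordinates are shared by
   all four channels, giving each channel a 4-D group indexed
   (frame-layer, block, y, x) with frame-layers
   ``[I(t), I'(t), I(t-1), I'(t-1)]`` for the default two-frame context.
   The filter is causal and streaming: the temporal context frames are the
   best causally available *estimates* of the preceding frames (the pilot
   output), which is what produces the characteristic saturation of the
   frame-count sweep (a large 1 -> 2 frame gain, a negligible 2 -> 3
   gain).
3. *Collaborative filtering.*  A separable 4-D transform —
   biorthogonal-1.5 wavelet within patches, orthonormal Hadamard across the
   block axis, orthonormal DCT-II across frame-layers — followed by hard
   thresholding at ``3 sigma`` (stage 1) and empirical Wiener shrinkage
   with ``lambda = 1`` guided by the stage-1 estimate (stage 2), then
   weighted aggregation of the overlapping patch estimates.

Ablation modes: ``bm4d_no_pp`` duplicates measured frames in place of the
virtual pairs; ``bm3d_single_frame`` filters each channel independently,
frame by frame, with no pairs.

Per-coefficient noise levels account for the layer covariance (virtual
pairs have variance ``3 sigma^2``; duplicated layers are perfectly
correlated) propagated through the frame-axis DCT, and for the
non-orthonormal gain of the biorthogonal wavelet, computed numerically
once per patch size.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache

import numpy as np
import pywt
from numpy.lib.stride_tricks import sliding_window_view
from scipy.fft import dct
from scipy.linalg import hadamard

from .containers import PolFrame, PolVideo

__all__ = [
    "PPConfig",
    "MatchResult",
    "generate_pairs",
    "block_match",
    "forward_transform_4d",
    "inverse_transform_4d",
    "hard_threshold",
    "wiener_refine",
    "aggregate",
    "estimate_sigma",
    "denoise",
]

_MODES = ("ppbm4d", "bm4d_no_pp", "bm3d_single_frame")


@dataclass(frozen=True)
class PPConfig:
    """Denoiser configuration (defaults are the reference operating point)."""

    patch: int = 8
    search: int = 40
    max_group: int = 16
    match_step: int = 4
    n_frames: int = 2
    sigma: float | None = None  # per-channel noise SD in counts; None = estimate
    hard_tau: float = 3.0
    wiener_lambda: float = 1.0
    wavelet: str = "bior1.5"
    wavelet_level: int = 0  # 0 = full decomposition (1x1 approximation)
    mode: str = "ppbm4d"

    def __post_init__(self) -> None:
        if self.patch < 2 or self.patch % 2:
            raise ValueError("patch must be an even integer >= 2")
        if self.search < self.patch:
            raise ValueError("search window must be at least the patch size")
        if self.max_group < 1 or (self.max_group & (self.max_group - 1)):
            raise ValueError("max_group must be a power of 2 (Hadamard)")
        if self.n_frames not in (1, 2, 3):
            raise ValueError("n_frames must be 1, 2 or 3")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}")
        if self.match_step < 1:
            raise ValueError("match_step must be >= 1")
        max_level = int(math.log2(self.patch))
        if not (0 <= self.wavelet_level <= max_level):
            raise ValueError(f"wavelet_level must be 0 (full) .. {max_level} for patch {self.patch}")

    @property
    def layers_per_frame(self) -> int:
        return 1 if self.mode == "bm3d_single_frame" else 2

    @property
    def n_layers(self) -> int:
        n_frames = 1 if self.mode == "bm3d_single_frame" else self.n_frames
        return self.layers_per_frame * n_frames


@dataclass
class MatchResult:
    """Block-matching output for one reference patch: matched patch
    top-left coordinates sorted by ascending distance (raster-order
    tie-break), the reference itself included with distance 0."""

    ref: tuple[int, int]
    coords: np.ndarray  # (K, 2) int
    distances: np.ndarray  # (K,)


# ---------------------------------------------------------------------------
# polarization pairs

def generate_pairs(frame: PolFrame | np.ndarray) -> PolFrame | np.ndarray:
    """Virtual re-measurement of each channel from the other three.

    Uses the conservation identity I0 + I90 = I45 + I135; negative values
    are permitted (not clipped).  Accepts a PolFrame or any array with the
    channel axis (order 0, 45, 90, 135) at position -3.
    """
    arr = frame.data if isinstance(frame, PolFrame) else np.asarray(frame)
    if not np.issubdtype(arr.dtype, np.floating):
        arr = arr.astype(float)
    if arr.shape[-3] != 4:
        raise ValueError("channel axis must have length 4")
    i0, i45, i90, i135 = (arr[..., k, :, :] for k in range(4))
    virt = np.stack(
        [i45 + i135 - i90, i0 + i90 - i135, i45 + i135 - i0, i0 + i90 - i45],
        axis=-3,
    )
    return PolFrame(virt) if isinstance(frame, PolFrame) else virt


# ---------------------------------------------------------------------------
# block matching

def _ref_positions(extent: int, patch: int, step: int) -> np.ndarray:
    """Stride positions with the trailing one forced onto the edge."""
    last = extent - patch
    pos = list(range(0, last + 1, step))
    if pos[-1] != last:
        pos.append(last)
    return np.asarray(pos)


def _block_match_arrays(layers, cfg: PPConfig):
    """Vectorized matcher; returns (refs (N,2), coords (N,K,2), dists (N,K)).

    ``layers`` is one 2-D image or a list of same-shaped layer images; the
    patch distance is the mean squared difference averaged over all layers
    (matching on the stacked reference-channel data)."""
    if isinstance(layers, np.ndarray) and layers.ndim == 2:
        layers = [layers]
    layers = [np.asarray(l) for l in layers]
    h, w = layers[0].shape
    p = cfg.patch
    if h < p or w < p:
        raise ValueError(f"image {layers[0].shape} smaller than patch {p}")
    views = [sliding_window_view(l, (p, p)) for l in layers]
    ys = _ref_positions(h, p, cfg.match_step)
    xs = _ref_positions(w, p, cfg.match_step)
    half = (cfg.search - p) // 2
    max_y, max_x = h - p, w - p

    refs, all_coords, all_dists = [], [], []
    for y in ys:
        y0, y1 = max(0, y - half), min(max_y, y + half)
        for x in xs:
            x0, x1 = max(0, x - half), min(max_x, x + half)
            d = None
            for v in views:
                dd = np.mean((v[y0 : y1 + 1, x0 : x1 + 1] - v[y, x]) ** 2, axis=(2, 3), dtype=float)
                d = dd if d is None else d + dd
            d_flat = (d / len(views)).ravel()
            ny, nx = d.shape
            cy = (np.arange(ny)[:, None] + y0).repeat(nx, axis=1).ravel()
            cx = np.tile(np.arange(nx) + x0, ny)
            order = np.lexsort((cy * w + cx, d_flat))[: cfg.max_group]
            refs.append((y, x))
            all_coords.append(np.stack([cy[order], cx[order]], axis=1))
            all_dists.append(d_flat[order])
    k = min(len(c) for c in all_coords)
    coords = np.stack([c[:k] for c in all_coords])
    dists = np.stack([d[:k] for d in all_dists])
    return np.asarray(refs), coords, dists


def block_match(image: np.ndarray, cfg: PPConfig | None = None) -> list[MatchResult]:
    """Match similar patches for every reference position on one image.

    The reference grid has stride ``cfg.match_step`` with the trailing
    row/column forced onto the frame edge so every pixel is covered; the
    distance is the mean squared difference over the patch, restricted to a
    ``search x search`` window centered on the reference (clipped at the
    borders).  The best ``max_group`` candidates are kept, sorted by
    (distance, raster order).
    """
    cfg = cfg or PPConfig()
    refs, coords, dists = _block_match_arrays(image, cfg)
    return [
        MatchResult(ref=(int(r[0]), int(r[1])), coords=c.copy(), distances=d.copy())
        for r, c, d in zip(refs, coords, dists)
    ]


def _extract_groups(layers: list[np.ndarray], coords: np.ndarray, patch: int) -> np.ndarray:
    """Gather patches at shared coordinates from each layer image.

    Returns (N, L, K, patch, patch) for N groups of K patches."""
    n, k, _ = coords.shape
    ys = coords[..., 0].ravel()
    xs = coords[..., 1].ravel()
    dtype = np.result_type(*(np.asarray(img).dtype for img in layers), np.float32)
    out = np.empty((n, len(layers), k, patch, patch), dtype=dtype)
    for li, img in enumerate(layers):
        win = sliding_window_view(np.asarray(img, dtype=dtype), (patch, patch))
        out[:, li] = win[ys, xs].reshape(n, k, patch, patch)
    return out


# ---------------------------------------------------------------------------
# separable 4-D transform

def _dwt2_step(g: np.ndarray, wavelet: str) -> np.ndarray:
    ca, (ch, cv, cd) = pywt.dwt2(g, wavelet, mode="periodization", axes=(-2, -1))
    top = np.concatenate([ca, ch], axis=-1)
    bot = np.concatenate([cv, cd], axis=-1)
    return np.concatenate([top, bot], axis=-2)


def _idwt2_step(t: np.ndarray, wavelet: str) -> np.ndarray:
    hp = t.shape[-1] // 2
    ca = t[..., :hp, :hp]
    ch = t[..., :hp, hp:]
    cv = t[..., hp:, :hp]
    cd = t[..., hp:, hp:]
    return pywt.idwt2((ca, (ch, cv, cd)), wavelet, mode="periodization", axes=(-2, -1))


def _resolve_levels(size: int, levels: int) -> int:
    return int(math.log2(size)) if levels == 0 else levels


def _dwt2_forward_ref(g: np.ndarray, wavelet: str, levels: int = 0) -> np.ndarray:
    """Reference multi-level 2-D DWT packed in the standard quadrant
    layout; the approximation is recursively decomposed, so with full
    depth the patch DC is the single coefficient at (0, 0)."""
    levels = _resolve_levels(g.shape[-1], levels)
    out = np.array(g, dtype=float, copy=True)
    size = g.shape[-1]
    for _ in range(levels):
        out[..., :size, :size] = _dwt2_step(out[..., :size, :size], wavelet)
        size //= 2
    return out


def _dwt2_inverse_ref(t: np.ndarray, wavelet: str, levels: int = 0) -> np.ndarray:
    levels = _resolve_levels(t.shape[-1], levels)
    out = np.array(t, dtype=float, copy=True)
    size = t.shape[-1] >> (levels - 1)
    for _ in range(levels):
        out[..., :size, :size] = _idwt2_step(out[..., :size, :size], wavelet)
        size *= 2
    return out


@lru_cache(maxsize=8)
def _patch_transform_matrices(wavelet: str, patch: int, levels: int) -> tuple[np.ndarray, np.ndarray]:
    """The patch DWT is a fixed linear map on patch*patch samples; cache
    its analysis matrix (built from the reference transform applied to the
    canonical basis) and the exact synthesis inverse, so the hot path is a
    single BLAS product per group batch."""
    n = patch * patch
    basis = np.eye(n).reshape(n, patch, patch)
    cols = _dwt2_forward_ref(basis, wavelet, levels).reshape(n, n)
    analysis = cols.T  # coefficient c = sum_i analysis[c, i] * x_i
    return analysis, np.linalg.inv(analysis)


def _dwt2_forward(g: np.ndarray, wavelet: str, levels: int = 0) -> np.ndarray:
    p = g.shape[-1]
    a, _ = _patch_transform_matrices(wavelet, p, _resolve_levels(p, levels))
    shape = g.shape
    return (np.reshape(g, shape[:-2] + (p * p,)) @ a.astype(g.dtype).T).reshape(shape)


def _dwt2_inverse(t: np.ndarray, wavelet: str, levels: int = 0) -> np.ndarray:
    p = t.shape[-1]
    _, ainv = _patch_transform_matrices(wavelet, p, _resolve_levels(p, levels))
    shape = t.shape
    return (np.reshape(t, shape[:-2] + (p * p,)) @ ainv.astype(t.dtype).T).reshape(shape)


@lru_cache(maxsize=8)
def _hadamard_orthonormal(k: int) -> np.ndarray:
    return hadamard(k).astype(float) / math.sqrt(k)


def _next_pow2(k: int) -> int:
    return 1 << (k - 1).bit_length()


@lru_cache(maxsize=16)
def _layer_block_matrices(l: int, k2: int) -> tuple[np.ndarray, np.ndarray]:
    """Fused frame-layer DCT x block Hadamard as one Kronecker matrix over
    the flattened (layer, block) axis, plus its exact inverse."""
    dmat = dct(np.eye(l), type=2, norm="ortho", axis=0)
    hmat = _hadamard_orthonormal(k2)
    fwd = np.kron(dmat, hmat)
    inv = np.kron(dmat.T, hmat)  # orthonormal DCT inverse; Hadamard is self-inverse
    return fwd, inv


def forward_transform_4d(g: np.ndarray, wavelet: str = "bior1.5", levels: int = 0) -> np.ndarray:
    """Separable transform of groups shaped (..., L, K, p, p).

    Biorthogonal wavelet over (y, x) (subbands tiled [[A, H], [V, D]]),
    orthonormal Hadamard over the block axis (zero-padded to the next power
    of two when K is not one), orthonormal DCT-II over the frame-layer
    axis.  The output block axis has the padded length.
    """
    g = np.asarray(g)
    if not np.issubdtype(g.dtype, np.floating):
        g = g.astype(float)
    t = _dwt2_forward(g, wavelet, levels)
    k = t.shape[-3]
    k2 = _next_pow2(k)
    if k2 != k:
        pad = [(0, 0)] * t.ndim
        pad[-3] = (0, k2 - k)
        t = np.pad(t, pad)
    lead, l, _, p, _ = t.shape[:-4], t.shape[-4], k2, t.shape[-2], t.shape[-1]
    fwd, _ = _layer_block_matrices(l, k2)
    x = t.reshape(lead + (l * k2, p * p))
    x = np.swapaxes(x, -1, -2) @ fwd.astype(t.dtype).T
    return np.swapaxes(x, -1, -2).reshape(lead + (l, k2, p, p))


def inverse_transform_4d(t: np.ndarray, k: int | None = None, wavelet: str = "bior1.5", levels: int = 0) -> np.ndarray:
    """Exact inverse of :func:`forward_transform_4d`; ``k`` slices the block
    axis back to the original group size."""
    t = np.asarray(t)
    if not np.issubdtype(t.dtype, np.floating):
        t = t.astype(float)
    lead, l, k2, p = t.shape[:-4], t.shape[-4], t.shape[-3], t.shape[-1]
    _, inv = _layer_block_matrices(l, k2)
    x = t.reshape(lead + (l * k2, p * p))
    x = np.swapaxes(x, -1, -2) @ inv.astype(t.dtype).T
    t = np.swapaxes(x, -1, -2).reshape(lead + (l, k2, p, p))
    if k is not None and k != t.shape[-3]:
        t = t[..., :k, :, :]
    return _dwt2_inverse(t, wavelet, levels)


@lru_cache(maxsize=8)
def _wavelet_noise_gain(wavelet: str, patch: int, levels: int = 0) -> np.ndarray:
    """Per-coefficient noise std gain of the patch wavelet for unit white
    noise, computed from the analysis operator (biorthogonal wavelets are
    not orthonormal, so the gain differs per subband)."""
    a, _ = _patch_transform_matrices(wavelet, patch, _resolve_levels(patch, levels))
    return np.sqrt((a**2).sum(axis=1)).reshape(patch, patch)


def _layer_cov_rel(cfg: PPConfig) -> np.ndarray:
    """Layer-axis noise covariance relative to sigma^2.

    Virtual-pair layers have variance 3 (their noise sums three channels);
    duplicated layers in the no-pair ablation are perfectly correlated."""
    if cfg.mode == "bm3d_single_frame":
        return np.array([[1.0]])
    f = cfg.n_frames
    c = np.zeros((2 * f, 2 * f))
    for i in range(f):
        if cfg.mode == "ppbm4d":
            c[2 * i, 2 * i] = 1.0
            c[2 * i + 1, 2 * i + 1] = 3.0
        else:  # bm4d_no_pp: I' layer is a copy of I
            c[2 * i : 2 * i + 2, 2 * i : 2 * i + 2] = 1.0
    return c


def _sigma_coeff(cfg: PPConfig, sigma: float) -> np.ndarray:
    """Per-coefficient noise std, shape (L, 1, p, p), after the full 4-D
    transform (Hadamard has unit gain)."""
    cov = _layer_cov_rel(cfg)
    l = cov.shape[0]
    dmat = dct(np.eye(l), type=2, norm="ortho", axis=0)
    var_rel = np.clip(np.diag(dmat @ cov @ dmat.T), 0.0, None)
    wgain = _wavelet_noise_gain(cfg.wavelet, cfg.patch, cfg.wavelet_level)
    return sigma * np.sqrt(var_rel)[:, None, None, None] * wgain[None, None, :, :]


# ---------------------------------------------------------------------------
# collaborative filtering

def hard_threshold(g: np.ndarray, sigma_coeff, tau: float = 3.0, wavelet: str = "bior1.5", levels: int = 0):
    """Hard-threshold collaborative filtering of groups (..., L, K, p, p).

    Transform coefficients with ``|c| < tau * sigma_coeff`` are zeroed
    (the group DC coefficient is exempt); returns the reconstructed groups,
    aggregation weights ``1 / max(N_retained, 1)`` and the retained-count
    array.  ``sigma_coeff`` broadcasts against the coefficient array."""
    g = np.asarray(g)
    k = g.shape[-3]
    t = forward_transform_4d(g, wavelet, levels)
    keep = np.abs(t) >= tau * np.asarray(sigma_coeff)
    keep[..., 0, 0, 0, 0] = True  # group DC always survives
    t = np.where(keep, t, 0.0)
    n_retained = keep.reshape(*keep.shape[:-4], -1).sum(axis=-1)
    weight = 1.0 / np.maximum(n_retained, 1)
    return inverse_transform_4d(t, k=k, wavelet=wavelet, levels=levels), weight, n_retained


def wiener_refine(g_noisy: np.ndarray, g_guide: np.ndarray, sigma_coeff, lam: float = 1.0, wavelet: str = "bior1.5", levels: int = 0):
    """Empirical Wiener refinement guided by the stage-1 estimate.

    Shrinkage ``w = G^2 / (G^2 + lam * sigma^2)`` per coefficient with G
    the guide's coefficient; aggregation weight ``1 / sum(w^2 sigma^2)``."""
    g_noisy = np.asarray(g_noisy)
    g_guide = np.asarray(g_guide)
    if g_noisy.shape != g_guide.shape:
        raise ValueError("noisy and guide groups must share shape")
    k = g_noisy.shape[-3]
    sig2 = np.square(np.asarray(sigma_coeff, dtype=float))
    guide_t = forward_transform_4d(g_guide, wavelet, levels)
    g2 = guide_t**2
    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(sig2 > 0, g2 / (g2 + lam * sig2), 1.0)
    t = w * forward_transform_4d(g_noisy, wavelet, levels)
    wsum = (w**2 * sig2).reshape(*w.shape[:-4], -1).sum(axis=-1)
    # sigma = 0 makes the filter an identity; fall back to uniform weights
    weight = np.where(wsum > 0, 1.0 / np.maximum(wsum, np.finfo(float).tiny), 1.0)
    return inverse_transform_4d(t, k=k, wavelet=wavelet, levels=levels), weight


def aggregate(estimates: np.ndarray, coords: np.ndarray, weights: np.ndarray, shape: tuple[int, int]) -> np.ndarray:
    """Weighted average of overlapping patch estimates into one image.

    ``estimates`` (N, K, p, p) with per-group weights (N,) placed at
    top-left ``coords`` (N, K, 2).  Every pixel must be covered by at least
    one patch (guaranteed by the edge-covering reference grid)."""
    estimates = np.asarray(estimates, dtype=float)
    coords = np.asarray(coords)
    weights = np.asarray(weights, dtype=float)
    h, w = shape
    n, k, p, _ = estimates.shape
    base = coords[..., 0] * w + coords[..., 1]  # (N, K)
    offs = (np.arange(p)[:, None] * w + np.arange(p)[None, :]).ravel()
    idx = (base[..., None] + offs[None, None, :]).ravel()
    vals = (estimates.reshape(n, k, -1).astype(float) * weights[:, None, None]).ravel()
    num = np.bincount(idx, weights=vals, minlength=h * w)
    den = np.bincount(idx, weights=np.broadcast_to(weights[:, None, None], (n, k, p * p)).ravel(), minlength=h * w)
    if np.any(den == 0):
        raise ValueError("aggregation left uncovered pixels (reference grid contract violated)")
    return (num / den).reshape(h, w)


def estimate_sigma(image: np.ndarray) -> float:
    """Additive-noise SD via the median absolute deviation of the finest
    diagonal wavelet subband, MAD / 0.6745."""
    _, (_, _, cd) = pywt.dwt2(np.asarray(image, dtype=float), "db1")
    return float(np.median(np.abs(cd)) / 0.6745)


# ---------------------------------------------------------------------------
# full two-stage pipeline

def _frame_layers(frame: np.ndarray, cfg: PPConfig) -> list[np.ndarray]:
    """[I_c, I'_c] layer images of one (4, H, W) frame for every channel:
    returns a (2 or 1, 4, H, W) array-like list indexable as [li][c]."""
    if cfg.layers_per_frame == 1:
        return [frame]
    virt = generate_pairs(frame) if cfg.mode == "ppbm4d" else frame
    return [frame, virt]


def _run_stage(
    noisy: np.ndarray,
    guide: np.ndarray | None,
    cfg: PPConfig,
    sigmas: np.ndarray,
) -> np.ndarray:
    """One filtering pass over the video, causal in time.

    The temporal context of frame t is the best causally available
    estimate of the preceding frames: in stage 1 the pass's own output
    (the pilot frames already computed), in stage 2 the pilot ("standard")
    video.  Frame 0 replicates its own input as context.  Matching runs on
    the stacked channel-0 layer images; coordinates are shared by all four
    channels.
    """
    n_t, _, h, w = noisy.shape
    n_ctx = 1 if cfg.mode == "bm3d_single_frame" else cfg.n_frames
    noisy = noisy.astype(np.float32)  # group filtering runs in single precision
    guide = guide.astype(np.float32) if guide is not None else None
    sig_coeff = [_sigma_coeff(cfg, float(s)).astype(np.float32) for s in sigmas]
    out = np.empty((n_t, 4, h, w))

    # stage-2 context source is the pilot video; stage-1 context is filled
    # from `out` as frames are produced
    ctx_source = guide
    ctx_layer_cache: dict[int, list[np.ndarray]] = {}

    def context_layers(t: int) -> list[list[np.ndarray]]:
        """Layer images [li][c] for frames t-1, ... (cfg.n_frames-1 of them)."""
        frames = []
        for i in range(1, n_ctx):
            f = t - i
            if f < 0:
                frames.append(_frame_layers(noisy[0], cfg))
            elif ctx_source is not None:
                frames.append(_frame_layers(ctx_source[f], cfg))
            else:
                if f not in ctx_layer_cache:
                    ctx_layer_cache[f] = _frame_layers(out[f].astype(np.float32), cfg)
                frames.append(ctx_layer_cache[f])
        return frames

    for t in range(n_t):
        if cfg.mode == "bm3d_single_frame":
            # independent per-channel matching and filtering
            match_base = noisy if guide is None else guide
            for c in range(4):
                refs, coords, _ = _block_match_arrays(match_base[t, c], cfg)
                g = _extract_groups([noisy[t, c]], coords, cfg.patch)
                if guide is None:
                    filt, wgt, _ = hard_threshold(g, sig_coeff[c], cfg.hard_tau, cfg.wavelet, cfg.wavelet_level)
                else:
                    gg = _extract_groups([guide[t, c]], coords, cfg.patch)
                    filt, wgt = wiener_refine(g, gg, sig_coeff[c], cfg.wiener_lambda, cfg.wavelet, cfg.wavelet_level)
                out[t, c] = aggregate(filt[:, 0], coords, wgt, (h, w))
            continue

        cur_noisy = _frame_layers(noisy[t], cfg)
        cur_guide = _frame_layers(guide[t], cfg) if guide is not None else None
        ctx = context_layers(t)

        # shared matching on the stacked 0-degree layers (guide stack in
        # the Wiener pass, per re-matching on the standard video)
        match_cur = cur_guide if guide is not None else cur_noisy
        match_layers = [li[0] for li in match_cur] + [li[0] for fr in ctx for li in fr]
        refs, coords, _ = _block_match_arrays(match_layers, cfg)

        for c in range(4):
            layers = [li[c] for li in cur_noisy] + [li[c] for fr in ctx for li in fr]
            g = _extract_groups(layers, coords, cfg.patch)
            if guide is None:
                filt, wgt, _ = hard_threshold(g, sig_coeff[c], cfg.hard_tau, cfg.wavelet, cfg.wavelet_level)
            else:
                glayers = [li[c] for li in cur_guide] + [li[c] for fr in ctx for li in fr]
                gg = _extract_groups(glayers, coords, cfg.patch)
                filt, wgt = wiener_refine(g, gg, sig_coeff[c], cfg.wiener_lambda, cfg.wavelet, cfg.wavelet_level)
            # the I(t) frame-layer (index 0) is the estimate of frame t
            out[t, c] = aggregate(filt[:, 0], coords, wgt, (h, w))
    return out


def denoise(video: PolVideo, cfg: PPConfig | None = None) -> PolVideo:
    """Two-stage collaborative-filtering denoising of a quad-polarization video.

    Stage 1 hard-thresholds the 4-D groups to produce the pilot ("standard")
    video; stage 2 re-matches on the pilot's 0-degree channel and applies
    guided empirical Wiener shrinkage to the original data.  The filter is
    causal: only past frames enter the temporal context.
    """
    cfg = cfg or PPConfig()
    n_ctx = 1 if cfg.mode == "bm3d_single_frame" else cfg.n_frames
    if video.n_frames < n_ctx:
        raise ValueError(f"need at least {n_ctx} frames, got {video.n_frames}")
    data = np.asarray(video.data, dtype=float)
    if cfg.sigma is not None:
        sigmas = np.full(4, float(cfg.sigma))
    else:
        sigmas = np.array([estimate_sigma(data[0, c]) for c in range(4)])

    pilot = _run_stage(data, None, cfg, sigmas)
    final = _run_stage(data, pilot, cfg, sigmas)
    meta = dict(video.meta, denoised={"mode": cfg.mode, "n_frames": cfg.n_frames, "sigma": sigmas.tolist()})
    return PolVideo(data=final, frame_rate=video.frame_rate, meta=meta)


def config_for_mode(mode: str, base: PPConfig | None = None, **overrides) -> PPConfig:
    """Convenience constructor for the ablation modes."""
    cfg = base or PPConfig()
    if mode == "bm3d_single_frame":
        overrides.setdefault("n_frames", 1)
    return replace(cfg, mode=mode, **overrides)
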