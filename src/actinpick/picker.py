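"""Micrograph-to-coordinates picking pipeline.

A motion-corrected micrograph (native pixel size 1.09 Å) is Fourier-crop
downsampled by 4 (to 4.36 Å/px), cut into 128-px tiles in a raster with
32 px overlap, segmented tile by tile, stitched back by per-channel
maximum-intensity projection, and the decorated-filament channel is
binarized at 0.8, skeletonized, and reduced to particle coordinates by
greedy non-maximum suppression with a 44 Å minimum spacing.

Conventions (this package's, where the procedure leaves them open):
after max-stitching the channels are renormalized to sum to one, so the
0.8 threshold stays on a probability scale; NMS ranks skeleton pixels
by the stitched decorated-channel probability with ties broken in
row-major order; edge tiles are clamped to the image boundary rather
than padded.  Output coordinates are 0-based full-resolution pixel
centres with x = column, y = row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree
from skimage.morphology import skeletonize as _sk_skeletonize

from .exceptions import ParameterError
from .targets import CHANNEL_NAMES, SemanticTarget

__all__ = [
    "Micrograph",
    "PickerParams",
    "SegmentationMap",
    "PickList",
    "downsample",
    "tile_raster",
    "stitch_max",
    "binarize_channel",
    "skeletonize",
    "nms_picks",
    "pick_micrograph",
    "pick_from_truth",
]


@dataclass
class Micrograph:
    """A 2-D micrograph with its native pixel size in Å."""

    image: np.ndarray
    pixel_size: float
    path: Optional[str] = None

    def __post_init__(self) -> None:
        self.image = np.asarray(self.image, dtype=np.float32)
        if self.image.ndim != 2:
            raise ParameterError("micrograph image must be 2-D")
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")
        if not np.all(np.isfinite(self.image)):
            raise ParameterError("micrograph contains non-finite values")


@dataclass(frozen=True)
class PickerParams:
    downsample_factor: int = 4
    tile_px: int = 128
    overlap_px: int = 32
    channel: str = "decorated"
    binarize_threshold: float = 0.8
    min_spacing_A: float = 44.0

    def validate(self) -> None:
        if not 0 < self.overlap_px < self.tile_px:
            raise ParameterError("overlap_px must satisfy 0 < overlap < tile_px")
        if not 0 < self.binarize_threshold < 1:
            raise ParameterError("binarize_threshold must lie in (0, 1)")
        if self.min_spacing_A <= 0:
            raise ParameterError("min_spacing_A must be positive")
        if self.downsample_factor < 1:
            raise ParameterError("downsample_factor must be >= 1")


@dataclass
class SegmentationMap:
    """Stitched per-channel probability map at the downsampled scale."""

    channels: np.ndarray  # (3, H, W)
    pixel_size: float

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.float32)
        if self.channels.ndim != 3:
            raise ParameterError("SegmentationMap channels must be (C, H, W)")


@dataclass
class PickList:
    """Scored 2-D particle coordinates with a minimum-spacing guarantee.

    ``coords`` are ``(x, y)`` pairs in pixels of the frame indicated by
    ``pixel_size`` (Å per coordinate unit).
    """

    coords: np.ndarray
    scores: np.ndarray
    pixel_size: float
    micrograph: Optional[str] = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float).reshape(-1, 2)
        self.scores = np.asarray(self.scores, dtype=float).reshape(-1)

    def __len__(self) -> int:
        return len(self.coords)

    def min_pairwise_spacing_A(self) -> float:
        """Minimum pairwise Euclidean distance in Å (inf for < 2 picks)."""
        if len(self) < 2:
            return float("inf")
        d = cKDTree(self.coords).query(self.coords, k=2)[0][:, 1]
        return float(d.min() * self.pixel_size)


def downsample(m: Micrograph, factor: int) -> Micrograph:
    """Fourier-crop downsampling: discard frequencies above the new Nyquist.

    DC and every surviving Fourier component keep their amplitude; the
    output pixel size is ``factor`` times the input's.  Dimensions not
    divisible by ``factor`` are trimmed at the high edge first.
    """
    if factor < 1:
        raise ParameterError("downsample factor must be >= 1")
    if factor == 1:
        return m
    img = m.image
    h = (img.shape[0] // factor) * factor
    w = (img.shape[1] // factor) * factor
    if h == 0 or w == 0:
        raise ParameterError("micrograph smaller than the downsampling factor")
    img = img[:h, :w].astype(np.float64)
    out_h, out_w = h // factor, w // factor
    spec = np.fft.fftshift(np.fft.fft2(img))
    cy, cx = h // 2, w // 2
    half_h, half_w = out_h // 2, out_w // 2
    crop = spec[cy - half_h : cy - half_h + out_h, cx - half_w : cx - half_w + out_w]
    small = np.fft.ifft2(np.fft.ifftshift(crop)).real * (out_h * out_w) / (h * w)
    return Micrograph(small.astype(np.float32), m.pixel_size * factor, m.path)


def tile_raster(
    image: np.ndarray, tile_px: int, overlap_px: int
) -> Tuple[List[np.ndarray], List[Tuple[int, int]]]:
    """Cut an image into overlapping tiles on a raster grid.

    Origins advance by ``tile_px - overlap_px``; the final tile on each
    axis is clamped to end exactly at the image edge, so every pixel is
    covered at least once and no pixels are fabricated.
    Returns ``(tiles, origins)`` with origins as ``(row, col)``.
    """
    if not 0 < overlap_px < tile_px:
        raise ParameterError("need 0 < overlap_px < tile_px")
    h, w = image.shape[:2]
    if h < tile_px or w < tile_px:
        raise ParameterError(
            f"image {image.shape} smaller than tile size {tile_px}"
        )
    stride = tile_px - overlap_px

    def axis_origins(size: int) -> List[int]:
        origins = list(range(0, size - tile_px + 1, stride))
        if origins[-1] + tile_px < size:
            origins.append(size - tile_px)
        return origins

    tiles, origins = [], []
    for oy in axis_origins(h):
        for ox in axis_origins(w):
            tiles.append(image[oy : oy + tile_px, ox : ox + tile_px])
            origins.append((oy, ox))
    return tiles, origins


def stitch_max(
    tile_maps: Sequence[np.ndarray],
    origins: Sequence[Tuple[int, int]],
    out_shape: Tuple[int, int],
    pixel_size: float = 4.36,
    renormalize: bool = True,
) -> SegmentationMap:
    """Stitch per-tile channel maps by per-pixel maximum-intensity projection.

    ``max`` over overlapping tiles breaks the per-pixel sum-to-one
    property, so channels are renormalized afterwards by default.  The
    result is order-invariant in the tile sequence.
    """
    if len(tile_maps) != len(origins):
        raise ParameterError("tile_maps and origins must be aligned")
    n_ch = tile_maps[0].shape[0]
    out = np.full((n_ch,) + tuple(out_shape), -np.inf, dtype=np.float32)
    for tm, (oy, ox) in zip(tile_maps, origins):
        th, tw = tm.shape[1:]
        if oy < 0 or ox < 0 or oy + th > out_shape[0] or ox + tw > out_shape[1]:
            raise ParameterError(f"tile origin {(oy, ox)} outside output {out_shape}")
        region = out[:, oy : oy + th, ox : ox + tw]
        np.maximum(region, tm, out=region)
    if np.any(np.isneginf(out)):
        raise ParameterError("tiles do not cover the full output")
    if renormalize:
        out = out / out.sum(axis=0, keepdims=True)
    return SegmentationMap(out, pixel_size)


def _channel_index(channel) -> int:
    if isinstance(channel, (int, np.integer)):
        return int(channel)
    try:
        return CHANNEL_NAMES.index(channel)
    except ValueError:
        raise ParameterError(
            f"unknown channel {channel!r}; expected one of {CHANNEL_NAMES}"
        ) from None


def binarize_channel(seg: SegmentationMap, channel="decorated", threshold: float = 0.8):
    """Threshold one channel; returns ``(mask, score_map)``.

    ``score_map`` is the pre-binarization channel, kept as the ranking
    score for NMS.
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must lie in (0, 1)")
    ch = seg.channels[_channel_index(channel)]
    return ch >= threshold, ch


def skeletonize(mask: np.ndarray) -> np.ndarray:
    """Topology-preserving thinning of a binary mask to 1-px width."""
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        return mask.copy()
    return _sk_skeletonize(mask)


def nms_picks(
    skeleton: np.ndarray,
    score_map: np.ndarray,
    min_spacing_A: float,
    pixel_size_A: float,
    micrograph: Optional[str] = None,
) -> PickList:
    """Greedy non-maximum suppression over skeleton pixels.

    Candidates are visited in descending score (ties broken by row-major
    pixel order); each accepted pick suppresses every remaining
    candidate within ``min_spacing_A`` Euclidean distance.  Every
    suppressed candidate is therefore within the spacing radius of a
    higher-or-equal-scored accepted pick.
    """
    if pixel_size_A <= 0:
        raise ParameterError("pixel_size_A must be positive")
    ys, xs = np.nonzero(skeleton)
    if len(ys) == 0:
        return PickList(np.empty((0, 2)), np.empty(0), pixel_size_A, micrograph)
    scores = np.asarray(score_map)[ys, xs].astype(float)
    # primary: score descending; then row, then column ascending
    order = np.lexsort((xs, ys, -scores))
    pts = np.stack([xs, ys], axis=1).astype(float)
    tree = cKDTree(pts)
    radius_px = min_spacing_A / pixel_size_A
    alive = np.ones(len(pts), dtype=bool)
    kept: List[int] = []
    for idx in order:
        if not alive[idx]:
            continue
        kept.append(idx)
        for j in tree.query_ball_point(pts[idx], radius_px):
            alive[j] = False
    return PickList(pts[kept], scores[kept], pixel_size_A, micrograph)


def _segment_tiles(model, tiles: Sequence[np.ndarray]) -> List[np.ndarray]:
    stack = np.stack(tiles).astype(np.float32)
    proba = model.predict_proba(stack)
    return [proba[i] for i in range(len(tiles))]


def pick_micrograph(
    m: Micrograph,
    model,
    params: PickerParams = PickerParams(),
    segmentation: Optional[SegmentationMap] = None,
) -> PickList:
    """End-to-end picking: downsample, tile, segment, stitch, extract.

    ``model`` must map a stack of square tiles to per-pixel 3-channel
    probabilities via ``predict_proba`` (any architecture satisfying
    that contract plugs in).  ``segmentation`` overrides the model
    output with a precomputed map (oracle hook used in validation).
    The pipeline is deterministic for fixed weights and parameters.
    """
    params.validate()
    try:
        if segmentation is None:
            small = downsample(m, params.downsample_factor)
            tiles, origins = tile_raster(small.image, params.tile_px, params.overlap_px)
            maps = _segment_tiles(model, tiles)
            segmentation = stitch_max(
                maps, origins, small.image.shape, pixel_size=small.pixel_size
            )
        mask, score_map = binarize_channel(
            segmentation, params.channel, params.binarize_threshold
        )
        skel = skeletonize(mask)
        picks = nms_picks(
            skel,
            score_map,
            params.min_spacing_A,
            segmentation.pixel_size,
            micrograph=m.path,
        )
    except ParameterError as exc:
        raise ParameterError(f"{m.path or 'micrograph'}: {exc}") from exc
    # rescale to the full-resolution frame
    factor = segmentation.pixel_size / m.pixel_size
    return PickList(picks.coords * factor, picks.scores, m.pixel_size, m.path)


def pick_from_truth(
    target: SemanticTarget,
    params: PickerParams = PickerParams(),
    pixel_size_A: float = 4.36,
) -> PickList:
    """Network-free picking path: run extraction on a one-hot target.

    The decorated channel is used directly as both mask and score map
    (scores are 1, ties resolved row-major), exercising
    binarize -> skeletonize -> NMS without a trained model.
    """
    params.validate()
    seg = SegmentationMap(target.channels.astype(np.float32), pixel_size_A)
    mask, score_map = binarize_channel(seg, params.channel, params.binarize_threshold)
    skel = skeletonize(mask)
    return nms_picks(skel, score_map, params.min_spacing_A, pixel_size_A)
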