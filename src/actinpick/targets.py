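"""One-hot semantic ground truth for rendered scenes.

Each per-filament noiseless projection is low-pass filtered at 30 Å,
binarized at a fraction of its own maximum, and merged into a
three-channel one-hot map with channel order
``(background, bare, decorated)``.  Pixels covered by both a bare and a
decorated filament are labelled decorated (decoration takes priority).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .exceptions import ParameterError

__all__ = ["TargetParams", "SemanticTarget", "make_semantic_target", "lowpass_filter"]

#: Channel indices of the semantic map.
CHANNEL_BACKGROUND, CHANNEL_BARE, CHANNEL_DECORATED = 0, 1, 2
CHANNEL_NAMES = ("background", "bare", "decorated")


@dataclass(frozen=True)
class TargetParams:
    """Semantic-target construction parameters.

    ``lowpass_A`` is the low-pass cutoff in Å (hard Fourier cutoff by
    default, Gaussian when ``soft_filter``); ``binarize_frac`` is the
    per-filament threshold as a fraction of that filament's maximum
    after filtering.  ``label_mode`` is ``"whole"`` (the entire
    decorated filament is labelled decorated) or ``"interface"`` (only a
    disc of ``interface_radius_A`` around the projected interface).
    """

    lowpass_A: float = 30.0
    binarize_frac: float = 0.2
    pixel_size_A: float = 4.36
    soft_filter: bool = False
    label_mode: str = "whole"
    interface_radius_A: float = 60.0

    def validate(self) -> None:
        if self.lowpass_A <= 0 or self.pixel_size_A <= 0:
            raise ParameterError("lowpass_A and pixel_size_A must be positive")
        if not 0 < self.binarize_frac < 1:
            raise ParameterError("binarize_frac must lie in (0, 1)")
        if self.label_mode not in ("whole", "interface"):
            raise ParameterError(f"unknown label_mode {self.label_mode!r}")


@dataclass
class SemanticTarget:
    """One-hot ``(3, H, W)`` semantic map."""

    channels: np.ndarray
    lowpass_A: float = 30.0
    binarize_frac: float = 0.2

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels, dtype=np.uint8)
        if self.channels.ndim != 3 or self.channels.shape[0] != 3:
            raise ParameterError("SemanticTarget channels must have shape (3, H, W)")

    def is_one_hot(self) -> bool:
        return bool(np.all(self.channels.sum(axis=0) == 1))


def lowpass_filter(
    image: np.ndarray, cutoff_A: float, pixel_size_A: float, soft: bool = False
) -> np.ndarray:
    """Low-pass filter at a physical resolution cutoff.

    Hard variant zeroes all Fourier components with ``|k| > 1/cutoff_A``;
    soft variant applies a Gaussian falling to 1/e at the cutoff.
    """
    f = np.fft.fftfreq(image.shape[0], d=pixel_size_A)
    fy = np.fft.fftfreq(image.shape[1], d=pixel_size_A)
    kx, ky = np.meshgrid(fy, f)
    k = np.sqrt(kx * kx + ky * ky)
    kc = 1.0 / cutoff_A
    mask = np.exp(-((k / kc) ** 2)) if soft else (k <= kc).astype(float)
    return np.fft.ifft2(np.fft.fft2(image) * mask).real


def _filament_mask(image: np.ndarray, params: TargetParams) -> np.ndarray:
    lp = lowpass_filter(image, params.lowpass_A, params.pixel_size_A, params.soft_filter)
    peak = lp.max()
    if peak <= 0:
        return np.zeros(image.shape, dtype=bool)
    return lp >= params.binarize_frac * peak


def make_semantic_target(
    per_filament_images: Sequence[np.ndarray],
    decorated_flags: Sequence[bool],
    params: TargetParams = TargetParams(),
    interface_xy_px: Optional[Sequence[Optional[Tuple[float, float]]]] = None,
    shape: Tuple[int, int] = (128, 128),
) -> SemanticTarget:
    """Build the one-hot target from per-filament noiseless renders.

    Parameters
    ----------
    per_filament_images:
        Noiseless projection of each filament, all sharing one shape.
    decorated_flags:
        Whether each filament is decorated; aligned with the images.
    interface_xy_px:
        Projected ``(x, y)`` interface positions in pixels, required per
        decorated filament when ``params.label_mode == "interface"``.
    shape:
        Map shape used when the scene is empty (otherwise taken from
        the per-filament images).

    The construction is a deterministic function of its inputs.
    """
    params.validate()
    if len(per_filament_images) != len(decorated_flags):
        raise ParameterError("images and decorated_flags must be aligned")
    if per_filament_images:
        shape = per_filament_images[0].shape
        if any(img.shape != shape for img in per_filament_images):
            raise ParameterError("per-filament images must share one shape")

    bare_mask = np.zeros(shape, dtype=bool)
    decorated_mask = np.zeros(shape, dtype=bool)
    for idx, (img, is_dec) in enumerate(zip(per_filament_images, decorated_flags)):
        mask = _filament_mask(np.asarray(img, dtype=float), params)
        if is_dec and params.label_mode == "interface":
            if interface_xy_px is None or interface_xy_px[idx] is None:
                raise ParameterError(
                    "interface label_mode requires interface_xy_px per decorated filament"
                )
            cx, cy = interface_xy_px[idx]
            yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
            r_px = params.interface_radius_A / params.pixel_size_A
            disc = (xx - cx) ** 2 + (yy - cy) ** 2 <= r_px**2
            decorated_mask |= mask & disc
            bare_mask |= mask & ~disc
        elif is_dec:
            decorated_mask |= mask
        else:
            bare_mask |= mask

    bare_mask &= ~decorated_mask  # decoration takes priority
    channels = np.zeros((3,) + shape, dtype=np.uint8)
    channels[CHANNEL_DECORATED] = decorated_mask
    channels[CHANNEL_BARE] = bare_mask
    channels[CHANNEL_BACKGROUND] = ~(bare_mask | decorated_mask)
    return SemanticTarget(channels, params.lowpass_A, params.binarize_frac)
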