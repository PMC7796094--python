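"""Three-channel input engineering for the segmentation network.

Each HU slice is re-expressed as an H x W x 3 stack: channel 0 is the
original image min-max normalized over a lung display window, channel 1 is
a Canny edge map, and channel 2 is the dilation of a binary image in which
the lung is black (0) and everything brighter is white (1) — the dilation
shrinks the dark lung area and removes small dark noise around it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage import feature

from .io import CTSlice
from .morphology import DEFAULT_THRESHOLD_HU, StructuringElement, binarize_hu, dilate


@dataclass(frozen=True)
class ChannelParams:
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    window_hu: tuple = (-1000.0, 400.0)  # standard lung display window
    canny_sigma: float = 2.0
    canny_low: float = 0.70   # hysteresis thresholds; quantiles of the
    canny_high: float = 0.90  # gradient magnitude unless use_quantiles=False
    canny_use_quantiles: bool = True
    dilation_radius: int = 2


def binarize_for_channels(
    ct: CTSlice, threshold_hu: float = DEFAULT_THRESHOLD_HU
) -> np.ndarray:
    """Binary image with the lung black: 0 where HU < threshold, else 1.

    Polarity is inverted relative to the ground-truth binarization (there
    the lung candidate is the foreground 1).
    """
    return (1 - binarize_hu(ct, threshold_hu)).astype(np.uint8)


def dilation_channel(binary: np.ndarray, selem: StructuringElement | None = None) -> np.ndarray:
    """Dilate the white foreground; the black lung region shrinks."""
    if selem is None:
        selem = StructuringElement(2)
    return dilate(binary, selem)


def normalize_window(ct: CTSlice, window_hu: tuple = (-1000.0, 400.0)) -> np.ndarray:
    """Clip HU to the window and min-max scale to [0, 1]."""
    lo, hi = float(window_hu[0]), float(window_hu[1])
    if hi <= lo:
        warnings.warn("degenerate HU window (max <= min); channel set to 0", stacklevel=2)
        return np.zeros_like(ct.pixels, dtype=np.float32)
    return np.clip((ct.pixels - lo) / (hi - lo), 0.0, 1.0).astype(np.float32)


def canny_edges(
    ct: CTSlice,
    sigma: float = 2.0,
    low: float = 0.70,
    high: float = 0.90,
    use_quantiles: bool = True,
    window_hu: tuple = (-1000.0, 400.0),
) -> np.ndarray:
    """Canny edge map of the (window-normalized) slice.

    Gaussian smoothing -> gradient magnitude/direction -> non-maximum
    suppression -> double-threshold hysteresis. With ``use_quantiles`` the
    thresholds are quantiles of the gradient magnitude in [0, 1].
    """
    if low < 0 or low > high:
        raise ValueError(f"require 0 <= low <= high, got low={low}, high={high}")
    img = normalize_window(ct, window_hu)
    if np.ptp(img) == 0:
        # zero gradient everywhere; quantile thresholds would degenerate to 0
        return np.zeros_like(img, dtype=np.uint8)
    edges = feature.canny(
        img, sigma=sigma, low_threshold=low, high_threshold=high,
        use_quantiles=use_quantiles,
    )
    return edges.astype(np.uint8)


def assemble_channels(ct: CTSlice, params: ChannelParams = ChannelParams()) -> np.ndarray:
    """Build the engineered H x W x 3 input (original / edges / dilation)."""
    ch0 = normalize_window(ct, params.window_hu)
    ch1 = canny_edges(
        ct,
        sigma=params.canny_sigma,
        low=params.canny_low,
        high=params.canny_high,
        use_quantiles=params.canny_use_quantiles,
        window_hu=params.window_hu,
    )
    ch2 = dilation_channel(
        binarize_for_channels(ct, params.threshold_hu),
        StructuringElement(params.dilation_radius),
    )
    return np.stack(
        [ch0, ch1.astype(np.float32), ch2.astype(np.float32)], axis=-1
    )


def replicate_default_channels(
    ct: CTSlice, params: ChannelParams = ChannelParams()
) -> np.ndarray:
    """Ablation arm: the normalized original image in all three channels."""
    ch0 = normalize_window(ct, params.window_hu)
    return np.stack([ch0, ch0, ch0], axis=-1)
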