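"""Semi-automatic lung-mask extraction from HU slices.

The ground-truth pipeline runs seven steps in strict sequence: threshold at
-604 HU (lung parenchyma is darker), remove blobs touching the image border,
label connected components, keep the two largest (the lungs), erode with a
disk of radius 2, close with a disk of radius 10 (to retain juxtapleural
nodules), and fill enclosed holes (vessels). Masks are {0,1} uint8 arrays
with lung = 1.

The individual operators follow the classical Minkowski set definitions:
out-of-frame pixels are background, the structuring element is the discrete
Euclidean disk {(dy,dx): dy^2+dx^2 <= r^2}, and closing is literally
erode(dilate(mask)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .io import CTSlice

DEFAULT_THRESHOLD_HU = -604.0


def disk_footprint(radius: int) -> np.ndarray:
    """Discrete Euclidean disk: pixels with dy^2 + dx^2 <= radius^2."""
    if radius < 1:
        raise ValueError("radius must be a positive integer")
    r = int(radius)
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    return (dy**2 + dx**2 <= r**2).astype(np.uint8)


@dataclass(frozen=True)
class StructuringElement:
    """A symmetric disk footprint for the morphological operators."""

    radius: int
    kind: str = "disk"
    footprint: np.ndarray = field(default=None, compare=False)

    def __post_init__(self):
        if self.kind != "disk":
            raise ValueError(f"unsupported structuring element kind {self.kind!r}")
        object.__setattr__(self, "footprint", disk_footprint(self.radius))


class LabelMap(NamedTuple):
    """Connected-component labels (0 = background, 1..n_labels = regions)."""

    labels: np.ndarray
    n_labels: int


def _check_mask(mask: np.ndarray) -> np.ndarray:
    arr = np.asarray(mask)
    if arr.ndim != 2:
        raise ValueError("mask must be 2-D")
    if arr.dtype != bool and not np.all(np.isin(np.unique(arr), (0, 1))):
        raise ValueError("mask values must be exactly 0 or 1")
    return arr.astype(bool)


def _structure(connectivity: int) -> np.ndarray:
    if connectivity == 8:
        return ndimage.generate_binary_structure(2, 2)
    if connectivity == 4:
        return ndimage.generate_binary_structure(2, 1)
    raise ValueError("connectivity must be 4 or 8")


def binarize_hu(ct: CTSlice, threshold_hu: float = DEFAULT_THRESHOLD_HU) -> np.ndarray:
    """Lung-candidate mask: 1 where HU is strictly below the threshold."""
    return (ct.pixels < threshold_hu).astype(np.uint8)


def clear_border(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Zero every foreground component that contains a border pixel."""
    m = _check_mask(mask)
    labels, n = ndimage.label(m, structure=_structure(connectivity))
    if n == 0:
        return m.astype(np.uint8)
    border = np.zeros_like(m)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    touching = np.unique(labels[border & m])
    keep = m & ~np.isin(labels, touching)
    return keep.astype(np.uint8)


def label_components(mask: np.ndarray, connectivity: int = 8) -> LabelMap:
    """Label maximal connected foreground regions 1..n."""
    m = _check_mask(mask)
    labels, n = ndimage.label(m, structure=_structure(connectivity))
    return LabelMap(labels=labels.astype(np.int32), n_labels=int(n))


def keep_largest_k(labelmap: LabelMap, k: int = 2) -> np.ndarray:
    """Union of the k largest components by pixel area (ties: smaller label)."""
    if k < 1:
        raise ValueError("k must be a positive integer")
    labels, n = labelmap
    if n == 0:
        return np.zeros_like(labels, dtype=np.uint8)
    areas = np.bincount(labels.ravel(), minlength=n + 1)[1:]
    order = sorted(range(1, n + 1), key=lambda lab: (-areas[lab - 1], lab))
    keep = order[:k]
    return np.isin(labels, keep).astype(np.uint8)


def erode(mask: np.ndarray, selem: StructuringElement) -> np.ndarray:
    """Minkowski erosion; out-of-frame counts as background."""
    m = _check_mask(mask)
    return ndimage.binary_erosion(m, structure=selem.footprint, border_value=0).astype(
        np.uint8
    )


def dilate(mask: np.ndarray, selem: StructuringElement) -> np.ndarray:
    """Minkowski dilation: union of the mask translated by every selem offset."""
    m = _check_mask(mask)
    return ndimage.binary_dilation(m, structure=selem.footprint, border_value=0).astype(
        np.uint8
    )


def close(mask: np.ndarray, selem: StructuringElement) -> np.ndarray:
    """Morphological closing: erode(dilate(mask)) on the infinite plane.

    The mask is embedded in a background margin of one structuring-element
    radius before composing the two operators, so the image frame does not
    clip the intermediate dilation; this keeps closing extensive and
    idempotent for foreground near the border.
    """
    m = _check_mask(mask).astype(np.uint8)
    r = selem.radius
    padded = np.pad(m, r)
    closed = erode(dilate(padded, selem), selem)
    return closed[r:-r, r:-r]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Flip background components not 4-connected to the image border."""
    m = _check_mask(mask)
    return ndimage.binary_fill_holes(m, structure=_structure(4)).astype(np.uint8)


@dataclass(frozen=True)
class ExtractionParams:
    threshold_hu: float = DEFAULT_THRESHOLD_HU
    connectivity: int = 8
    keep_k: int = 2
    erosion_radius: int = 2
    closing_radius: int = 10


@dataclass(frozen=True)
class ExtractionResult:
    mask: np.ndarray
    n_components: int
    needs_review: bool  # empty mask: candidate for manual reform


def extract_lung_mask(
    ct: CTSlice, params: ExtractionParams = ExtractionParams()
) -> ExtractionResult:
    """Run the seven-step ground-truth extraction on one slice.

    Pure and deterministic. An empty final mask is returned flagged for
    manual review rather than raised, since threshold/morphology extraction
    is expected to fail on some slices.
    """
    binary = binarize_hu(ct, params.threshold_hu)
    cleared = clear_border(binary, params.connectivity)
    labelmap = label_components(cleared, params.connectivity)
    largest = keep_largest_k(labelmap, params.keep_k)
    eroded = erode(largest, StructuringElement(params.erosion_radius))
    closed = close(eroded, StructuringElement(params.closing_radius))
    filled = fill_holes(closed)
    empty = not bool(filled.any())
    if empty:
        warnings.warn(
            "extracted lung mask is empty; slice flagged for manual review",
            stacklevel=2,
        )
    return ExtractionResult(
        mask=filled, n_components=labelmap.n_labels, needs_review=empty
    )
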