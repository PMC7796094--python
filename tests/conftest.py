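"""Shared fixtures and independent brute-force oracles.

The morphology oracles below implement the raw set definitions of the
operators (explicit loops over structuring-element offsets, flood fills by
breadth-first search) so the package implementations can be checked against
something that shares no code with them.
"""

from collections import deque

import numpy as np
import pytest

from lungseg import CTSlice, PhantomSpec, generate_phantom


# --------------------------------------------------------------------------
# brute-force morphology oracles (set definitions, no scipy/skimage)

def brute_erode(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    r = footprint.shape[0] // 2
    offsets = [(dy - r, dx - r) for dy in range(footprint.shape[0])
               for dx in range(footprint.shape[1]) if footprint[dy, dx]]
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            ok = True
            for dy, dx in offsets:
                yy, xx = y + dy, x + dx
                if not (0 <= yy < h and 0 <= xx < w and mask[yy, xx]):
                    ok = False
                    break
            out[y, x] = 1 if ok else 0
    return out


def brute_dilate(mask: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    h, w = mask.shape
    r = footprint.shape[0] // 2
    out = np.zeros_like(mask)
    for y in range(h):
        for x in range(w):
            if not mask[y, x]:
                continue
            for dy in range(footprint.shape[0]):
                for dx in range(footprint.shape[1]):
                    if footprint[dy, dx]:
                        yy, xx = y + dy - r, x + dx - r
                        if 0 <= yy < h and 0 <= xx < w:
                            out[yy, xx] = 1
    return out


def _neighbours(y, x, h, w, connectivity):
    steps4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    steps8 = steps4 + [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    for dy, dx in (steps8 if connectivity == 8 else steps4):
        yy, xx = y + dy, x + dx
        if 0 <= yy < h and 0 <= xx < w:
            yield yy, xx


def _flood(mask, seeds, connectivity):
    h, w = mask.shape
    seen = np.zeros((h, w), dtype=bool)
    queue = deque((y, x) for y, x in seeds if mask[y, x] and not seen[y, x])
    for y, x in queue:
        seen[y, x] = True
    while queue:
        y, x = queue.popleft()
        for yy, xx in _neighbours(y, x, h, w, connectivity):
            if mask[yy, xx] and not seen[yy, xx]:
                seen[yy, xx] = True
                queue.append((yy, xx))
    return seen


def _border_pixels(h, w):
    return (
        [(0, x) for x in range(w)] + [(h - 1, x) for x in range(w)]
        + [(y, 0) for y in range(h)] + [(y, w - 1) for y in range(h)]
    )


def brute_clear_border(mask: np.ndarray, connectivity: int = 8) -> np.ndarray:
    reached = _flood(mask.astype(bool), _border_pixels(*mask.shape), connectivity)
    return (mask.astype(bool) & ~reached).astype(np.uint8)


def brute_fill_holes(mask: np.ndarray) -> np.ndarray:
    bg = ~mask.astype(bool)
    reachable = _flood(bg, _border_pixels(*mask.shape), connectivity=4)
    return (mask.astype(bool) | (bg & ~reachable)).astype(np.uint8)


def brute_label(mask: np.ndarray, connectivity: int = 8):
    m = mask.astype(bool)
    h, w = m.shape
    labels = np.zeros((h, w), dtype=int)
    n = 0
    for y in range(h):
        for x in range(w):
            if m[y, x] and labels[y, x] == 0:
                n += 1
                comp = _flood(m, [(y, x)], connectivity)
                labels[comp] = n
    return labels, n


# --------------------------------------------------------------------------
# fixtures

@pytest.fixture(scope="session")
def default_phantom():
    return generate_phantom(PhantomSpec(seed=11))


@pytest.fixture(scope="session")
def noiseless_phantom():
    return generate_phantom(PhantomSpec(seed=3, noise_sd=0.0, n_vessels=0))


@pytest.fixture()
def flat_slice():
    def make(value, shape=(16, 16)):
        return CTSlice(np.full(shape, float(value), dtype=np.float32),
                       source="phantom")
    return make


def random_masks(rng, count, max_size=20, min_size=4):
    """Random small binary masks with mixed densities (shared helper)."""
    masks = []
    for _ in range(count):
        h = int(rng.integers(min_size, max_size + 1))
        w = int(rng.integers(min_size, max_size + 1))
        density = rng.uniform(0.15, 0.85)
        masks.append((rng.random((h, w)) < density).astype(np.uint8))
    return masks
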