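"""Synthetic HU-calibrated lung phantoms with exact ground-truth masks.

A phantom slice mimics the gross attenuation structure of an axial chest CT:
air background (~-1000 HU), a soft-tissue body wall ellipse (~+40 HU), two
dark lung ellipses (~-800 HU, well below the -604 HU parenchyma threshold),
bright intra-lung vessels (~0 HU), and optionally a juxtapleural nodule
(~+20 HU) abutting the lung wall. The ground-truth mask is known exactly by
construction (filled lung ellipses plus the nodule disk, vessels included),
so every downstream stage can be scored without external CT archives.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .io import CTSlice

LUNG_THRESHOLD_HU = -604.0

#: clearance (pixels) between nodule rim and lung wall; two pixels beyond
#: the ground-truth pipeline's erosion radius (one for the erosion itself,
#: one for discrete-grid rounding) so the nodule bite stays an enclosed
#: hole that hole-filling recovers in full.
NODULE_WALL_CLEARANCE = 4.0


class PhantomSpecError(ValueError):
    """A phantom specification violates one of its invariants."""


@dataclass(frozen=True)
class Geometry:
    """Ellipse layout as fractions of the frame (rows = y, cols = x)."""

    body_center: tuple = (0.50, 0.50)
    body_axes: tuple = (0.42, 0.46)
    lung_centers: tuple = ((0.50, 0.28), (0.50, 0.72))
    lung_axes: tuple = (0.30, 0.16)
    nodule_angle: float = 3.6  # radians on the left lung ellipse


@dataclass(frozen=True)
class PhantomSpec:
    height: int = 256
    width: int = 256
    background_hu: float = -1000.0
    body_hu: float = 40.0
    lung_hu: float = -800.0
    vessel_hu: float = 0.0
    nodule_hu: float = 20.0
    n_vessels: int = 3
    attach_nodule: bool = False
    nodule_radius: float = 6.0
    noise_sd: float = 20.0
    seed: int = 0
    geometry: Geometry = field(default_factory=Geometry)

    def validate(self) -> None:
        if self.height <= 0 or self.width <= 0:
            raise PhantomSpecError("height and width must be positive")
        if not (self.lung_hu < LUNG_THRESHOLD_HU):
            raise PhantomSpecError(
                f"lung_hu ({self.lung_hu}) must lie below the lung threshold "
                f"({LUNG_THRESHOLD_HU} HU)"
            )
        for name in ("body_hu", "nodule_hu"):
            val = getattr(self, name)
            if not (val > LUNG_THRESHOLD_HU):
                raise PhantomSpecError(
                    f"{name} ({val}) must lie above the lung threshold "
                    f"({LUNG_THRESHOLD_HU} HU)"
                )
        if self.n_vessels < 0:
            raise PhantomSpecError("n_vessels must be non-negative")
        if self.nodule_radius <= 0:
            raise PhantomSpecError("nodule_radius must be positive")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be non-negative")
        body, lungs = self._ellipse_masks()
        interior = ndimage.binary_erosion(body, iterations=2, border_value=0)
        if body[0, :].any() or body[-1, :].any() or body[:, 0].any() or body[:, -1].any():
            raise PhantomSpecError("body ellipse must lie strictly inside the frame")
        for i, lung in enumerate(lungs):
            if not lung.any():
                raise PhantomSpecError(f"lung ellipse {i} is empty")
            if np.any(lung & ~interior):
                raise PhantomSpecError(
                    f"lung ellipse {i} must lie strictly inside the body ellipse"
                )
        if np.any(lungs[0] & lungs[1]):
            raise PhantomSpecError("lung ellipses must not overlap")

    # -- geometry rasterisation -------------------------------------------

    def _grid(self):
        yy, xx = np.mgrid[0 : self.height, 0 : self.width]
        return yy, xx

    def _ellipse(self, center_frac, axes_frac) -> np.ndarray:
        yy, xx = self._grid()
        cy = center_frac[0] * self.height
        cx = center_frac[1] * self.width
        ay = axes_frac[0] * self.height
        ax = axes_frac[1] * self.width
        return ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0

    def _ellipse_masks(self):
        g = self.geometry
        body = self._ellipse(g.body_center, g.body_axes)
        lungs = [self._ellipse(c, g.lung_axes) for c in g.lung_centers]
        return body, lungs

    def digest(self) -> str:
        """Stable hex digest of this parameter set (for cohort manifests)."""
        payload = repr(self).encode()
        return hashlib.sha256(payload).hexdigest()[:16]


def _sample_seed(seed: int, index: int) -> int:
    """Per-sample child seed; index 0 reuses the parent seed unchanged."""
    if index == 0:
        return int(seed)
    state = np.random.SeedSequence([int(seed) & 0x7FFFFFFF, int(index)])
    return int(state.generate_state(1)[0] % (2**31))


def _place_nodule(lung_mask: np.ndarray, spec: PhantomSpec) -> np.ndarray:
    """Disk of nodule_radius just inside the lung wall of the left lung.

    The centre sits on the inward ray from the wall point at the configured
    angle, at the first position whose distance to background is at least
    nodule_radius + NODULE_WALL_CLEARANCE, so the disk abuts the wall while
    remaining strictly inside the lung.
    """
    g = spec.geometry
    cy = g.lung_centers[0][0] * spec.height
    cx = g.lung_centers[0][1] * spec.width
    ay = g.lung_axes[0] * spec.height
    ax = g.lung_axes[1] * spec.width
    theta = g.nodule_angle
    py, px = cy + ay * np.sin(theta), cx + ax * np.cos(theta)
    # inward normal of the ellipse at (py, px)
    ny, nx = -(py - cy) / ay**2, -(px - cx) / ax**2
    norm = np.hypot(ny, nx)
    ny, nx = ny / norm, nx / norm

    edt = ndimage.distance_transform_edt(lung_mask)
    target = spec.nodule_radius + NODULE_WALL_CLEARANCE
    h, w = lung_mask.shape
    for t in np.arange(0.0, max(h, w), 0.5):
        iy, ix = int(round(py + t * ny)), int(round(px + t * nx))
        if 0 <= iy < h and 0 <= ix < w and edt[iy, ix] >= target:
            break
    else:
        raise PhantomSpecError(
            "nodule_radius too large for the lung geometry (no interior "
            "position with the required wall clearance)"
        )
    yy, xx = np.mgrid[0:h, 0:w]
    return (yy - iy) ** 2 + (xx - ix) ** 2 <= spec.nodule_radius**2


def generate_phantom(spec: PhantomSpec) -> tuple[CTSlice, np.ndarray]:
    """Render one phantom slice and its exact ground-truth lung mask.

    Deterministic in ``spec`` (including ``spec.seed``); the ground truth is
    the union of the filled lung ellipses and the attached-nodule disk, with
    interior vessel pixels included.
    """
    ct, truth, _ = generate_phantom_parts(spec)
    return ct, truth


def generate_phantom_parts(
    spec: PhantomSpec,
) -> tuple[CTSlice, np.ndarray, dict]:
    """As :func:`generate_phantom`, also returning the constituent masks
    (``lungs``, ``nodule``, ``body``) for fine-grained checks."""
    spec.validate()
    rng = np.random.default_rng(_sample_seed(spec.seed, 0))

    body, lungs = spec._ellipse_masks()
    lung_union = lungs[0] | lungs[1]

    hu = np.full((spec.height, spec.width), spec.background_hu, dtype=np.float64)
    hu[body] = spec.body_hu
    hu[lung_union] = spec.lung_hu

    # vessels: small bright disks well inside the lungs
    if spec.n_vessels > 0:
        edt = ndimage.distance_transform_edt(lung_union)
        yy, xx = np.mgrid[0 : spec.height, 0 : spec.width]
        for _ in range(spec.n_vessels):
            r = rng.uniform(1.5, 3.0)
            candidates = np.argwhere(edt >= r + 5.0)
            cy, cx = candidates[rng.integers(len(candidates))]
            hu[(yy - cy) ** 2 + (xx - cx) ** 2 <= r**2] = spec.vessel_hu

    truth = lung_union.copy()
    nodule = np.zeros_like(truth)
    if spec.attach_nodule:
        nodule = _place_nodule(lungs[0], spec)
        hu[nodule] = spec.nodule_hu
        truth |= nodule

    if spec.noise_sd > 0:
        hu += rng.normal(0.0, spec.noise_sd, hu.shape)

    ct = CTSlice(
        pixels=hu.astype(np.float32),
        patient_id="phantom",
        slice_id=f"phantom-{spec.seed}",
        source="phantom",
    )
    parts = {
        "lungs": lung_union.astype(np.uint8),
        "nodule": nodule.astype(np.uint8),
        "body": body.astype(np.uint8),
    }
    return ct, truth.astype(np.uint8), parts


def jitter_spec(spec: PhantomSpec, jitter: float, rng: np.random.Generator) -> PhantomSpec:
    """Randomly perturb ellipse centres/axes and nodule placement."""
    g = spec.geometry
    u = lambda: rng.uniform(-1.0, 1.0)
    shift = 0.03 * jitter
    scale = 0.10 * jitter
    lung_centers = tuple(
        (cy + shift * u(), cx + shift * u()) for cy, cx in g.lung_centers
    )
    lung_axes = tuple(a * (1.0 + scale * u()) for a in g.lung_axes)
    geom = replace(
        g,
        lung_centers=lung_centers,
        lung_axes=lung_axes,
        nodule_angle=g.nodule_angle + 0.8 * jitter * u(),
    )
    radius = spec.nodule_radius * (1.0 + 0.2 * jitter * u())
    return replace(spec, geometry=geom, nodule_radius=radius)


def generate_cohort(
    n: int, spec: PhantomSpec, jitter: float = 0.0
) -> list[tuple[CTSlice, np.ndarray]]:
    """Generate ``n`` phantoms with per-sample geometric jitter.

    Per-sample seeds derive deterministically from ``spec.seed`` and the
    sample index, so cohorts are reproducible and order-independent;
    ``generate_cohort(1, spec, 0.0)`` equals ``[generate_phantom(spec)]``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not (0.0 <= jitter <= 1.0):
        raise ValueError("jitter must lie in [0, 1]")
    spec.validate()
    out = []
    for i in range(n):
        child = _sample_seed(spec.seed, i)
        sample_spec = replace(spec, seed=child)
        if jitter > 0.0:
            jrng = np.random.default_rng(np.random.SeedSequence([child, 0x9E3779]))
            sample_spec = jitter_spec(sample_spec, jitter, jrng)
            sample_spec.validate()
        ct, mask = generate_phantom(sample_spec)
        ct.slice_id = f"phantom-{spec.seed}-{i:04d}"
        out.append((ct, mask))
    return out
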